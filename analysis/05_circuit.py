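#!/usr/bin/env python
"""Reconstruct a peptidergic sensory circuit from synthetic tracings.

Builds a nuchal-organ-style circuit: a group of PDF-expressing sensory
neurons converging onto a pair of strongly connected interneurons plus
many weakly contacted targets, and photoreceptor-like neurons with purely
ipsilateral output for contrast. Reports the synapse-count graph (edge
width proportional to sqrt(synapses)), the in-degree spectrum of the
sensory group, per-neuron laterality, and vesicle-based synapse classes.
Writes the graph (GraphML + DOT) to results/circuit/.
"""

import json
from pathlib import Path

import numpy as np

from sigold.circuit import (
    Connector, Skeleton, SkeletonNode, build_graph, classify_synapse,
    in_degree_spectrum, laterality_profile,
)
from sigold.io import export_dot, export_graphml
from sigold.synthetic import sample_clear_diameters, sample_dcv_diameters

OUT = Path(__file__).resolve().parent.parent / "results" / "circuit"


def _skel(nid, x, y=0.0):
    nodes = [SkeletonNode(1, -1, x, y, 0.0),
             SkeletonNode(2, 1, x * 0.5, y + 5.0, 10.0),
             SkeletonNode(3, 2, -x * 0.2, y + 10.0, 20.0)]
    return Skeleton(nid, nodes, soma_node=1)


def main(seed: int = 1) -> None:
    rng = np.random.default_rng(seed)
    sks = {}
    grouping = {}
    sensory = []
    for i in range(1, 7):
        for side, sx in (("l", -1.0), ("r", 1.0)):
            nid = f"SN{side}{i}"
            sks[nid] = _skel(nid, sx * (3 + i))
            grouping[nid] = "SNnuch"
            sensory.append(nid)
    for nid, x in (("INarc-l1", -2.0), ("INarc-r1", 2.0),
                   ("INarc-l2", -2.5), ("INarc-r2", 2.5)):
        sks[nid] = _skel(nid, x)
        grouping[nid] = "INarc"
    weak_targets = [f"t{i}" for i in range(20)]
    for i, nid in enumerate(weak_targets):
        sks[nid] = _skel(nid, float(rng.uniform(-8, 8)))
    for nid, x in (("PRC-r", 4.0), ("PRC-l", -4.0)):
        sks[nid] = _skel(nid, x)
        grouping[nid] = "PRC"

    conns = []
    k = 0
    # sensory neurons synapse bilaterally onto both interneuron pairs
    for pre in sensory:
        for post in ("INarc-l1", "INarc-r1", "INarc-l2", "INarc-r2"):
            if rng.uniform() < 0.45:
                conns.append(Connector(
                    f"c{k}", (pre, 2), [(post, 3)],
                    vesicle_diameters_nm=sample_dcv_diameters(8, rng)))
                k += 1
    # plus scattered single synapses onto weak targets
    for pre in sensory:
        for post in rng.choice(weak_targets, size=3, replace=False):
            conns.append(Connector(
                f"c{k}", (pre, 2), [(str(post), 3)],
                vesicle_diameters_nm=sample_dcv_diameters(8, rng)))
            k += 1
    # photoreceptors: classical, strictly ipsilateral output (post node 2
    # stays on the target's soma side; node 3 crosses the midline)
    for pre, post in (("PRC-r", "INarc-r1"), ("PRC-l", "INarc-l1")):
        for _ in range(4):
            conns.append(Connector(
                f"c{k}", (pre, 2), [(post, 2)],
                vesicle_diameters_nm=sample_clear_diameters(8, rng)))
            k += 1

    g = build_graph(sks, conns, grouping)
    OUT.mkdir(parents=True, exist_ok=True)
    export_graphml(g, OUT / "circuit.graphml")
    export_dot(g, OUT / "circuit.dot")

    w = g["SNnuch"]["INarc"]["weight"]
    print(f"SNnuch -> INarc: {w} synapses (edge width sqrt = "
          f"{g['SNnuch']['INarc']['width']:.2f})")
    per_target, hist = in_degree_spectrum(sks, conns, "SNnuch", grouping)
    single = hist.get(1, 0)
    print(f"in-degree spectrum from SNnuch: max {max(per_target.values())} "
          f"synapses onto one target, {single} targets with exactly one")

    lat = {}
    for nid in ("PRC-r", "PRC-l", "SNl3", "SNr3"):
        lat[nid] = laterality_profile(sks[nid], sks, conns)[2]
    print("laterality indices:",
          {k: (None if np.isnan(v) else round(v, 2))
           for k, v in lat.items()})

    classes = {}
    for c in conns:
        cl = classify_synapse(c.vesicle_diameters_nm)
        classes[cl] = classes.get(cl, 0) + 1
    print(f"synapse classes at the 45-nm cut: {classes}")

    (OUT / "summary.json").write_text(json.dumps({
        "sn_to_inarc_weight": int(w),
        "in_degree_histogram": {str(k): v for k, v in sorted(hist.items())},
        "laterality": {k: (None if np.isnan(v) else v)
                       for k, v in lat.items()},
        "synapse_classes": classes,
    }, indent=1))


if __name__ == "__main__":
    main()
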