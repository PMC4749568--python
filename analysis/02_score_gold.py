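#!/usr/bin/env python
"""Score gold labeling: candidates, control transect, co-occurrence.

Applies the >= 2-gold candidate rule to (a) the simulated dataset from
01_simulate and (b) the packaged PDF gold-count fixture for the
nuchal-organ sensory neurons, samples an unbiased control transect (two
profiles per micrometer), and runs the gold/DCV co-occurrence check.
Writes candidate lists and the co-occurrence report to results/scoring/.
"""

import json
from pathlib import Path

import numpy as np

from sigold import load_table2_fixture, select_candidates, tabulate_gold
from sigold.gold import dcv_cooccurrence_check, sample_control_transect
from sigold.synthetic import SyntheticDataset

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "scoring"


def main() -> None:
    ds = SyntheticDataset.from_json(
        (ROOT / "results" / "simulated" / "dataset.json").read_text())
    table = tabulate_gold(ds)
    OUT.mkdir(parents=True, exist_ok=True)

    cands = select_candidates(table, min_gold=2)
    print(f"simulated series: {len(cands.ids)} candidate neurites "
          f"(>= 2 gold in some labeled section)")

    mid = ds.config.n_sections // 2
    cross = {n.id: tuple(n.centroid(mid)) for n in ds.neurites}
    transect = sample_control_transect(cross)
    print(f"control transect: {len(transect.sampled_neurite_ids)} profiles "
          f"sampled at 2/um")

    rep = dcv_cooccurrence_check(table, ds.dcv_tracks, ds.design)
    print(f"co-occurrence: {rep.n_violations} violations in "
          f"{rep.n_scored_cells} gold-positive cells "
          f"(fraction with DCVs {rep.cooccurrence_fraction:.3f}); "
          f"{len(rep.false_negative_flags)} DCV-absence false negatives")

    tab2 = load_table2_fixture()
    c2 = select_candidates(tab2, min_gold=2)
    print(f"PDF fixture: {len(c2.ids)} of {len(tab2.columns)} neurons are "
          f"candidates: {', '.join(sorted(c2.ids))}")

    (OUT / "scoring.json").write_text(json.dumps({
        "simulated_candidates": sorted(cands.ids),
        "transect_n": len(transect.sampled_neurite_ids),
        "cooccurrence_violations": rep.n_violations,
        "cooccurrence_fraction": rep.cooccurrence_fraction,
        "dcv_absence_false_negatives":
            [[n, a, list(r)] for n, a, r in rep.false_negative_flags],
        "fixture_candidates": sorted(c2.ids),
    }, indent=1))


if __name__ == "__main__":
    main()
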