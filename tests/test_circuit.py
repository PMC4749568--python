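"""Synapse-count graphs, in-degree spectra, laterality, and vesicle-based
synapse classification."""

import numpy as np
import pytest

from sigold.circuit import (
    Connector, Skeleton, SkeletonNode, attach_identities, build_graph,
    classify_synapse, in_degree_spectrum, laterality_profile,
)


def _skel(nid, x=1.0, soma=True, n_nodes=3):
    nodes = [SkeletonNode(1, -1, x, 0.0, 0.0)]
    for k in range(2, n_nodes + 1):
        nodes.append(SkeletonNode(k, k - 1, x, float(k), 0.0))
    return Skeleton(nid, nodes, soma_node=1 if soma else None)


def _conn(cid, pre, posts):
    return Connector(cid, pre, posts)


# ---------------------------------------------------------------------------
# skeleton validation

def test_two_roots_rejected():
    nodes = [SkeletonNode(1, -1, 0, 0, 0), SkeletonNode(2, -1, 0, 1, 0)]
    with pytest.raises(ValueError, match="one root"):
        Skeleton("bad", nodes)


def test_cycle_rejected():
    nodes = [SkeletonNode(1, -1, 0, 0, 0), SkeletonNode(2, 3, 0, 1, 0),
             SkeletonNode(3, 2, 0, 2, 0)]
    with pytest.raises(ValueError, match="cycle"):
        Skeleton("bad", nodes)


# ---------------------------------------------------------------------------
# identity attachment

class _FakeCall:
    def __init__(self, nid, labels):
        self.neurite_id = nid
        self.confirmed_labels = set(labels)


def test_attach_single_match():
    sks = {"n1": _skel("n1")}
    unmatched = attach_identities(sks, [_FakeCall("n1", {"PDF"})])
    assert unmatched == []
    assert sks["n1"].annotations["identity_labels"] == ["PDF"]


def test_attach_unmatched_listed_not_raised():
    sks = {"n1": _skel("n1")}
    unmatched = attach_identities(sks, [_FakeCall("ghost", {"PDF"})])
    assert unmatched == ["ghost"]


def test_ambiguous_mapping_rejected():
    sks = {"n1": _skel("n1")}
    calls = [_FakeCall("a", {"PDF"}), _FakeCall("b", {"FVa"})]
    with pytest.raises(ValueError, match="ambiguous"):
        attach_identities(sks, calls, mapping={"a": "n1", "b": "n1"})


# ---------------------------------------------------------------------------
# graph construction

def test_three_connectors_weight_and_width():
    sks = {"A": _skel("A"), "B": _skel("B")}
    conns = [_conn(f"c{i}", ("A", 2), [("B", 2)]) for i in range(3)]
    g = build_graph(sks, conns)
    assert g["A"]["B"]["weight"] == 3
    assert g["A"]["B"]["width"] == pytest.approx(np.sqrt(3))


def test_polyadic_connector_one_pair_per_post():
    sks = {"A": _skel("A"), "B": _skel("B"), "C": _skel("C")}
    g = build_graph(sks, [_conn("c0", ("A", 2), [("B", 2), ("C", 2)])],
                    grouping={"B": "G1", "C": "G2"})
    assert g["A"]["G1"]["weight"] == 1
    assert g["A"]["G2"]["weight"] == 1


def test_dangling_reference_rejected():
    sks = {"A": _skel("A")}
    with pytest.raises(ValueError, match="unknown"):
        build_graph(sks, [_conn("c0", ("A", 2), [("ghost", 1)])])


def test_weight_conservation_random_sets(rng):
    # sum of edge weights == brute-force (pre, post) pair count, under any
    # random grouping
    names = [f"n{i}" for i in range(12)]
    sks = {n: _skel(n) for n in names}
    for trial in range(30):
        conns = []
        n_pairs = 0
        for c in range(int(rng.integers(1, 25))):
            pre = names[int(rng.integers(len(names)))]
            k = int(rng.integers(1, 4))
            # post node 3 != pre node 2, so self-synapses onto other nodes
            # of the same neuron remain legal
            posts = [(names[int(j)], 3)
                     for j in rng.choice(len(names), size=k, replace=False)]
            conns.append(_conn(f"c{trial}_{c}", (pre, 2), posts))
            n_pairs += k
        grouping = {n: f"g{int(rng.integers(4))}" for n in names
                    if rng.uniform() < 0.5}
        g = build_graph(sks, conns, grouping)
        total = sum(d["weight"] for _, _, d in g.edges(data=True))
        assert total == n_pairs
        # regrouping never changes the total
        g2 = build_graph(sks, conns, None)
        assert sum(d["weight"] for _, _, d in g2.edges(data=True)) == n_pairs


# ---------------------------------------------------------------------------
# in-degree spectrum

def test_in_degree_histogram_toy():
    sks = {n: _skel(n) for n in ("s1", "s2", "t1", "t2", "t3", "t4")}
    grouping = {"s1": "SRC", "s2": "SRC"}
    counts = {"t1": 1, "t2": 1, "t3": 2, "t4": 22}
    conns = []
    i = 0
    for t, k in counts.items():
        for _ in range(k):
            conns.append(_conn(f"c{i}", ("s1" if i % 2 else "s2", 2),
                               [(t, 2)]))
            i += 1
    per_target, hist = in_degree_spectrum(sks, conns, "SRC", grouping)
    assert per_target == counts
    assert hist == {1: 2, 2: 1, 22: 1}
    assert sum(hist.values()) == len(per_target)


def test_empty_source_group_empty_histogram():
    sks = {"a": _skel("a")}
    per_target, hist = in_degree_spectrum(sks, [], "a")
    assert per_target == {} and hist == {}


def test_unknown_group_raises():
    with pytest.raises(KeyError):
        in_degree_spectrum({"a": _skel("a")}, [], "nope")


# ---------------------------------------------------------------------------
# laterality

def _post_at(sks, nid, x):
    sks[nid] = Skeleton(nid, [SkeletonNode(1, -1, x, 0, 0)], soma_node=1)


def test_ipsilateral_only_index_one():
    sks = {}
    _post_at(sks, "prc", 4.0)
    _post_at(sks, "t1", 3.0)
    _post_at(sks, "t2", 6.0)
    conns = [_conn("c0", ("prc", 1), [("t1", 1)]),
             _conn("c1", ("prc", 1), [("t2", 1)])]
    assert laterality_profile(sks["prc"], sks, conns) == (2, 0, 1.0)


def test_balanced_bilateral_index_half():
    sks = {}
    _post_at(sks, "sn", 2.0)
    _post_at(sks, "l", -3.0)
    _post_at(sks, "r", 3.0)
    conns = [_conn("c0", ("sn", 1), [("l", 1)]),
             _conn("c1", ("sn", 1), [("r", 1)])]
    n_ipsi, n_contra, idx = laterality_profile(sks["sn"], sks, conns)
    assert (n_ipsi, n_contra, idx) == (1, 1, 0.5)


def test_all_contralateral_index_zero():
    sks = {}
    _post_at(sks, "a", -2.0)
    _post_at(sks, "t", 3.0)
    conns = [_conn("c0", ("a", 1), [("t", 1)])]
    assert laterality_profile(sks["a"], sks, conns)[2] == 0.0


def test_laterality_invariant_under_reflection():
    sks = {}
    _post_at(sks, "a", 2.0)
    _post_at(sks, "t1", -1.0)
    _post_at(sks, "t2", 4.0)
    _post_at(sks, "t3", 5.0)
    conns = [_conn(f"c{i}", ("a", 1), [(t, 1)])
             for i, t in enumerate(("t1", "t2", "t3"))]
    idx = laterality_profile(sks["a"], sks, conns)[2]
    mirrored = {}
    for nid, sk in sks.items():
        mirrored[nid] = Skeleton(
            nid, [SkeletonNode(n.node_id, n.parent_id, -n.x, n.y, n.z)
                  for n in sk.nodes], soma_node=sk.soma_node)
    assert laterality_profile(mirrored["a"], mirrored, conns)[2] == idx


def test_missing_soma_uses_root_with_warning():
    sks = {}
    sks["a"] = Skeleton("a", [SkeletonNode(1, -1, 2.0, 0, 0)])
    _post_at(sks, "t", 3.0)
    conns = [_conn("c0", ("a", 1), [("t", 1)])]
    with pytest.warns(UserWarning, match="root"):
        assert laterality_profile(sks["a"], sks, conns)[2] == 1.0


# ---------------------------------------------------------------------------
# synapse classification

def test_classify_dense_core_like():
    rng = np.random.default_rng(0)
    d = rng.normal(63, 8.4, size=20).clip(min=46)
    assert classify_synapse(d) == "peptidergic"


def test_classify_clear_and_mixed_and_errors():
    assert classify_synapse([30, 35, 40]) == "classical"
    assert classify_synapse([30, 50]) == "mixed"
    with pytest.raises(ValueError):
        classify_synapse([])
    with pytest.raises(ValueError):
        classify_synapse([-1.0])


def test_misclassification_matches_overlap_prediction(rng):
    # per-synapse misclassification at the 45-nm cut equals the
    # truncated-normal tail prediction, 1 - (1 - p_tail)^k for k vesicles
    from scipy import stats
    from sigold.synthetic import sample_clear_diameters, sample_dcv_diameters
    k, n_syn = 10, 3000
    # peptidergic: any vesicle below the cut makes the call not-peptidergic
    p_below = stats.truncnorm.cdf((45 - 63) / 8.4, (0 - 63) / 8.4, np.inf)
    pred_pep = 1 - (1 - p_below) ** k
    mis = sum(
        classify_synapse(sample_dcv_diameters(k, rng)) != "peptidergic"
        for _ in range(n_syn)) / n_syn
    assert abs(mis - pred_pep) < 3 * np.sqrt(pred_pep * (1 - pred_pep) / n_syn) + 1e-3
    # classical: any vesicle at/above the cut
    p_above = stats.truncnorm.sf((45 - 35) / 5.0, (0 - 35) / 5.0, np.inf)
    pred_cls = 1 - (1 - p_above) ** k
    mis = sum(
        classify_synapse(sample_clear_diameters(k, rng)) != "classical"
        for _ in range(n_syn)) / n_syn
    assert abs(mis - pred_cls) < 3 * np.sqrt(pred_cls * (1 - pred_cls) / n_syn) + 1e-3
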