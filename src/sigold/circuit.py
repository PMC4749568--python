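"""Circuit reconstruction from skeletons and synapse connectors.

Builds directed synapse-count graphs over identity-tagged neurons (edge
weight = number of presynaptic-to-postsynaptic pairs, display width
proportional to the square root of the weight), computes per-target
in-degree spectra, laterality of presynaptic output relative to the soma
side, and classifies synapses as peptidergic or classical from vesicle
diameters (dense-core vesicles are ~63 nm, clear vesicles ~35 nm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Skeleton", "SkeletonNode", "Connector", "attach_identities",
    "build_graph", "in_degree_spectrum", "laterality_profile",
    "classify_synapse",
]


@dataclass
class SkeletonNode:
    node_id: int
    parent_id: int          # -1 for the root
    x: float
    y: float
    z: float
    radius: float = 1.0
    struct_type: int = 0    # SWC structure-type column


@dataclass
class Skeleton:
    """A traced neuron: a rooted tree of 3D nodes plus annotations."""

    neuron_id: str
    nodes: list[SkeletonNode]
    soma_node: int | None = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [n.node_id for n in self.nodes]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.neuron_id}: duplicate node ids")
        idset = set(ids)
        roots = [n for n in self.nodes if n.parent_id == -1]
        if len(roots) != 1:
            raise ValueError(
                f"{self.neuron_id}: expected exactly one root, "
                f"found {len(roots)}")
        for n in self.nodes:
            if n.parent_id != -1 and n.parent_id not in idset:
                raise ValueError(
                    f"{self.neuron_id}: node {n.node_id} references missing "
                    f"parent {n.parent_id}")
        # acyclicity + connectedness follow from each non-root having a
        # parent chain terminating at the root
        parent = {n.node_id: n.parent_id for n in self.nodes}
        for start in ids:
            seen = set()
            cur = start
            while cur != -1:
                if cur in seen:
                    raise ValueError(
                        f"{self.neuron_id}: cycle through node {cur}")
                seen.add(cur)
                cur = parent[cur]

    @property
    def root(self) -> SkeletonNode:
        return next(n for n in self.nodes if n.parent_id == -1)

    def node(self, node_id: int) -> SkeletonNode:
        for n in self.nodes:
            if n.node_id == node_id:
                return n
        raise KeyError(node_id)

    def soma_side(self, midline_x: float = 0.0) -> str:
        """'left'/'right' of the soma (root node if no soma is marked)."""
        if self.soma_node is not None:
            ref = self.node(self.soma_node)
        else:
            warnings.warn(
                f"{self.neuron_id}: no soma marked, using root node side",
                stacklevel=2)
            ref = self.root
        return "left" if ref.x < midline_x else "right"


@dataclass
class Connector:
    """One (possibly polyadic) synapse: one presynaptic node, >= 1 posts."""

    connector_id: str
    pre: tuple[str, int]                 # (neuron_id, node_id)
    posts: list[tuple[str, int]]
    section_index: int | None = None
    vesicle_diameters_nm: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.posts:
            raise ValueError(f"{self.connector_id}: needs >= 1 post target")
        if self.pre in self.posts:
            raise ValueError(
                f"{self.connector_id}: presynaptic node cannot also be "
                f"postsynaptic on the same node")


# ---------------------------------------------------------------------------
# identity attachment

def attach_identities(skeletons: Mapping[str, Skeleton],
                      calls: Iterable,
                      mapping: Mapping[str, str] | None = None,
                      ) -> list[str]:
    """Copy confirmed identity labels from calls onto skeleton annotations.

    ``mapping`` translates call neurite IDs to skeleton neuron IDs
    (identity mapping by default). Returns the list of call IDs that
    matched no skeleton; raises on ambiguous (duplicate-target) mappings.
    """
    mapping = dict(mapping) if mapping is not None else None
    if mapping is not None:
        targets = list(mapping.values())
        dupes = sorted({t for t in targets if targets.count(t) > 1})
        if dupes:
            raise ValueError(f"ambiguous identity mapping onto {dupes}")
    unmatched: list[str] = []
    for call in calls:
        nid = call.neurite_id
        target = mapping.get(nid, nid) if mapping is not None else nid
        if target not in skeletons:
            unmatched.append(nid)
            continue
        ann = skeletons[target].annotations
        labels = set(ann.get("identity_labels", ())) | call.confirmed_labels
        ann["identity_labels"] = sorted(labels)
    return unmatched


# ---------------------------------------------------------------------------
# synapse-count graph

def build_graph(skeletons: Mapping[str, Skeleton],
                connectors: Sequence[Connector],
                grouping: Mapping[str, str] | None = None) -> nx.DiGraph:
    """Directed graph with edge weight = synaptic pair count.

    Nodes are neurons, or named groups where ``grouping`` maps neuron_id ->
    group name (ungrouped neurons stay singleton nodes). Each polyadic
    connector contributes one pair per post target (the CATMAID
    convention). Every edge also carries ``width = sqrt(weight)`` for
    display. Sum of weights always equals the number of (pre, post) pairs.
    """
    grouping = dict(grouping or {})

    def node_of(neuron_id: str) -> str:
        return grouping.get(neuron_id, neuron_id)

    g = nx.DiGraph()
    for nid, sk in skeletons.items():
        g.add_node(node_of(nid))
        members = g.nodes[node_of(nid)].setdefault("members", [])
        members.append(nid)
    for c in connectors:
        pre_id = c.pre[0]
        if pre_id not in skeletons:
            raise ValueError(
                f"{c.connector_id}: presynaptic neuron {pre_id} unknown")
        for post_id, _node in c.posts:
            if post_id not in skeletons:
                raise ValueError(
                    f"{c.connector_id}: postsynaptic neuron {post_id} unknown")
            u, v = node_of(pre_id), node_of(post_id)
            if g.has_edge(u, v):
                g[u][v]["weight"] += 1
            else:
                g.add_edge(u, v, weight=1)
    for u, v, d in g.edges(data=True):
        d["width"] = float(np.sqrt(d["weight"]))
    return g


def in_degree_spectrum(skeletons: Mapping[str, Skeleton],
                       connectors: Sequence[Connector],
                       source_group: str,
                       grouping: Mapping[str, str] | None = None,
                       ) -> tuple[dict[str, int], dict[int, int]]:
    """Synapses received per target neuron from one source group.

    Returns (per-target synapse counts, histogram {k: number of target
    neurons receiving exactly k synapses from the group}).
    """
    grouping = dict(grouping or {})
    members = {nid for nid in skeletons
               if grouping.get(nid, nid) == source_group}
    if not members and source_group not in set(grouping.values()) \
            and source_group not in skeletons:
        raise KeyError(f"unknown source group {source_group!r}")
    per_target: dict[str, int] = {}
    for c in connectors:
        if c.pre[0] not in members:
            continue
        for post_id, _ in c.posts:
            per_target[post_id] = per_target.get(post_id, 0) + 1
    hist: dict[int, int] = {}
    for k in per_target.values():
        hist[k] = hist.get(k, 0) + 1
    return per_target, hist


# ---------------------------------------------------------------------------
# laterality

def laterality_profile(skeleton: Skeleton,
                       skeletons: Mapping[str, Skeleton],
                       connectors: Sequence[Connector],
                       midline_x: float = 0.0,
                       ) -> tuple[int, int, float]:
    """Ipsi/contralateral split of a neuron's outgoing synapses.

    Each outgoing synaptic pair is classified by the side of the
    postsynaptic *node* relative to the presynaptic neuron's soma side.
    Returns (n_ipsi, n_contra, index) with index = n_ipsi / total; the
    index is NaN for a neuron with no outgoing synapses.
    """
    side = skeleton.soma_side(midline_x)
    n_ipsi = n_contra = 0
    for c in connectors:
        if c.pre[0] != skeleton.neuron_id:
            continue
        for post_id, node_id in c.posts:
            post_sk = skeletons[post_id]
            node = post_sk.node(node_id)
            post_side = "left" if node.x < midline_x else "right"
            if post_side == side:
                n_ipsi += 1
            else:
                n_contra += 1
    total = n_ipsi + n_contra
    index = n_ipsi / total if total else float("nan")
    return n_ipsi, n_contra, index


# ---------------------------------------------------------------------------
# synapse classification

def classify_synapse(vesicle_diameters_nm: Sequence[float],
                     cut_nm: float = 45.0) -> str:
    """'peptidergic' | 'classical' | 'mixed' from vesicle diameters.

    Dense-core (neuropeptide) vesicles are large (~63 nm); clear synaptic
    vesicles are small (~35 nm). All diameters >= ``cut_nm`` ->
    peptidergic; all below -> classical; otherwise mixed.
    """
    d = np.asarray(list(vesicle_diameters_nm), float)
    if d.size == 0:
        raise ValueError("need at least one vesicle diameter")
    if np.any(d <= 0):
        raise ValueError("vesicle diameters must be positive")
    if np.all(d >= cut_nm):
        return "peptidergic"
    if np.all(d < cut_nm):
        return "classical"
    return "mixed"
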