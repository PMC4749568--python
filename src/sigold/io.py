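"""File formats and packaged fixtures.

SWC skeletons (standard 7-column, with a JSON sidecar for annotations),
JSON-lines connectors, CSV gold tables, GraphML/DOT circuit graphs,
multi-page TIFF image stacks, YAML run configs, and the packaged
PDF-antibody gold-count fixture for the nuchal-organ sensory neurons.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .circuit import Connector, Skeleton, SkeletonNode
from .gold import GoldTable
from .synthetic import ImageStack

__all__ = [
    "load_table2_fixture", "table2_notes", "read_swc", "write_swc",
    "read_connectors", "write_connectors", "read_stacks", "write_stacks",
    "export_graphml", "export_dot", "FormatError",
]

TABLE2_LAYERS = (703, 723, 787)
TABLE2_ANTIBODY = "PDF"


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# packaged fixture

def load_table2_fixture() -> GoldTable:
    """PDF-antibody gold counts for the 35 nuchal-organ sensory neurons
    (r1–r20, l1–l15) over the three labeled whole-body sections
    (703, 723, 787).

    The returned table carries an ``ambiguity_notes`` attribute mapping
    neuron id -> note for cells whose printed rendering is ambiguous (these
    are excluded from worked-example assertions).
    """
    src = resources.files("sigold.data").joinpath("table2_pdf_gold.csv")
    with resources.as_file(src) as p:
        df = pd.read_csv(p, dtype={"note": str}, keep_default_na=False)
    cells: dict[tuple[str, int], dict[str, int]] = {
        (TABLE2_ANTIBODY, layer): {} for layer in TABLE2_LAYERS
    }
    notes: dict[str, str] = {}
    for _, row in df.iterrows():
        nid = str(row["neuron"])
        for layer in TABLE2_LAYERS:
            cells[(TABLE2_ANTIBODY, layer)][nid] = int(row[f"layer_{layer}"])
        if row["note"]:
            notes[nid] = str(row["note"])
    table = GoldTable(cells, column_order=[str(n) for n in df["neuron"]])
    table.ambiguity_notes = notes  # type: ignore[attr-defined]
    return table


def table2_notes() -> str:
    """Provenance and transcription notes for the packaged fixture."""
    src = resources.files("sigold.data").joinpath("table2_notes.md")
    return src.read_text(encoding="utf-8")


# ---------------------------------------------------------------------------
# SWC skeletons

def read_swc(path, neuron_id: str | None = None) -> Skeleton:
    """Read a standard 7-column SWC file ('#' comments allowed).

    Columns: node_id, structure_type, x, y, z, radius, parent_id. A node of
    structure type 1 (soma) becomes the skeleton's soma node. A JSON
    sidecar ``<path>.json``, if present, supplies annotations.
    """
    path = Path(path)
    nodes: list[SkeletonNode] = []
    soma = None
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise FormatError(
                f"{path}:{lineno}: expected 7 SWC columns, got {len(parts)}")
        nid, stype = int(parts[0]), int(parts[1])
        x, y, z, r = (float(v) for v in parts[2:6])
        parent = int(parts[6])
        nodes.append(SkeletonNode(nid, parent, x, y, z, r, stype))
        if stype == 1 and soma is None:
            soma = nid
    name = neuron_id if neuron_id is not None else path.stem
    try:
        sk = Skeleton(name, nodes, soma_node=soma)
    except ValueError as e:
        raise FormatError(f"{path}: {e}") from e
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        sk.annotations.update(json.loads(sidecar.read_text()))
    return sk


def write_swc(skeleton: Skeleton, path, sidecar: bool = True) -> None:
    """Write a skeleton as 7-column SWC (+ JSON annotation sidecar)."""
    path = Path(path)
    lines = [f"# neuron {skeleton.neuron_id}"]
    for n in sorted(skeleton.nodes, key=lambda n: n.node_id):
        stype = 1 if n.node_id == skeleton.soma_node else (n.struct_type or 0)
        lines.append(
            f"{n.node_id} {stype} {n.x:.6g} {n.y:.6g} {n.z:.6g} "
            f"{n.radius:.6g} {n.parent_id}")
    path.write_text("\n".join(lines) + "\n")
    if sidecar and skeleton.annotations:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(skeleton.annotations, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# connectors (JSON-lines)

def write_connectors(connectors: Sequence[Connector], path) -> None:
    with open(path, "w") as fh:
        for c in connectors:
            fh.write(json.dumps({
                "connector_id": c.connector_id,
                "pre": list(c.pre),
                "posts": [list(p) for p in c.posts],
                "section_index": c.section_index,
                "vesicle_diameters_nm": (
                    None if c.vesicle_diameters_nm is None
                    else np.asarray(c.vesicle_diameters_nm).tolist()),
            }) + "\n")


def read_connectors(path) -> list[Connector]:
    out: list[Connector] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        try:
            d = json.loads(line)
            out.append(Connector(
                connector_id=str(d["connector_id"]),
                pre=(d["pre"][0], int(d["pre"][1])),
                posts=[(p[0], int(p[1])) for p in d["posts"]],
                section_index=d.get("section_index"),
                vesicle_diameters_nm=(
                    None if d.get("vesicle_diameters_nm") is None
                    else np.asarray(d["vesicle_diameters_nm"], float)),
            ))
        except (KeyError, ValueError, IndexError) as e:
            raise FormatError(f"{path}:{lineno}: {e}") from e
    return out


# ---------------------------------------------------------------------------
# graphs

def export_graphml(graph, path) -> None:
    import networkx as nx
    g = graph.copy()
    for _, d in g.nodes(data=True):
        if "members" in d:
            d["members"] = ",".join(d["members"])
    nx.write_graphml(g, path)


def export_dot(graph, path) -> None:
    """Minimal DOT export with weight labels and sqrt-weight pen widths."""
    lines = ["digraph circuit {"]
    for n in sorted(graph.nodes):
        lines.append(f'  "{n}";')
    for u, v, d in sorted(graph.edges(data=True)):
        w = d.get("weight", 1)
        width = d.get("width", float(np.sqrt(w)))
        lines.append(
            f'  "{u}" -> "{v}" [label="{w}", penwidth={width:.3f}];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# image stacks

def write_stacks(stacks: Sequence[ImageStack] | ImageStack, path) -> None:
    """Write one stack (or a cohort) as multi-page TIFF(s)."""
    import tifffile
    if isinstance(stacks, ImageStack):
        tifffile.imwrite(path, np.asarray(stacks.data, np.float32),
                         photometric="minisblack")
        return
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for st in stacks:
        name = st.stack_id or f"stack{id(st)}"
        tifffile.imwrite(path / f"{name}.tif",
                         np.asarray(st.data, np.float32),
                         photometric="minisblack")


def read_stacks(path) -> list[ImageStack]:
    """Read all .tif stacks in a directory (or one file) as ImageStacks."""
    import tifffile
    path = Path(path)
    files = sorted(path.glob("*.tif")) if path.is_dir() else [path]
    if not files:
        raise FormatError(f"no .tif stacks under {path}")
    return [ImageStack(tifffile.imread(f), stack_id=f.stem) for f in files]
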