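"""Gold-particle quantification over serial sections.

Implements the scoring side of serial-multiplex immunogold labeling: the
antibody x layer x neurite count table with row/column totals, the
>= 2-gold candidate-selection rule, unbiased control-transect sampling
(two profiles per micrometer), ordinal intensity shading, and the check
that gold only ever co-occurs with dense-core vesicles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic import DCVTrack, LabelingDesign, SyntheticDataset

__all__ = [
    "GoldTable", "TransectSample", "ShadeBin", "CandidateSet",
    "CooccurrenceReport", "tabulate_gold", "select_candidates",
    "sample_control_transect", "dcv_cooccurrence_check", "shade",
]


class TableIntegrityError(ValueError):
    """Duplicate or inconsistent cells while building a gold table."""


class CoverageError(ValueError):
    """A tabulated neurite lacks the auxiliary data a check requires."""


# ---------------------------------------------------------------------------
# the gold table

class GoldTable:
    """Antibody x layer x neurite gold-count matrix.

    Rows are keyed by (antibody, layer_index) and ordered by antibody then
    layer; columns are neurite IDs ordered by spatial position in the
    cross-section when geometry is available. Cells where a neurite does
    not intersect a labeled layer are *absent* — distinct from zero — and
    are ignored by all totals.
    """

    def __init__(self,
                 cells: Mapping[tuple[str, int], Mapping[str, int]],
                 column_order: Sequence[str] | None = None,
                 antibody_order: Sequence[str] | None = None) -> None:
        self.cells: dict[tuple[str, int], dict[str, int]] = {}
        for key, row in cells.items():
            ab, layer = key
            r: dict[str, int] = {}
            for nid, c in row.items():
                if c < 0:
                    raise TableIntegrityError(
                        f"negative count at ({ab}, {layer}, {nid})")
                if nid in r:
                    raise TableIntegrityError(
                        f"duplicate cell ({ab}, {layer}, {nid})")
                r[nid] = int(c)
            if (ab, int(layer)) in self.cells:
                raise TableIntegrityError(f"duplicate row ({ab}, {layer})")
            self.cells[(ab, int(layer))] = r

        if antibody_order is None:
            antibody_order = []
            for ab, _ in sorted(self.cells, key=lambda k: (k[1], k[0])):
                if ab not in antibody_order:
                    antibody_order.append(ab)
        self.antibody_order = list(antibody_order)
        self.row_keys: list[tuple[str, int]] = sorted(
            self.cells,
            key=lambda k: (self.antibody_order.index(k[0]), k[1]),
        )
        if column_order is None:
            seen: list[str] = []
            for key in self.row_keys:
                for nid in self.cells[key]:
                    if nid not in seen:
                        seen.append(nid)
            column_order = seen
        self.columns = list(column_order)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, str, int]],
                     **kw) -> "GoldTable":
        """Build from (antibody, layer, neurite, count) records."""
        cells: dict[tuple[str, int], dict[str, int]] = {}
        for ab, layer, nid, c in records:
            row = cells.setdefault((ab, int(layer)), {})
            if nid in row:
                raise TableIntegrityError(
                    f"duplicate cell ({ab}, {layer}, {nid})")
            row[nid] = int(c)
        return cls(cells, **kw)

    # -- access -----------------------------------------------------------

    def get(self, antibody: str, layer: int, neurite_id: str) -> int | None:
        """Cell count, or None where the cell is absent."""
        return self.cells.get((antibody, int(layer)), {}).get(neurite_id)

    def column(self, neurite_id: str) -> dict[tuple[str, int], int]:
        return {
            key: row[neurite_id]
            for key, row in self.cells.items() if neurite_id in row
        }

    def row_total(self, antibody: str, layer: int) -> int:
        return sum(self.cells[(antibody, int(layer))].values())

    def column_total(self, neurite_id: str) -> int:
        return sum(self.column(neurite_id).values())

    @property
    def grand_total(self) -> int:
        return sum(sum(r.values()) for r in self.cells.values())

    def n_layers_per_antibody(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for ab, _ in self.row_keys:
            out[ab] = out.get(ab, 0) + 1
        return out

    @property
    def n_cells(self) -> int:
        return sum(len(r) for r in self.cells.values())

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, GoldTable)
                and self.cells == other.cells
                and self.columns == other.columns)

    # -- views ------------------------------------------------------------

    def to_frame(self, totals: bool = False) -> pd.DataFrame:
        """DataFrame view; absent cells are NaN. With ``totals`` a final
        'total' row and column are appended."""
        idx = pd.MultiIndex.from_tuples(self.row_keys,
                                        names=["antibody", "layer"])
        df = pd.DataFrame(np.nan, index=idx, columns=list(self.columns))
        for (ab, layer), row in self.cells.items():
            for nid, c in row.items():
                df.loc[(ab, layer), nid] = c
        if totals:
            df["total"] = df.sum(axis=1, skipna=True)
            df.loc[("total", -1), :] = df.sum(axis=0, skipna=True)
        return df

    def to_csv(self, path) -> None:
        self.to_frame(totals=True).to_csv(path)

    @classmethod
    def read_csv(cls, path) -> "GoldTable":
        df = pd.read_csv(path, index_col=[0, 1])
        df = df[[c for c in df.columns if c != "total"]]
        df = df[[i != ("total", -1) for i in
                 zip(df.index.get_level_values(0),
                     df.index.get_level_values(1).astype(int))]]
        cells: dict[tuple[str, int], dict[str, int]] = {}
        ab_order: list[str] = []
        for (ab, layer), row in df.iterrows():
            if ab not in ab_order:
                ab_order.append(ab)
            cells[(str(ab), int(layer))] = {
                str(n): int(v) for n, v in row.items() if pd.notna(v)
            }
        return cls(cells, column_order=[str(c) for c in df.columns],
                   antibody_order=ab_order)


def tabulate_gold(source: SyntheticDataset | Mapping | Iterable,
                  neurite_positions: Mapping[str, float] | None = None,
                  ) -> GoldTable:
    """Tabulate gold counts into a GoldTable.

    ``source`` may be a SyntheticDataset (columns ordered left-to-right by
    the neurites' mean x, the spatial arrangement used in cross-section
    figures), a mapping {(antibody, layer): {neurite: count}}, or an
    iterable of (antibody, layer, neurite, count) records.
    """
    if isinstance(source, SyntheticDataset):
        order = sorted(
            {nid for row in source.gold.values() for nid in row},
            key=lambda nid: float(np.mean(source.neurite(nid).path[:, 0])),
        )
        ab_order = [a for a in source.config.antibody_panel
                    if any(k[0] == a for k in source.gold)]
        return GoldTable(source.gold, column_order=order,
                         antibody_order=ab_order)
    if isinstance(source, Mapping):
        table = GoldTable(source)
    else:
        table = GoldTable.from_records(source)
    if neurite_positions is not None:
        table.columns.sort(key=lambda nid: neurite_positions.get(nid, 0.0))
    return table


# ---------------------------------------------------------------------------
# candidate selection

@dataclass
class CandidateSet:
    """Neurites passing the >= min_gold rule, with witnessing cells."""

    min_gold: int
    witnesses: dict[str, list[tuple[str, int, int]]]  # nid -> [(ab, layer, c)]

    @property
    def ids(self) -> set[str]:
        return set(self.witnesses)

    def __contains__(self, neurite_id: str) -> bool:
        return neurite_id in self.witnesses


def select_candidates(table: GoldTable, min_gold: int = 2) -> CandidateSet:
    """All neurites with >= ``min_gold`` gold particles in any labeled
    section — the rule used to pick neurites for full tracing."""
    if min_gold < 1:
        raise ValueError("min_gold must be >= 1")
    witnesses: dict[str, list[tuple[str, int, int]]] = {}
    for (ab, layer), row in sorted(table.cells.items()):
        for nid, c in row.items():
            if c >= min_gold:
                witnesses.setdefault(nid, []).append((ab, layer, c))
    return CandidateSet(min_gold=min_gold, witnesses=witnesses)


# ---------------------------------------------------------------------------
# control transect

@dataclass
class TransectSample:
    """Profiles sampled along a line across the cross-section."""

    transect: tuple[tuple[float, float], tuple[float, float]]
    sampled_neurite_ids: list[str]
    step_um: float = 1.0
    per_step: int = 2


def _widest_chord(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Endpoints of the widest chord (diameter) of a point set."""
    if len(points) == 1:
        return points[0], points[0]
    try:
        from scipy.spatial import ConvexHull
        hull = points[ConvexHull(points).vertices]
    except Exception:  # collinear or tiny sets
        hull = points
    d = ((hull[:, None, :] - hull[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    return hull[i], hull[j]


def sample_control_transect(cross_section: Mapping[str, tuple[float, float]],
                            step_um: float = 1.0,
                            per_step: int = 2,
                            endpoints: tuple | None = None,
                            rng: np.random.Generator | None = None,
                            ) -> TransectSample:
    """Unbiased control sampling: walk a transect across the cross-section
    and take ``per_step`` nearest not-yet-sampled profiles every
    ``step_um`` micrometers.

    ``cross_section`` maps neurite id -> (x, y) centroid in one reference
    section. The default transect is the widest chord of the convex hull of
    the centroids. If fewer profiles remain than requested, a warning is
    issued and a shorter sample returned.
    """
    if step_um <= 0:
        raise ValueError("step_um must be > 0")
    if per_step < 0:
        raise ValueError("per_step must be >= 0")
    ids = sorted(cross_section)
    if not ids or per_step == 0:
        ep = endpoints if endpoints is not None else ((0.0, 0.0), (0.0, 0.0))
        return TransectSample(ep, [], step_um, per_step)
    pts = np.array([cross_section[i] for i in ids], float)
    if endpoints is None:
        a, b = _widest_chord(pts)
    else:
        a, b = np.asarray(endpoints[0], float), np.asarray(endpoints[1], float)
    length = float(np.linalg.norm(b - a))
    n_steps = int(np.floor(length / step_um))
    direction = (b - a) / length if length > 0 else np.zeros(2)

    available = dict(zip(ids, pts))
    sampled: list[str] = []
    for k in range(1, n_steps + 1):
        p = a + direction * (k * step_um)
        for _ in range(per_step):
            if not available:
                warnings.warn(
                    "fewer profiles available than requested along the "
                    "transect; returning a shorter sample",
                    stacklevel=2,
                )
                return TransectSample((tuple(a), tuple(b)), sampled,
                                      step_um, per_step)
            rest = sorted(available)
            dist = [float(np.linalg.norm(available[i] - p)) for i in rest]
            pick = rest[int(np.argmin(dist))]
            sampled.append(pick)
            del available[pick]
    return TransectSample((tuple(a), tuple(b)), sampled, step_um, per_step)


# ---------------------------------------------------------------------------
# DCV co-occurrence

@dataclass
class CooccurrenceReport:
    """Outcome of the gold/DCV co-occurrence check.

    ``violations`` lists cells with >= min_gold gold but zero DCVs — the
    pattern the deposition model forbids at zero background.
    ``false_negative_flags`` lists (neurite, antibody, run_range) where an
    entire labeled run shows no gold *and* no DCVs while another run of the
    same antibody labels the neurite: absence of signal explained by
    absence of vesicles, not by absence of the peptide.
    """

    violations: list[tuple[str, str, int, int]]  # (nid, ab, layer, gold)
    cooccurrence_fraction: float
    n_scored_cells: int
    false_negative_flags: list[tuple[str, str, tuple[int, int]]] = field(
        default_factory=list)

    @property
    def n_violations(self) -> int:
        return len(self.violations)


def dcv_cooccurrence_check(table: GoldTable,
                           dcv_tracks: Mapping[str, DCVTrack],
                           design: LabelingDesign | None = None,
                           min_gold: int = 2) -> CooccurrenceReport:
    """Check that gold labeling only occurs on sections containing DCVs."""
    missing = sorted({
        nid for row in table.cells.values() for nid in row
        if nid not in dcv_tracks
    })
    if missing:
        raise CoverageError(
            f"no DCV track for tabulated neurites: {missing}")

    violations: list[tuple[str, str, int, int]] = []
    n_hot = 0
    n_hot_with_dcv = 0
    for (ab, layer), row in sorted(table.cells.items()):
        for nid, c in sorted(row.items()):
            if c >= min_gold:
                n_hot += 1
                if dcv_tracks[nid].count(layer) > 0:
                    n_hot_with_dcv += 1
                else:
                    violations.append((nid, ab, layer, c))
    frac = n_hot_with_dcv / n_hot if n_hot else 1.0

    flags: list[tuple[str, str, tuple[int, int]]] = []
    if design is not None:
        nids = {nid for row in table.cells.values() for nid in row}
        for ab in design.antibodies:
            runs = design.runs_for(ab)
            for nid in sorted(nids):
                hot_runs, silent_dcvless = [], []
                for run in runs:
                    cells = [
                        table.get(ab, s, nid) for s in range(*run)
                        if table.get(ab, s, nid) is not None
                    ]
                    if not cells:
                        continue
                    if max(cells) >= min_gold:
                        hot_runs.append(run)
                    elif (sum(cells) == 0 and
                          all(dcv_tracks[nid].count(s) == 0
                              for s in range(*run))):
                        silent_dcvless.append(run)
                if hot_runs and silent_dcvless:
                    flags.extend((nid, ab, run) for run in silent_dcvless)
    return CooccurrenceReport(violations, frac, n_hot, flags)


# ---------------------------------------------------------------------------
# intensity shading

@dataclass
class ShadeBin:
    """Ordinal intensity bins; ``lower_bounds[k]`` is the smallest count of
    shade ``k``. Shade 0 is reserved for count 0."""

    lower_bounds: tuple[int, ...] = (0, 1, 2, 5, 10)

    def __post_init__(self) -> None:
        lb = self.lower_bounds
        if len(lb) < 2 or lb[0] != 0 or lb[1] != 1:
            raise ValueError("shade 0 must be reserved for count 0")
        if any(b >= a for b, a in zip(lb, lb[1:])):
            raise ValueError("bin edges must be strictly increasing")

    def shade_of(self, count: int) -> int:
        if count < 0:
            raise ValueError("counts are non-negative")
        return int(np.searchsorted(self.lower_bounds, count, side="right") - 1)


def shade(table: GoldTable,
          bins: ShadeBin | None = None) -> dict[tuple[str, int], dict[str, int]]:
    """Ordinal shade per cell, monotone in count (absent cells stay absent)."""
    bins = bins if bins is not None else ShadeBin()
    return {
        key: {nid: bins.shade_of(c) for nid, c in row.items()}
        for key, row in table.cells.items()
    }
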