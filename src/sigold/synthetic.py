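"""Synthetic serial-section immunogold datasets.

Generates stacks of serial sections crossed by neurite profiles with the
statistical structure the serial-multiplex immunogold (siGOLD) strategy
assumes:

* bilaterally mirrored neurite positions about the x=0 midline;
* bursty, non-uniform dense-core-vesicle (DCV) occupancy along each neurite
  (two-state Markov chain with Poisson counts in the 'on' state), so that
  zero-runs — sections completely lacking DCVs — occur naturally;
* a sparse labeling design assigning one antibody per short run of
  consecutive sections, either as paired grids ~50 sections apart or as
  1–6-section runs scattered over thousands of sections;
* stochastic gold deposition proportional to local DCV content with
  antibody cross-reactivity, area-proportional background, and incomplete
  silver enhancement (a thinned Poisson law);
* synapse records carrying vesicle-diameter samples (dense-core vs clear).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage, stats

from .config import ConfigurationError, SimConfig

__all__ = [
    "Neurite", "DCVTrack", "LabelingDesign", "SynapseRecord",
    "SyntheticDataset", "ImageStack", "ImageStackSet",
    "generate_neurites", "sample_dcv_counts", "make_paired_grid_design",
    "make_whole_body_design", "deposit_gold", "generate_synapses",
    "generate_dataset", "sample_dcv_diameters", "render_if_stacks",
]


# ---------------------------------------------------------------------------
# domain types

@dataclass
class Neurite:
    """A neurite profile crossing a contiguous range of sections.

    IDs follow the convention 'n<k>' for the first series and 'N<k>' for a
    second series. ``path`` holds one (x, y) centroid in um per section of
    ``section_range`` (half-open). x < 0 is the left body side.
    """

    id: str
    side: str                      # 'left' | 'right' | 'medial'
    section_range: tuple[int, int]  # half-open [start, end)
    path: np.ndarray               # (n_sections_spanned, 2) centroids, um
    area_per_section: np.ndarray   # (n_sections_spanned,) profile area, um^2
    true_peptides: frozenset[str] = frozenset()
    soma_section: int | None = None
    mirror_of: str | None = None

    def spans(self, section: int) -> bool:
        return self.section_range[0] <= section < self.section_range[1]

    def local(self, section: int) -> int:
        if not self.spans(section):
            raise IndexError(
                f"section {section} outside {self.id} range "
                f"{self.section_range}"
            )
        return section - self.section_range[0]

    def centroid(self, section: int) -> np.ndarray:
        return self.path[self.local(section)]

    def area(self, section: int) -> float:
        return float(self.area_per_section[self.local(section)])


@dataclass
class DCVTrack:
    """Per-section DCV counts over one neurite's section range."""

    neurite_id: str
    section_range: tuple[int, int]
    counts: np.ndarray  # non-negative ints, len == range span

    def count(self, section: int) -> int:
        s0, s1 = self.section_range
        if not s0 <= section < s1:
            raise IndexError(
                f"section {section} outside DCV track range {self.section_range}"
            )
        return int(self.counts[section - s0])


@dataclass
class LabelingDesign:
    """Sparse assignment of antibodies to runs of consecutive sections.

    ``assignments`` is a list of (antibody, (start, end)) with half-open,
    pairwise-disjoint section ranges. ``style`` tags the geometry:
    'paired-grids' (each antibody on >= 2 runs ~spacing sections apart) or
    'whole-body' (short 1–6-section runs scattered over a long series).
    """

    assignments: list[tuple[str, tuple[int, int]]]
    style: str = "paired-grids"

    def __post_init__(self) -> None:
        self.assignments = [
            (a, (int(r[0]), int(r[1]))) for a, r in self.assignments
        ]

    def validate(self, n_sections: int) -> None:
        seen: set[int] = set()
        for a, (s0, s1) in self.assignments:
            if not (0 <= s0 < s1 <= n_sections):
                raise ValueError(
                    f"run {a}:[{s0},{s1}) outside stack of {n_sections} sections"
                )
            r = set(range(s0, s1))
            if seen & r:
                raise ValueError(f"run {a}:[{s0},{s1}) overlaps another run")
            seen |= r

    @property
    def antibodies(self) -> list[str]:
        out: list[str] = []
        for a, _ in self.assignments:
            if a not in out:
                out.append(a)
        return out

    def runs_for(self, antibody: str) -> list[tuple[int, int]]:
        return [r for a, r in self.assignments if a == antibody]

    def labeled_sections(self, antibody: str | None = None) -> list[int]:
        secs: list[int] = []
        for a, (s0, s1) in self.assignments:
            if antibody is None or a == antibody:
                secs.extend(range(s0, s1))
        return sorted(secs)

    def run_of(self, antibody: str, section: int) -> int:
        """Index (within this antibody's runs) of the run containing section."""
        for i, (s0, s1) in enumerate(self.runs_for(antibody)):
            if s0 <= section < s1:
                return i
        raise KeyError(f"section {section} not in any {antibody} run")

    def n_layers_per_antibody(self) -> dict[str, int]:
        return {a: len(self.labeled_sections(a)) for a in self.antibodies}


@dataclass
class SynapseRecord:
    """One presynaptic site with sampled vesicle diameters."""

    id: str
    pre_neurite_id: str
    post_neurite_id: str
    section_index: int
    side_of_post: str              # 'left' | 'right'
    vesicle_diameters_nm: np.ndarray
    vesicle_class_truth: str       # 'peptidergic' | 'classical'


@dataclass
class SyntheticDataset:
    """Ground-truth neurites + DCV tracks + design + gold counts + synapses."""

    config: SimConfig
    neurites: list[Neurite]
    dcv_tracks: dict[str, DCVTrack]
    design: LabelingDesign
    # gold[(antibody, section)][neurite_id] -> int; only cells where the
    # neurite intersects the labeled section exist (absent != 0).
    gold: dict[tuple[str, int], dict[str, int]]
    synapses: list[SynapseRecord]

    def neurite(self, neurite_id: str) -> Neurite:
        for n in self.neurites:
            if n.id == neurite_id:
                return n
        raise KeyError(neurite_id)

    def to_json(self) -> str:
        doc = {
            "config": self.config.to_dict(),
            "neurites": [
                {
                    **asdict(n),
                    "path": np.asarray(n.path).tolist(),
                    "area_per_section": np.asarray(n.area_per_section).tolist(),
                    "true_peptides": sorted(n.true_peptides),
                }
                for n in self.neurites
            ],
            "dcv_tracks": [
                {
                    "neurite_id": t.neurite_id,
                    "section_range": list(t.section_range),
                    "counts": np.asarray(t.counts).tolist(),
                }
                for t in self.dcv_tracks.values()
            ],
            "design": {
                "style": self.design.style,
                "assignments": [
                    [a, list(r)] for a, r in self.design.assignments
                ],
            },
            "gold": [
                [a, s, nid, c]
                for (a, s), row in sorted(self.gold.items())
                for nid, c in sorted(row.items())
            ],
            "synapses": [
                {
                    **asdict(sy),
                    "vesicle_diameters_nm":
                        np.asarray(sy.vesicle_diameters_nm).tolist(),
                }
                for sy in self.synapses
            ],
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticDataset":
        doc = json.loads(text)
        cfg = SimConfig.from_dict(doc["config"])
        neurites = [
            Neurite(
                id=n["id"], side=n["side"],
                section_range=tuple(n["section_range"]),
                path=np.asarray(n["path"], float),
                area_per_section=np.asarray(n["area_per_section"], float),
                true_peptides=frozenset(n["true_peptides"]),
                soma_section=n.get("soma_section"),
                mirror_of=n.get("mirror_of"),
            )
            for n in doc["neurites"]
        ]
        tracks = {
            t["neurite_id"]: DCVTrack(
                t["neurite_id"], tuple(t["section_range"]),
                np.asarray(t["counts"], int),
            )
            for t in doc["dcv_tracks"]
        }
        design = LabelingDesign(
            [(a, tuple(r)) for a, r in doc["design"]["assignments"]],
            style=doc["design"]["style"],
        )
        gold: dict[tuple[str, int], dict[str, int]] = {}
        for a, s, nid, c in doc["gold"]:
            gold.setdefault((a, int(s)), {})[nid] = int(c)
        synapses = [
            SynapseRecord(
                id=sy["id"], pre_neurite_id=sy["pre_neurite_id"],
                post_neurite_id=sy["post_neurite_id"],
                section_index=sy["section_index"],
                side_of_post=sy["side_of_post"],
                vesicle_diameters_nm=np.asarray(
                    sy["vesicle_diameters_nm"], float),
                vesicle_class_truth=sy["vesicle_class_truth"],
            )
            for sy in doc["synapses"]
        ]
        return cls(cfg, neurites, tracks, design, gold, synapses)


# ---------------------------------------------------------------------------
# neurite geometry

def generate_neurites(config: SimConfig,
                      rng: np.random.Generator | None = None,
                      id_prefix: str = "n") -> list[Neurite]:
    """Lay out neurite profiles crossing the whole stack.

    With ``config.bilateral`` neurites come in mirrored pairs: partner
    centroids are (-x, y) of each other at every section (before the shared
    per-pair jitter, which is mirrored too, so symmetry is exact).
    """
    rng = rng if rng is not None else config.rng("neurites")
    n = config.n_neurites
    neurites: list[Neurite] = []
    if n == 0:
        return neurites

    n_pairs = n // 2 if config.bilateral else n
    peptide_names = list(config.antibody_panel)

    k = 1
    for p in range(n_pairs):
        # base position on the right half of the cross-section (um)
        x0 = rng.uniform(0.8, 15.0)
        y0 = rng.uniform(0.0, 10.0)
        steps = rng.normal(0.0, config.position_jitter_um,
                           size=(config.n_sections, 2))
        path_r = np.cumsum(steps, axis=0) + [x0, y0]
        area = float(np.exp(rng.normal(np.log(0.25), 0.4)))
        areas = np.full(config.n_sections, area)

        peptides: frozenset[str] = frozenset()
        if rng.uniform() < config.peptidergic_fraction and peptide_names:
            chosen = [rng.choice(peptide_names)]
            if rng.uniform() < config.coexpression_prob and len(peptide_names) > 1:
                second = rng.choice([q for q in peptide_names if q != chosen[0]])
                chosen.append(second)
            peptides = frozenset(str(c) for c in chosen)

        rid = f"{id_prefix}{k}"
        neurites.append(Neurite(
            id=rid, side="right",
            section_range=(0, config.n_sections),
            path=path_r, area_per_section=areas.copy(),
            true_peptides=peptides,
        ))
        k += 1
        if config.bilateral:
            lid = f"{id_prefix}{k}"
            path_l = path_r.copy()
            path_l[:, 0] *= -1.0
            neurites.append(Neurite(
                id=lid, side="left",
                section_range=(0, config.n_sections),
                path=path_l, area_per_section=areas.copy(),
                true_peptides=peptides, mirror_of=rid,
            ))
            neurites[-2].mirror_of = lid
            k += 1
    return neurites


# ---------------------------------------------------------------------------
# DCV occupancy

def sample_dcv_counts(neurite: Neurite, config: SimConfig,
                      rng: np.random.Generator) -> DCVTrack:
    """Bursty per-section DCV counts along one neurite.

    A two-state (off/on) Markov chain runs over the neurite's sections:
    P(off->on) = ``dcv_on_rate``, P(on->off) = ``dcv_off_rate``. The initial
    state is drawn from the stationary law. In 'on' sections the count is
    Poisson(``dcv_mean``); 'off' sections have exactly 0, producing the
    zero-runs seen in real neurites.
    """
    s0, s1 = neurite.section_range
    span = s1 - s0
    if span <= 0:
        raise ValueError(f"neurite {neurite.id} has an empty section range")
    p_on, p_off = config.dcv_on_rate, config.dcv_off_rate
    state = rng.uniform() < config.dcv_stationary_on_fraction
    u = rng.uniform(size=span)
    states = np.empty(span, dtype=bool)
    for i in range(span):
        states[i] = state
        state = (u[i] < p_on) if not state else (u[i] >= p_off)
    counts = np.zeros(span, dtype=np.int64)
    n_on = int(states.sum())
    if n_on:
        counts[states] = rng.poisson(config.dcv_mean, size=n_on)
    return DCVTrack(neurite.id, (s0, s1), counts)


# ---------------------------------------------------------------------------
# labeling designs

def make_paired_grid_design(config: SimConfig,
                            runs_per_antibody: int = 2,
                            run_length_range: tuple[int, int] = (4, 6),
                            spacing: int = 50,
                            rng: np.random.Generator | None = None,
                            ) -> LabelingDesign:
    """Paired-grids design: each antibody on ``runs_per_antibody`` runs of
    consecutive sections, successive runs ~``spacing`` sections apart.

    Runs of the same block (one per antibody) are laid back-to-back; blocks
    are offset so each antibody's run starts differ by about ``spacing``.
    """
    rng = rng if rng is not None else config.rng("design")
    lo, hi = run_length_range
    if not (1 <= lo <= hi):
        raise ConfigurationError("invalid run_length_range")
    lengths = rng.integers(lo, hi + 1,
                           size=(runs_per_antibody, len(config.antibody_panel)))
    assignments: list[tuple[str, tuple[int, int]]] = []
    block_starts: list[int] = []
    cursor = 0
    for b in range(runs_per_antibody):
        if b > 0:
            cursor = max(cursor, block_starts[b - 1] + spacing)
        block_starts.append(cursor)
        for j, ab in enumerate(config.antibody_panel):
            L = int(lengths[b, j])
            assignments.append((ab, (cursor, cursor + L)))
            cursor += L
    design = LabelingDesign(sorted(assignments, key=lambda t: t[1][0]),
                            style="paired-grids")
    design.validate(config.n_sections)
    return design


def make_whole_body_design(config: SimConfig,
                           runs_per_antibody: int = 2,
                           run_length_range: tuple[int, int] = (1, 6),
                           rng: np.random.Generator | None = None,
                           ) -> LabelingDesign:
    """Whole-body design: short 1–6-section runs scattered over a long
    series, >= 2 runs per antibody separated by up to ~1000 sections."""
    rng = rng if rng is not None else config.rng("design")
    lo, hi = run_length_range
    n_runs = runs_per_antibody * len(config.antibody_panel)
    lengths = rng.integers(lo, hi + 1, size=n_runs)
    total = int(lengths.sum())
    if total > config.n_sections:
        raise ConfigurationError(
            "stack too short for the requested whole-body design"
        )
    # place runs at sorted random, collision-free starts
    gaps = rng.multinomial(config.n_sections - total,
                           np.ones(n_runs + 1) / (n_runs + 1))
    abs_order = list(config.antibody_panel) * runs_per_antibody
    rng.shuffle(abs_order)
    assignments = []
    cursor = 0
    for g, L, ab in zip(gaps[:-1], lengths, abs_order):
        cursor += int(g)
        assignments.append((ab, (cursor, cursor + int(L))))
        cursor += int(L)
    design = LabelingDesign(assignments, style="whole-body")
    design.validate(config.n_sections)
    return design


# ---------------------------------------------------------------------------
# gold deposition

def deposit_gold(neurites: Sequence[Neurite],
                 dcv_tracks: dict[str, DCVTrack],
                 design: LabelingDesign,
                 config: SimConfig,
                 rng: np.random.Generator,
                 ) -> dict[tuple[str, int], dict[str, int]]:
    """Thinned-Poisson gold deposition on labeled sections.

    For antibody ``a`` on section ``s`` and neurite ``i`` spanning ``s``::

        raw   ~ Poisson(alpha * D(i, s) * max_p S[a, p] + lambda_bg * A_i(s))
        count ~ Binomial(raw, p_enh)

    where D is the DCV count, S the recognition matrix over the neurite's
    expressed peptides, A the profile area, and p_enh the silver-enhancement
    probability. Counts exist only for (labeled section x intersecting
    neurite) cells; elsewhere they are absent, not zero.
    """
    design.validate(config.n_sections)
    for n in neurites:
        if n.id not in dcv_tracks:
            raise ValueError(f"missing DCV track for neurite {n.id}")
    alpha = config.gold_per_dcv
    lam_bg = config.background_rate
    p_enh = config.enhancement_prob
    gold: dict[tuple[str, int], dict[str, int]] = {}
    for ab, (s0, s1) in design.assignments:
        for s in range(s0, s1):
            row: dict[str, int] = {}
            for n in neurites:
                if not n.spans(s):
                    continue
                recog = max(
                    (config.recognition(ab, p) for p in n.true_peptides),
                    default=0.0,
                )
                rate = alpha * dcv_tracks[n.id].count(s) * recog \
                    + lam_bg * n.area(s)
                raw = int(rng.poisson(rate))
                row[n.id] = int(rng.binomial(raw, p_enh)) if raw else 0
            gold[(ab, s)] = row
    return gold


# ---------------------------------------------------------------------------
# vesicle diameters and synapses

def sample_dcv_diameters(n: int,
                         rng: np.random.Generator,
                         mean_nm: float = 63.0,
                         sd_nm: float = 8.4) -> np.ndarray:
    """Dense-core vesicle diameters: normal(mean, sd) truncated at 0."""
    a = (0.0 - mean_nm) / sd_nm
    return stats.truncnorm.rvs(a, np.inf, loc=mean_nm, scale=sd_nm,
                               size=n, random_state=rng)


def sample_clear_diameters(n: int,
                           rng: np.random.Generator,
                           mean_nm: float = 35.0,
                           sd_nm: float = 5.0) -> np.ndarray:
    """Clear synaptic-vesicle diameters: smaller truncated normal."""
    a = (0.0 - mean_nm) / sd_nm
    return stats.truncnorm.rvs(a, np.inf, loc=mean_nm, scale=sd_nm,
                               size=n, random_state=rng)


def generate_synapses(neurites: Sequence[Neurite],
                      config: SimConfig,
                      rng: np.random.Generator,
                      n_synapses: int = 0,
                      vesicles_per_synapse: int = 10,
                      ) -> list[SynapseRecord]:
    """Random presynaptic sites between distinct neurites.

    Peptidergic neurites (non-empty ``true_peptides``) form purely
    dense-core-vesicle synapses; others form classical clear-vesicle
    synapses. ``side_of_post`` records the post target's side of the x=0
    midline at the synapse section.
    """
    if n_synapses == 0 or len(neurites) < 2:
        return []
    out: list[SynapseRecord] = []
    for i in range(n_synapses):
        pre, post = rng.choice(len(neurites), size=2, replace=False)
        pre_n, post_n = neurites[pre], neurites[post]
        lo = max(pre_n.section_range[0], post_n.section_range[0])
        hi = min(pre_n.section_range[1], post_n.section_range[1])
        if hi <= lo:
            continue
        s = int(rng.integers(lo, hi))
        if pre_n.true_peptides:
            cls = "peptidergic"
            d = sample_dcv_diameters(vesicles_per_synapse, rng,
                                     config.vesicle_diam_mean_nm,
                                     config.vesicle_diam_sd_nm)
        else:
            cls = "classical"
            d = sample_clear_diameters(vesicles_per_synapse, rng,
                                       config.clear_diam_mean_nm,
                                       config.clear_diam_sd_nm)
        side = "left" if post_n.centroid(s)[0] < 0 else "right"
        out.append(SynapseRecord(
            id=f"syn{i}", pre_neurite_id=pre_n.id, post_neurite_id=post_n.id,
            section_index=s, side_of_post=side,
            vesicle_diameters_nm=d, vesicle_class_truth=cls,
        ))
    return out


# ---------------------------------------------------------------------------
# top-level composition

def generate_dataset(config: SimConfig,
                     design: LabelingDesign | None = None,
                     n_synapses: int = 0) -> SyntheticDataset:
    """Compose a full synthetic experiment, reproducible from the seed."""
    config.validate()
    neurites = generate_neurites(config, config.rng("neurites"))
    tracks = {
        n.id: sample_dcv_counts(n, config, config.rng("dcv", n.id))
        for n in neurites
    }
    if design is None:
        design = make_paired_grid_design(config)
    design.validate(config.n_sections)
    gold = deposit_gold(neurites, tracks, design, config, config.rng("gold"))
    synapses = generate_synapses(neurites, config, config.rng("synapses"),
                                 n_synapses=n_synapses)
    return SyntheticDataset(config, neurites, tracks, design, gold, synapses)


# ---------------------------------------------------------------------------
# synthetic image stacks for template building

@dataclass
class ImageStack:
    """A voxel intensity grid with isotropic-ish spacing, axis order (z,y,x)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    frame: str = "native"
    stack_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("stack intensities must be finite")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be > 0")


@dataclass
class ImageStackSet:
    """Rendered stacks plus the ground truth they were deformed from."""

    stacks: list[ImageStack]
    ground_truth: np.ndarray
    true_affines: list[np.ndarray]     # 3x4 [A|t]: out-coord -> truth-coord
    true_displacements: list[np.ndarray]  # coarse control grids (gz,gy,gx,3)


def _blob_pattern(shape: tuple[int, int, int],
                  rng: np.random.Generator,
                  n_blobs: int = 10) -> np.ndarray:
    """Smooth blobby intensity pattern standing in for a stained body scan."""
    gt = np.zeros(shape)
    zz, yy, xx = np.indices(shape).astype(float)
    for _ in range(n_blobs):
        c = rng.uniform([0.2 * shape[0], 0.2 * shape[1], 0.2 * shape[2]],
                        [0.8 * shape[0], 0.8 * shape[1], 0.8 * shape[2]])
        lo = np.array([1.0, 2.0, 2.0])
        hi = np.maximum(lo + 0.5, [0.2 * shape[0], 0.25 * shape[1],
                                   0.25 * shape[2]])
        s = rng.uniform(lo, hi)
        amp = rng.uniform(0.5, 1.0)
        gt += amp * np.exp(-(((zz - c[0]) / s[0]) ** 2
                             + ((yy - c[1]) / s[1]) ** 2
                             + ((xx - c[2]) / s[2]) ** 2) / 2.0)
    return gt / gt.max()


def _upsample_displacement(disp: np.ndarray,
                           shape: tuple[int, int, int]) -> np.ndarray:
    """Trilinear upsampling of a coarse (gz,gy,gx,3) control grid to a dense
    per-voxel displacement field of ``shape + (3,)``."""
    gz, gy, gx, _ = disp.shape
    dense = np.empty(shape + (3,))
    coords = np.indices(shape).astype(float)
    scale = [(g - 1) / max(s - 1, 1) for g, s in zip((gz, gy, gx), shape)]
    sample = np.array([coords[d] * scale[d] for d in range(3)])
    for c in range(3):
        dense[..., c] = ndimage.map_coordinates(
            disp[..., c], sample.reshape(3, -1), order=1, mode="nearest"
        ).reshape(shape)
    return dense


def warp_volume(vol: np.ndarray,
                affine: np.ndarray,
                displacement: np.ndarray | None = None) -> np.ndarray:
    """Resample ``vol`` with output->input map x_in = A @ x_out + t (+ disp)."""
    A, t = affine[:, :3], affine[:, 3]
    if displacement is None:
        return ndimage.affine_transform(vol, A, offset=t, order=1,
                                        mode="constant", cval=0.0)
    shape = vol.shape
    coords = np.indices(shape).astype(float).reshape(3, -1)
    mapped = A @ coords + t[:, None]
    dense = _upsample_displacement(displacement, shape)
    mapped = mapped + dense.reshape(-1, 3).T
    return ndimage.map_coordinates(vol, mapped, order=1,
                                   mode="constant", cval=0.0).reshape(shape)


def render_if_stacks(n_stacks: int,
                     config: SimConfig | None = None,
                     rng: np.random.Generator | None = None,
                     shape: tuple[int, int, int] = (8, 64, 64),
                     rotation_sd_deg: float = 4.0,
                     scale_sd: float = 0.03,
                     translation_sd_vox: float = 1.5,
                     deform_amp_vox: float = 1.0,
                     noise_sd: float = 0.02,
                     ctrl_grid: tuple[int, int, int] = (2, 4, 4),
                     ) -> ImageStackSet:
    """Render a cohort of stacks as deformed noisy copies of one pattern.

    Emulates whole-body confocal scans of sibling specimens: a shared
    ground-truth intensity pattern viewed through per-specimen affine
    differences (orientation, scale, offset), a smooth low-frequency
    deformation, and imaging noise. Ground-truth transforms are retained so
    registration can be scored against them.
    """
    if n_stacks < 1:
        raise ValueError("n_stacks must be >= 1")
    if rng is None:
        rng = (config.rng("if_stacks") if config is not None
               else np.random.default_rng(0))
    gt = _blob_pattern(shape, rng)
    # put the pattern's center of mass at the grid center so the centered
    # template frame coincides with the ground-truth frame
    com = np.array(ndimage.center_of_mass(gt))
    center = (np.asarray(shape, float) - 1.0) / 2.0
    gt = ndimage.shift(gt, center - com, order=1, mode="constant", cval=0.0)
    stacks: list[ImageStack] = []
    affines: list[np.ndarray] = []
    disps: list[np.ndarray] = []
    for i in range(n_stacks):
        ang = np.deg2rad(rng.normal(0.0, rotation_sd_deg))
        c, s = np.cos(ang), np.sin(ang)
        # in-plane (y,x) rotation, mild anisotropic scale
        R = np.array([[1.0, 0.0, 0.0],
                      [0.0, c, -s],
                      [0.0, s, c]])
        S = np.diag(1.0 + rng.normal(0.0, scale_sd, size=3))
        A = R @ S
        t_shift = rng.normal(0.0, translation_sd_vox, size=3)
        t_shift[0] *= 0.3  # thin z axis: keep offsets inside the volume
        t = center - A @ center + t_shift
        disp = rng.normal(0.0, deform_amp_vox, size=ctrl_grid + (3,))
        disp[..., 0] *= 0.3
        img = warp_volume(gt, np.c_[A, t], disp)
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=shape)
        stacks.append(ImageStack(img, stack_id=f"stack{i:02d}"))
        affines.append(np.c_[A, t])
        disps.append(disp)
    return ImageStackSet(stacks, gt, affines, disps)
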