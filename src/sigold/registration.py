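"""Iterative unbiased average-template construction.

Implements the groupwise registration scheme used to build reference
templates from cohorts of whole-body scans: orient and center every stack,
average, then repeat {register all original oriented stacks to the current
average, keep the k most similar, average those} with progressively richer
transform models (affine, then affine + deformable). Because each cycle
re-registers the *original* stacks and averages the best-matching subset,
no single specimen dominates the final template.

Similarity is normalized cross-correlation (NCC). The deformable model is
a coarse control-point displacement grid with trilinear interpolation,
optimized — like the affine part — by deterministic greedy coordinate
descent, which keeps the desk-scale build cheap and exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .synthetic import ImageStack, warp_volume, _upsample_displacement

__all__ = [
    "TransformModel", "SimilarityScore", "TemplateResult",
    "ncc", "orient_and_center", "register", "build_template",
]


# ---------------------------------------------------------------------------
# similarity

def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation in [-1, 1]; ncc(a, a) == 1."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.shape != b.shape:
        raise ValueError("volumes must share a voxel grid")
    da, db = a - a.mean(), b - b.mean()
    na, nb = np.linalg.norm(da), np.linalg.norm(db)
    if na == 0.0 or nb == 0.0:
        return 1.0 if np.allclose(a, b) else 0.0
    return float(np.clip(da @ db / (na * nb), -1.0, 1.0))


@dataclass
class SimilarityScore:
    value: float
    metric: str = "ncc"


# ---------------------------------------------------------------------------
# transform model

@dataclass
class TransformModel:
    """Spatial transform: affine (output -> input map) plus an optional
    coarse control-point displacement grid for the deformable part."""

    kind: str = "affine"            # 'rigid' | 'affine' | 'affine+deformable'
    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))
    offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    displacement: np.ndarray | None = None   # (gz, gy, gx, 3) or None
    converged: bool = True

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        self.offset = np.asarray(self.offset, float)
        if np.abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("affine part must be invertible")

    @property
    def affine(self) -> np.ndarray:
        return np.c_[self.matrix, self.offset]

    def apply(self, vol: np.ndarray) -> np.ndarray:
        return warp_volume(vol, self.affine, self.displacement)

    def max_displacement(self, shape: tuple[int, int, int]) -> float:
        """Largest voxel displacement this transform induces on the grid
        corners (used to compare recovered against true transforms)."""
        corners = np.array([
            [z, y, x]
            for z in (0, shape[0] - 1)
            for y in (0, shape[1] - 1)
            for x in (0, shape[2] - 1)
        ], float).T
        mapped = self.matrix @ corners + self.offset[:, None]
        d = np.linalg.norm(mapped - corners, axis=0).max()
        if self.displacement is not None:
            d += float(np.linalg.norm(self.displacement, axis=-1).max())
        return float(d)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "matrix": self.matrix.tolist(),
            "offset": self.offset.tolist(),
            "displacement": (None if self.displacement is None
                             else self.displacement.tolist()),
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransformModel":
        return cls(
            kind=d["kind"],
            matrix=np.asarray(d["matrix"], float),
            offset=np.asarray(d["offset"], float),
            displacement=(None if d.get("displacement") is None
                          else np.asarray(d["displacement"], float)),
            converged=bool(d.get("converged", True)),
        )


# ---------------------------------------------------------------------------
# orientation / centering

def orient_and_center(stacks: Sequence[ImageStack],
                      orient: bool = False) -> list[ImageStack]:
    """Translate each stack so its intensity center of mass sits at the
    grid center; optionally align the principal intensity axis to y.

    Raises on an all-zero stack (center of mass undefined).
    """
    if len(stacks) < 1:
        raise ValueError("need at least one stack")
    out: list[ImageStack] = []
    for st in stacks:
        vol = np.asarray(st.data, float)
        total = vol.sum()
        if total <= 0:
            raise ValueError(
                f"stack {st.stack_id or '?'} has no intensity mass")
        com = np.array(ndimage.center_of_mass(vol))
        center = (np.asarray(vol.shape, float) - 1.0) / 2.0
        shifted = ndimage.shift(vol, center - com, order=1,
                                mode="constant", cval=0.0)
        if orient:
            zz, yy, xx = np.indices(vol.shape).astype(float)
            w = shifted / max(shifted.sum(), 1e-12)
            yc = (yy * w).sum()
            xc = (xx * w).sum()
            cyy = ((yy - yc) ** 2 * w).sum()
            cxx = ((xx - xc) ** 2 * w).sum()
            cxy = ((yy - yc) * (xx - xc) * w).sum()
            theta = 0.5 * np.arctan2(2 * cxy, cyy - cxx)
            shifted = ndimage.rotate(shifted, np.rad2deg(theta),
                                     axes=(1, 2), reshape=False, order=1,
                                     mode="constant", cval=0.0)
        out.append(ImageStack(shifted, spacing=st.spacing,
                              frame="centered", stack_id=st.stack_id))
    return out


# ---------------------------------------------------------------------------
# optimization

def _coordinate_descent(f: Callable[[np.ndarray], float],
                        x0: np.ndarray,
                        steps: np.ndarray,
                        n_sweeps: int,
                        shrink: float = 0.5,
                        bounds: tuple[np.ndarray, np.ndarray] | None = None,
                        ) -> tuple[np.ndarray, float, int]:
    """Greedy per-coordinate line search; deterministic, never accepts a
    worse value. Returns (x, f(x), number of evaluations)."""
    x = np.asarray(x0, float).copy()
    best = f(x)
    n_eval = 1
    steps = np.asarray(steps, float).copy()
    for _ in range(n_sweeps):
        improved = False
        for i in range(x.size):
            for sign in (+1.0, -1.0):
                trial = x.copy()
                trial[i] += sign * steps[i]
                if bounds is not None:
                    trial = np.clip(trial, bounds[0], bounds[1])
                v = f(trial)
                n_eval += 1
                if v < best - 1e-12:
                    x, best = trial, v
                    improved = True
                    break
        if not improved:
            steps *= shrink
    return x, best, n_eval


def _upsample_operator(ctrl_grid: tuple[int, int, int],
                       shape: tuple[int, int, int]):
    """Sparse (n_voxels x n_ctrl) trilinear interpolation operator matching
    the dense upsampling used by ``warp_volume``."""
    from scipy import sparse
    coords = np.indices(shape).astype(float).reshape(3, -1)
    n_vox = coords.shape[1]
    scale = [(g - 1) / max(s - 1, 1) for g, s in zip(ctrl_grid, shape)]
    g = np.array([coords[d] * scale[d] for d in range(3)])
    g = np.clip(g, 0, [[c - 1] for c in ctrl_grid])
    f = np.floor(g).astype(int)
    f = np.minimum(f, np.array([[c - 2 if c > 1 else 0] for c in ctrl_grid]))
    w = g - f
    rows, cols, vals = [], [], []
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                iz = np.minimum(f[0] + dz, ctrl_grid[0] - 1)
                iy = np.minimum(f[1] + dy, ctrl_grid[1] - 1)
                ix = np.minimum(f[2] + dx, ctrl_grid[2] - 1)
                wz = w[0] if dz else 1 - w[0]
                wy = w[1] if dy else 1 - w[1]
                wx = w[2] if dx else 1 - w[2]
                weight = wz * wy * wx
                idx = (iz * ctrl_grid[1] + iy) * ctrl_grid[2] + ix
                rows.append(np.arange(n_vox))
                cols.append(idx)
                vals.append(weight)
    W = sparse.coo_matrix(
        (np.concatenate(vals),
         (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_vox, int(np.prod(ctrl_grid)))).tocsr()
    return W


def _euler_matrix(angles: np.ndarray) -> np.ndarray:
    az, ay, ax = angles
    cz, sz = np.cos(az), np.sin(az)
    cy, sy = np.cos(ay), np.sin(ay)
    cx, sx = np.cos(ax), np.sin(ax)
    rz = np.array([[1, 0, 0], [0, cz, -sz], [0, sz, cz]])   # about z (in-plane)
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rx = np.array([[cx, -sx, 0], [sx, cx, 0], [0, 0, 1]])
    return rz @ ry @ rx


def register(moving: ImageStack | np.ndarray,
             reference: ImageStack | np.ndarray,
             model_kind: str = "affine",
             init: TransformModel | None = None,
             ctrl_grid: tuple[int, int, int] = (2, 3, 3),
             n_sweeps_affine: int = 6,
             n_sweeps_deform: int = 3,
             max_disp_frac: float = 0.15,
             ) -> tuple[TransformModel, SimilarityScore]:
    """Register ``moving`` onto ``reference`` maximizing NCC.

    Transforms are centered: rotation/scale act about the grid center. The
    optimizer is greedy coordinate descent (multi-scale step shrinking); it
    never returns a transform scoring worse than the initial one. If the
    final score does not reach the initial score plus a minimal gain while
    the model has room to move, the returned model carries
    ``converged=False`` rather than failing.
    """
    mov = np.asarray(moving.data if isinstance(moving, ImageStack)
                     else moving, float)
    ref = np.asarray(reference.data if isinstance(reference, ImageStack)
                     else reference, float)
    if mov.shape != ref.shape:
        raise ValueError("moving and reference must share a voxel grid")
    if model_kind not in ("rigid", "affine", "affine+deformable"):
        raise ValueError(f"unknown model kind {model_kind!r}")
    center = (np.asarray(mov.shape, float) - 1.0) / 2.0

    def affine_cost(p: np.ndarray) -> float:
        if model_kind == "rigid":
            A = _euler_matrix(p[:3])
            t = center - A @ center + p[3:6]
        else:
            A = np.eye(3) + p[:9].reshape(3, 3)
            t = center - A @ center + p[9:12]
        try:
            warped = warp_volume(mov, np.c_[A, t])
        except Exception:
            return 2.0
        return -ncc(warped, ref)

    if model_kind == "rigid":
        p0 = np.zeros(6)
        steps = np.array([0.05] * 3 + [1.0] * 3)
    else:
        p0 = np.zeros(12)
        if init is not None:
            A0 = init.matrix
            t0 = init.offset - (center - A0 @ center)
            p0 = np.r_[(A0 - np.eye(3)).ravel(), t0]
        steps = np.array([0.02] * 9 + [1.0] * 3)

    p, best, _ = _coordinate_descent(affine_cost, p0, steps,
                                     n_sweeps=n_sweeps_affine)
    if model_kind == "rigid":
        A = _euler_matrix(p[:3])
        t = center - A @ center + p[3:6]
    else:
        A = np.eye(3) + p[:9].reshape(3, 3)
        t = center - A @ center + p[9:12]

    disp = None
    if model_kind == "affine+deformable":
        if init is not None and init.displacement is not None \
                and init.displacement.shape == tuple(ctrl_grid) + (3,):
            d0 = init.displacement.ravel().copy()
        else:
            d0 = np.zeros(int(np.prod(ctrl_grid)) * 3)
        max_disp = max_disp_frac * max(mov.shape)

        # precompute the affine-mapped base coordinates and the trilinear
        # control-grid upsampling operator (sparse) so each trial costs one
        # interpolation pass
        coords = np.indices(mov.shape).astype(float).reshape(3, -1)
        base = A @ coords + t[:, None]
        W = _upsample_operator(tuple(ctrl_grid), mov.shape)
        ref_flat = ref.ravel()
        n_ctrl = int(np.prod(ctrl_grid))

        def deform_cost(d: np.ndarray) -> float:
            mapped = base + (W @ d.reshape(n_ctrl, 3)).T
            vals = ndimage.map_coordinates(mov, mapped, order=1,
                                           mode="constant", cval=0.0)
            return -ncc(vals, ref_flat)

        d, best, _ = _coordinate_descent(
            deform_cost, d0, np.full(d0.size, 0.5),
            n_sweeps=n_sweeps_deform,
            bounds=(np.full(d0.size, -max_disp), np.full(d0.size, max_disp)),
        )
        disp = d.reshape(tuple(ctrl_grid) + (3,))

    model = TransformModel(kind=model_kind, matrix=A, offset=t,
                           displacement=disp, converged=True)
    score = -best
    if score < 0.2:  # hopeless alignment: flag, never fail silently
        model.converged = False
    return model, SimilarityScore(score)


# ---------------------------------------------------------------------------
# template building

@dataclass
class TemplateResult:
    """Final average template plus per-stage provenance."""

    template: np.ndarray
    stage_kinds: list[str]
    transforms: list[list[TransformModel]]   # per stage, per stack (canonical)
    scores: list[np.ndarray]                 # per stage, per stack
    contributors: list[list[str]]            # stack ids averaged per stage
    stack_ids: list[str]

    @property
    def mean_scores(self) -> list[float]:
        return [float(s.mean()) for s in self.scores]


def build_template(stacks: Sequence[ImageStack],
                   k_keep: int = 24,
                   stages: Sequence[str] = (
                       "affine", "affine+deformable", "affine+deformable"),
                   orient: bool = False,
                   **register_kw) -> TemplateResult:
    """Unbiased average template by iterative register-rank-average cycles.

    1. Orient and center all stacks; average them into a first template.
    2. For each stage: register every *original oriented* stack to the
       current template (warm-started from the previous stage's transform),
       rank by NCC, and average the ``k_keep`` best-matching warped stacks
       into the next template.

    Stacks are processed in canonical (stack-id) order, so the result is
    bit-for-bit independent of input ordering.
    """
    if k_keep > len(stacks):
        raise ValueError(
            f"k_keep={k_keep} exceeds the {len(stacks)}-stack cohort")
    if k_keep < 1:
        raise ValueError("k_keep must be >= 1")
    ordered = sorted(stacks, key=lambda s: (s.stack_id, id(s)))
    oriented = orient_and_center(ordered, orient=orient)
    ids = [s.stack_id for s in oriented]
    template = np.mean([s.data for s in oriented], axis=0)

    all_transforms: list[list[TransformModel]] = []
    all_scores: list[np.ndarray] = []
    contributors: list[list[str]] = []
    prev: list[TransformModel | None] = [None] * len(oriented)
    for kind in stages:
        models: list[TransformModel] = []
        scores = np.empty(len(oriented))
        for i, st in enumerate(oriented):
            model, score = register(st, template, model_kind=kind,
                                    init=prev[i], **register_kw)
            models.append(model)
            scores[i] = score.value
        # rank by similarity, tie-break on canonical index for determinism
        order = sorted(range(len(oriented)),
                       key=lambda i: (-scores[i], i))[:k_keep]
        order = sorted(order)  # canonical averaging order -> bitwise stable
        template = np.mean(
            [models[i].apply(oriented[i].data) for i in order], axis=0)
        all_transforms.append(models)
        all_scores.append(scores)
        contributors.append([ids[i] for i in order])
        prev = list(models)
    return TemplateResult(template, list(stages), all_transforms,
                          all_scores, contributors, ids)
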