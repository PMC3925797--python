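"""Biopsy core planning.

Two strategies are planned here:

* ``TRUS12`` — a systematic 12-core transrectal scheme placed purely by
  anatomy (left/right x base/mid/apex x medial/lateral), with trajectories
  fanning from an anus reference point toward nominal gland-fraction
  positions.  The planner never reads lesion positions — it is blinded to
  the pathology, as a clinical TRUS biopsy is.
* ``TARGETED_k`` (k = 1..5) — transperineal image-targeted cores constrained
  to a 5-mm brachytherapy template grid (urethra anchored at column D, row
  2.0).  Grid positions are chosen to maximise the summed target-intersection
  length of the k cores, each core's axial extent centred on its maximal
  chord through the target ("aim for the deepest part of the lesion").
  Because distinct grid positions sample disjoint needle lines, greedy
  selection of the k best positions attains the exhaustive-search optimum.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import BiopsyCore, Ellipsoid

__all__ = [
    "TrusSchemeSpec",
    "TemplateGrid",
    "BiopsyPlan",
    "default_trus_scheme",
    "plan_trus12",
    "eligible_targets",
    "plan_targeted",
    "targeted_strategy_label",
]

TRUS12 = "TRUS12"


def targeted_strategy_label(k: int) -> str:
    return f"TARGETED_{k}"


@dataclass(frozen=True)
class TrusSchemeSpec:
    """Anatomic parameterisation of the 12-core transrectal scheme.

    ``core_slots`` holds 12 (side, axial, lateral) placement fractions in
    units of the gland semi-axes: side in {-1, +1} (right/left), axial in
    [-1, 1] (apex..base), lateral in [0, 1] (medial..lateral extension).
    ``posterior_depth_frac`` sets how deep (toward anterior) the nominal
    sampling midpoint sits; ``jitter_sd_mm`` is the per-axis SD of the
    probe/insertion variability drawn per repetition.
    """

    core_slots: tuple = (
        # (side, axial_frac, lateral_frac): sextant + lateral extension
        (-1, 0.55, 0.35), (-1, 0.55, 0.70),
        (-1, 0.00, 0.35), (-1, 0.00, 0.70),
        (-1, -0.55, 0.35), (-1, -0.55, 0.70),
        (+1, 0.55, 0.35), (+1, 0.55, 0.70),
        (+1, 0.00, 0.35), (+1, 0.00, 0.70),
        (+1, -0.55, 0.35), (+1, -0.55, 0.70),
    )
    posterior_depth_frac: float = 0.45
    jitter_sd_mm: float = 2.0
    effective_length_mm: float = 17.0

    def __post_init__(self):
        if len(self.core_slots) != 12:
            raise ValueError("a TRUS scheme must define exactly 12 core slots")
        for side, ax, lat in self.core_slots:
            if side not in (-1, 1) or not -1 <= ax <= 1 or not 0 <= lat <= 1:
                raise ValueError(f"bad core slot {(side, ax, lat)}")


def default_trus_scheme() -> TrusSchemeSpec:
    return TrusSchemeSpec()


def _gland_frame(model):
    """(center, semi_axes) of the gland, for analytic or voxel models."""
    gland = getattr(model, "gland", None)
    if isinstance(gland, Ellipsoid):
        return gland.center, gland.semi_axes
    voxel = model.voxel
    idx = np.argwhere(voxel.gland_mask)
    if len(idx) == 0:
        raise ValueError("empty gland mask")
    # idx columns are (iz, iy, ix) -> world (x, y, z)
    world = voxel.origin + voxel.spacing * idx[:, ::-1]
    center = 0.5 * (world.min(axis=0) + world.max(axis=0))
    semi = 0.5 * (world.max(axis=0) - world.min(axis=0))
    return center, np.maximum(semi, voxel.spacing)


def plan_trus12(model, spec: TrusSchemeSpec | None = None,
                rng: np.random.Generator | None = None):
    """Plan a systematic 12-core TRUS biopsy from anatomy alone.

    Deterministic given the generator state.  Cores whose nominal position
    falls outside the gland are retained (the realised session flags gland
    misses); nothing about the pathology is consulted.
    """
    if spec is None:
        spec = default_trus_scheme()
    if rng is None:
        rng = np.random.default_rng(0)
    center, semi = _gland_frame(model)
    anus = np.asarray(model.anus_reference, float)
    cores = []
    for side, ax_frac, lat_frac in spec.core_slots:
        nominal = center + np.array(
            [
                side * lat_frac * semi[0],
                -spec.posterior_depth_frac * semi[1],
                ax_frac * semi[2],
            ]
        )
        target = nominal + rng.normal(0.0, spec.jitter_sd_mm, size=3)
        d = target - anus
        d /= np.linalg.norm(d)
        cores.append(
            BiopsyCore.aimed(anus, d, target, spec.effective_length_mm)
        )
    return BiopsyPlan(strategy=TRUS12, cores=tuple(cores), target_ids=())


@dataclass(frozen=True)
class TemplateGrid:
    """5-mm brachytherapy template with the urethra at column D, row 2.0.

    Columns are lettered (A, a, B, b, ... laterally, 2.5-mm half-steps on the
    physical template; here integer 5-mm columns suffice) and rows numbered;
    grid coordinate (i, j) maps to the template-plane position
    ``urethra_xy + spacing * (i - D_index, j - 2.0)``.  Needles travel along
    +z (parallel to the base-apex axis).
    """

    urethra_xy: tuple[float, float]
    spacing: float = 5.0
    urethra_col: float = 3.0  # index of column "D" (A=0, B=1, C=2, D=3)
    urethra_row: float = 2.0

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    def grid_to_xy(self, col: float, row: float) -> np.ndarray:
        return np.array(
            [
                self.urethra_xy[0] + self.spacing * (col - self.urethra_col),
                self.urethra_xy[1] + self.spacing * (row - self.urethra_row),
            ]
        )

    def xy_to_grid(self, x: float, y: float) -> tuple[float, float]:
        return (
            self.urethra_col + (x - self.urethra_xy[0]) / self.spacing,
            self.urethra_row + (y - self.urethra_xy[1]) / self.spacing,
        )

    def coordinate_label(self, col: int, row: float) -> str:
        letters = string.ascii_uppercase
        name = letters[col] if 0 <= col < 26 else f"C{col}"
        return f"{name}{row:.1f}"

    def lattice_in_box(self, x_lo, x_hi, y_lo, y_hi):
        """Integer grid coordinates whose positions fall in the box."""
        c_lo = int(np.ceil(self.urethra_col + (x_lo - self.urethra_xy[0]) / self.spacing))
        c_hi = int(np.floor(self.urethra_col + (x_hi - self.urethra_xy[0]) / self.spacing))
        r_lo = int(np.ceil(self.urethra_row + (y_lo - self.urethra_xy[1]) / self.spacing))
        r_hi = int(np.floor(self.urethra_row + (y_hi - self.urethra_xy[1]) / self.spacing))
        return [
            (c, r)
            for c in range(c_lo, c_hi + 1)
            for r in range(r_lo, r_hi + 1)
        ]


@dataclass(frozen=True)
class BiopsyPlan:
    strategy: str
    cores: tuple[BiopsyCore, ...]
    target_ids: tuple[str, ...]
    grid_coords: tuple = ()
    warnings: tuple[str, ...] = ()

    def __post_init__(self):
        if self.strategy == TRUS12 and len(self.cores) != 12:
            raise ValueError("TRUS12 plans must contain 12 cores")
        if self.strategy.startswith("TARGETED_"):
            k = int(self.strategy.split("_")[1])
            if len(self.cores) != k:
                raise ValueError(f"{self.strategy} plans must contain {k} cores")

    @property
    def n_cores(self) -> int:
        return len(self.cores)


def eligible_targets(model, threshold: float = 0.2) -> list[str]:
    """Lesion ids (true and false-positive) with volume >= threshold (ml),
    sorted by volume descending.  Boundary inclusive."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    pairs = [
        (l.volume_ml, l.id) for l in model.lesions if l.volume_ml >= threshold
    ]
    pairs.sort(key=lambda p: (-p[0], p[1]))
    return [pid for _, pid in pairs]


def _target_interval_fn(model, lesion_id: str):
    """Chord interval (z0, z1) along the +z needle line at (x, y), against
    the imaged target shape, plus a bounding box and centroid."""
    lesion = next(l for l in model.lesions if l.id == lesion_id)
    geom = getattr(lesion, "ellipsoid", None)
    if geom is not None:
        pts = geom.surface_points(130)
        box = (pts[:, 0].min(), pts[:, 0].max(), pts[:, 1].min(), pts[:, 1].max())

        def interval(x, y):
            return geom.line_interval(np.array([x, y, 0.0]), np.array([0.0, 0.0, 1.0]))

        return interval, box, geom.center[:2]
    # voxel-backed lesion: sample the mask column
    voxel = model.voxel
    mask = voxel.lesion_masks[lesion_id]
    idx = np.argwhere(mask)
    world = voxel.origin + voxel.spacing * idx[:, ::-1]
    box = (world[:, 0].min(), world[:, 0].max(), world[:, 1].min(), world[:, 1].max())
    centroid = world[:, :2].mean(axis=0)
    z_lo, z_hi = world[:, 2].min(), world[:, 2].max()
    step = voxel.spacing / 2.0

    def interval(x, y):
        z = np.arange(z_lo - voxel.spacing, z_hi + voxel.spacing + step, step)
        pts = np.column_stack([np.full_like(z, x), np.full_like(z, y), z])
        ii = np.round((pts - voxel.origin) / voxel.spacing).astype(int)
        nz, ny, nx = mask.shape
        ok = (
            (ii >= 0).all(axis=1)
            & (ii[:, 0] < nx) & (ii[:, 1] < ny) & (ii[:, 2] < nz)
        )
        inside = np.zeros(len(z), bool)
        inside[ok] = mask[ii[ok, 2], ii[ok, 1], ii[ok, 0]]
        if not inside.any():
            return None
        hit = z[inside]
        return float(hit.min() - step / 2), float(hit.max() + step / 2)

    return interval, box, centroid


def plan_targeted(
    model,
    k: int,
    grid: TemplateGrid | None = None,
    effective_length: float = 17.0,
    target_threshold: float = 0.2,
):
    """Plan k transperineal targeted cores on the template lattice.

    Cores are aimed at the largest eligible target (true or false-positive);
    positions are ranked by the (effective-length-clipped) chord through the
    imaged target, ties broken by in-plane distance to the target centroid
    then lexicographic grid order.  If fewer lattice positions intersect the
    target than k, the remaining cores are stacked on the best position and
    a warning is emitted.
    """
    if not 1 <= k <= 5:
        raise ValueError("k must be between 1 and 5")
    ids = eligible_targets(model, target_threshold)
    if not ids:
        raise ValueError("no eligible target (model reverts to TRUS-only analysis)")
    target_id = ids[0]
    if grid is None:
        grid = TemplateGrid(urethra_xy=tuple(model.urethra_xy))
    interval_at, (x_lo, x_hi, y_lo, y_hi), centroid = _target_interval_fn(
        model, target_id
    )
    pad = grid.spacing / 2.0
    candidates = []
    for col, row in grid.lattice_in_box(x_lo - pad, x_hi + pad, y_lo - pad, y_hi + pad):
        x, y = grid.grid_to_xy(col, row)
        iv = interval_at(x, y)
        if iv is None:
            continue
        chord = iv[1] - iv[0]
        score = min(chord, effective_length)
        dist2 = (x - centroid[0]) ** 2 + (y - centroid[1]) ** 2
        candidates.append((-score, dist2, col, row, x, y, iv))
    notes = []
    if not candidates:
        raise ValueError(
            f"no template lattice position intersects target {target_id!r}"
        )
    candidates.sort()
    chosen = candidates[:k]
    if len(chosen) < k:
        notes.append(
            f"only {len(chosen)} lattice positions intersect target "
            f"{target_id!r}; stacking remaining cores on the best position"
        )
        warnings.warn(notes[-1])
        chosen = chosen + [candidates[0]] * (k - len(chosen))
    cores, coords = [], []
    center, semi = _gland_frame(model)
    z_entry = center[2] - semi[2] - 20.0  # perineal side, beyond the apex
    for _, _, col, row, x, y, iv in chosen:
        z_mid = 0.5 * (iv[0] + iv[1])
        cores.append(
            BiopsyCore.aimed(
                np.array([x, y, z_entry]),
                np.array([0.0, 0.0, 1.0]),
                np.array([x, y, z_mid]),
                effective_length,
            )
        )
        coords.append((col, row))
    return BiopsyPlan(
        strategy=targeted_strategy_label(k),
        cores=tuple(cores),
        target_ids=(target_id,),
        grid_coords=tuple(coords),
        warnings=tuple(notes),
    )
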