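"""Needle-segment geometry: ellipsoids, biopsy cores and cancer core lengths.

A biopsy core is modelled as a zero-width line segment of fixed effective
(sampling-notch) length centred on the core midpoint.  The cancer length of a
core is the length of the segment's intersection with the *union* of the true
tumour foci — overlapping foci are never double counted.  Two computational
routes are provided and cross-checked in the test suite: an exact quadratic
chord computation for ellipsoidal lesions, and a dense point-sampling route
for voxelised models.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Ellipsoid",
    "BiopsyCore",
    "CoreResult",
    "chord_length_ellipsoid",
    "core_cancer_length",
    "segment_in_gland_length",
    "merge_interval_lengths",
]

_UNIT_TOL = 1e-9


def _as_vec3(x) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {v.shape}")
    return v


@dataclass(frozen=True)
class Ellipsoid:
    """A (possibly rotated) ellipsoid: world = center + rotation @ local.

    ``semi_axes`` are the local-frame semi-axis lengths in mm.
    """

    center: np.ndarray
    semi_axes: np.ndarray
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        object.__setattr__(self, "center", _as_vec3(self.center))
        ax = np.asarray(self.semi_axes, dtype=float)
        if ax.shape != (3,) or np.any(ax <= 0):
            raise ValueError("semi_axes must be 3 positive lengths")
        object.__setattr__(self, "semi_axes", ax)
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be a 3x3 orthonormal matrix")
        object.__setattr__(self, "rotation", R)

    # -- basic measures -------------------------------------------------
    @property
    def volume_mm3(self) -> float:
        return float(4.0 / 3.0 * np.pi * np.prod(self.semi_axes))

    @property
    def volume_ml(self) -> float:
        return self.volume_mm3 / 1000.0

    def quadratic_matrix(self) -> np.ndarray:
        """M such that the surface is (x-c)^T M (x-c) = 1."""
        D = np.diag(1.0 / self.semi_axes**2)
        return self.rotation @ D @ self.rotation.T

    # -- predicates -----------------------------------------------------
    def scaled_distance(self, points: np.ndarray) -> np.ndarray:
        """sqrt((x-c)^T M (x-c)): 1 on the surface, <1 inside."""
        p = np.atleast_2d(np.asarray(points, dtype=float)) - self.center
        local = p @ self.rotation  # rows in local frame
        return np.sqrt(np.sum((local / self.semi_axes) ** 2, axis=-1))

    def contains(self, points: np.ndarray, tol: float = 0.0) -> np.ndarray:
        return self.scaled_distance(points) <= 1.0 + tol

    def surface_points(self, n: int = 66) -> np.ndarray:
        """Deterministic quasi-uniform surface samples (Fibonacci sphere)."""
        i = np.arange(n, dtype=float) + 0.5
        phi = np.arccos(1.0 - 2.0 * i / n)
        theta = np.pi * (1.0 + np.sqrt(5.0)) * i
        unit = np.stack(
            [
                np.sin(phi) * np.cos(theta),
                np.sin(phi) * np.sin(theta),
                np.cos(phi),
            ],
            axis=1,
        )
        return self.center + (unit * self.semi_axes) @ self.rotation.T

    # -- line and plane intersections -----------------------------------
    def line_interval(self, point, direction):
        """Parameters (t0, t1) with p(t) = point + t*direction on/inside the
        ellipsoid, or ``None`` if the line misses it."""
        t0, t1 = self.line_intervals_batch(
            np.asarray(point, float)[None, :], np.asarray(direction, float)[None, :]
        )
        if np.isnan(t0[0]):
            return None
        return float(t0[0]), float(t1[0])

    def line_intervals_batch(self, points: np.ndarray, directions: np.ndarray):
        """Vectorised line/ellipsoid intersection.

        Returns (t0, t1) arrays; NaN where the line misses.  ``directions``
        need not be normalised; parameters are in units of |direction|.
        """
        y = (np.asarray(points, float) - self.center) @ self.rotation / self.semi_axes
        d = np.asarray(directions, float) @ self.rotation / self.semi_axes
        a = np.sum(d * d, axis=-1)
        b = np.sum(y * d, axis=-1)
        c = np.sum(y * y, axis=-1) - 1.0
        disc = b * b - a * c
        ok = (disc >= 0) & (a > 0)
        sq = np.sqrt(np.where(ok, disc, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t0 = np.where(ok, (-b - sq) / a, np.nan)
            t1 = np.where(ok, (-b + sq) / a, np.nan)
        return t0, t1

    def plane_section(self, z: float):
        """Intersection with the axial plane at ``z``.

        Returns (center_xy, semi_axes_xy, angle) of the section ellipse or
        ``None`` if the plane misses the ellipsoid.
        """
        M = self.quadratic_matrix()
        A = M[:2, :2]
        b = M[:2, 2]
        m33 = M[2, 2]
        h = z - self.center[2]
        Ainv = np.linalg.inv(A)
        k = 1.0 - h * h * (m33 - b @ Ainv @ b)
        if k <= 1e-12:
            return None
        w0 = -h * (Ainv @ b)
        # section: (w - w0)^T (A/k) (w - w0) = 1
        evals, evecs = np.linalg.eigh(A / k)
        axes = 1.0 / np.sqrt(evals)
        angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
        return self.center[:2] + w0, axes[::-1], angle + np.pi / 2.0

    def section_polygon(self, z: float, n_vertices: int = 64):
        """CCW polygon approximating the axial cross-section, or None."""
        sec = self.plane_section(z)
        if sec is None:
            return None
        c, axes, angle = sec
        t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
        ca, sa = np.cos(angle), np.sin(angle)
        x = axes[0] * np.cos(t)
        y = axes[1] * np.sin(t)
        return np.stack([c[0] + ca * x - sa * y, c[1] + sa * x + ca * y], axis=1)

    def transformed(self, rotation=None, translation=None) -> "Ellipsoid":
        R = np.eye(3) if rotation is None else np.asarray(rotation, float)
        t = np.zeros(3) if translation is None else _as_vec3(translation)
        return Ellipsoid(R @ self.center + t, self.semi_axes, R @ self.rotation)


@dataclass(frozen=True)
class BiopsyCore:
    """A needle sampling segment.

    The sampled segment is ``realized_midpoint ± (effective_length/2) *
    direction``; ``planned_midpoint`` records where the core was aimed before
    targeting error displaced it.
    """

    entry: np.ndarray
    direction: np.ndarray
    effective_length: float
    planned_midpoint: np.ndarray
    realized_midpoint: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "entry", _as_vec3(self.entry))
        d = _as_vec3(self.direction)
        n = np.linalg.norm(d)
        if abs(n - 1.0) > 1e-6:
            raise ValueError("direction must be a unit vector")
        object.__setattr__(self, "direction", d / n)
        if not self.effective_length > 0:
            raise ValueError("effective_length must be positive")
        object.__setattr__(self, "planned_midpoint", _as_vec3(self.planned_midpoint))
        object.__setattr__(self, "realized_midpoint", _as_vec3(self.realized_midpoint))

    @classmethod
    def aimed(cls, entry, direction, midpoint, effective_length=17.0) -> "BiopsyCore":
        """A planned core whose realised position equals its plan."""
        return cls(entry, direction, effective_length, midpoint, midpoint)

    @property
    def segment(self):
        half = 0.5 * self.effective_length * self.direction
        return self.realized_midpoint - half, self.realized_midpoint + half

    def with_displacement(self, err) -> "BiopsyCore":
        return dataclasses.replace(
            self, realized_midpoint=self.realized_midpoint + _as_vec3(err)
        )


@dataclass(frozen=True)
class CoreResult:
    """Outcome of scoring one core against a model."""

    core: BiopsyCore
    cancer_length: float
    per_lesion_lengths: Mapping[str, float]
    positive: bool
    longest_run: float = 0.0
    gland_miss: bool = False


# ---------------------------------------------------------------------------
# interval bookkeeping


def merge_interval_lengths(starts: np.ndarray, ends: np.ndarray):
    """Union length and longest merged-interval length per row.

    ``starts``/``ends`` are (N, L) arrays of interval bounds along each of N
    lines; NaN marks an absent interval.  Intervals within a row may overlap.
    """
    starts = np.atleast_2d(np.asarray(starts, float))
    ends = np.atleast_2d(np.asarray(ends, float))
    n, m = starts.shape
    empty = ~np.isfinite(starts) | ~np.isfinite(ends) | (ends <= starts)
    s = np.where(empty, np.inf, starts)
    e = np.where(empty, -np.inf, ends)
    order = np.argsort(s, axis=1)
    s = np.take_along_axis(s, order, axis=1)
    e = np.take_along_axis(e, order, axis=1)
    total = np.zeros(n)
    longest = np.zeros(n)
    cur_s = np.full(n, np.nan)
    cur_e = np.full(n, np.nan)
    for j in range(m):
        sj, ej = s[:, j], e[:, j]
        valid = np.isfinite(sj) & (ej > sj)
        have = np.isfinite(cur_s)
        extend = valid & have & (sj <= cur_e)
        new = valid & (~have | (sj > cur_e))
        # close out the current run where a new disjoint interval starts
        close = new & have
        run = np.where(close, cur_e - cur_s, 0.0)
        total += run
        longest = np.maximum(longest, np.where(close, run, 0.0))
        cur_s = np.where(new, sj, cur_s)
        cur_e = np.where(new, ej, np.where(extend, np.maximum(cur_e, ej), cur_e))
    have = np.isfinite(cur_s)
    run = np.where(have, cur_e - cur_s, 0.0)
    total += run
    longest = np.maximum(longest, run)
    return total, longest


# ---------------------------------------------------------------------------
# analytic chord lengths


def chord_length_ellipsoid(core: BiopsyCore, ellipsoid: Ellipsoid) -> float:
    """Exact length of the core's sampled segment inside an ellipsoid (mm)."""
    iv = ellipsoid.line_interval(core.realized_midpoint, core.direction)
    if iv is None:
        return 0.0
    half = 0.5 * core.effective_length
    lo = max(iv[0], -half)
    hi = min(iv[1], half)
    return max(0.0, hi - lo)


def _clipped_intervals(midpoints, directions, half_len, ellipsoid):
    t0, t1 = ellipsoid.line_intervals_batch(midpoints, directions)
    return np.maximum(t0, -half_len), np.minimum(t1, half_len)


def cancer_lengths_batch(
    midpoints: np.ndarray,
    directions: np.ndarray,
    effective_length: float,
    lesion_ellipsoids: Sequence[Ellipsoid],
    cancer_flags: Sequence[bool],
):
    """Score N realised cores against ellipsoidal lesions at once.

    Returns (total, longest, per_lesion) where per_lesion is (N, L) clipped
    chord lengths for *all* lesions and total/longest are union lengths over
    the cancer-bearing (non-false-target) lesions only.
    """
    midpoints = np.atleast_2d(midpoints)
    directions = np.atleast_2d(directions)
    n = midpoints.shape[0]
    L = len(lesion_ellipsoids)
    half = 0.5 * effective_length
    per = np.zeros((n, L))
    starts = np.full((n, max(L, 1)), np.nan)
    ends = np.full((n, max(L, 1)), np.nan)
    for j, (ell, is_cancer) in enumerate(zip(lesion_ellipsoids, cancer_flags)):
        s, e = _clipped_intervals(midpoints, directions, half, ell)
        per[:, j] = np.clip(np.nan_to_num(e - s, nan=0.0), 0.0, None)
        if is_cancer:
            starts[:, j] = s
            ends[:, j] = e
    total, longest = merge_interval_lengths(starts, ends)
    return total, longest, per


# ---------------------------------------------------------------------------
# voxel (brute-force) route


def _sample_points(core: BiopsyCore, step: float):
    half = 0.5 * core.effective_length
    n = max(2, int(np.ceil(core.effective_length / step)) + 1)
    t = np.linspace(-half, half, n)
    pts = core.realized_midpoint + t[:, None] * core.direction
    return pts, t[1] - t[0]


def _mask_lookup(voxel_model, mask: np.ndarray, points: np.ndarray) -> np.ndarray:
    idx = np.round((points - voxel_model.origin) / voxel_model.spacing).astype(int)
    inside = np.zeros(len(points), dtype=bool)
    nz, ny, nx = mask.shape
    ok = (
        (idx[:, 0] >= 0)
        & (idx[:, 0] < nx)
        & (idx[:, 1] >= 0)
        & (idx[:, 1] < ny)
        & (idx[:, 2] >= 0)
        & (idx[:, 2] < nz)
    )
    sel = idx[ok]
    inside[ok] = mask[sel[:, 2], sel[:, 1], sel[:, 0]]
    return inside


def _run_lengths(flags: np.ndarray, dt: float):
    total = float(np.count_nonzero(flags)) * dt
    longest = 0
    run = 0
    for f in flags:
        run = run + 1 if f else 0
        longest = max(longest, run)
    return total, longest * dt


def _lesion_items(model) -> Iterable:
    """Yield (lesion_id, geometry, is_cancer) for analytic models."""
    for les in model.lesions:
        yield str(les.id), les.ellipsoid, not les.is_false_target


def core_cancer_length(core: BiopsyCore, model) -> CoreResult:
    """Score one core against an analytic or voxelised prostate model.

    ``model`` may be a ProstateModel (ellipsoidal lesions; exact chords) or a
    VoxelModel / reconstructed model (mask point-sampling at a step of half
    the voxel spacing).
    """
    from .reconstruct import VoxelModel  # local import: avoid cycle

    voxel = getattr(model, "voxel", model if isinstance(model, VoxelModel) else None)
    if voxel is not None:
        step = voxel.spacing / 2.0
        pts, dt = _sample_points(core, step)
        per = {}
        union = np.zeros(len(pts), dtype=bool)
        flags = getattr(model, "false_target_ids", frozenset())
        for name, mask in voxel.lesion_masks.items():
            inside = _mask_lookup(voxel, mask, pts)
            per[name] = float(np.count_nonzero(inside)) * dt
            if name not in flags:
                union |= inside
        total, longest = _run_lengths(union, dt)
        in_gland = _mask_lookup(voxel, voxel.gland_mask, pts)
        miss = not bool(in_gland.any())
    else:
        per = {}
        items = list(_lesion_items(model))
        ells = [g for _, g, _ in items]
        flags_c = [c for _, _, c in items]
        total_a, longest_a, per_l = cancer_lengths_batch(
            core.realized_midpoint[None, :],
            core.direction[None, :],
            core.effective_length,
            ells,
            flags_c,
        )
        for (name, _, _), val in zip(items, per_l[0]):
            per[name] = float(val)
        total = float(total_a[0])
        longest = float(longest_a[0])
        miss = chord_length_ellipsoid(core, model.gland) <= 0.0
    thresh = getattr(model, "positivity_threshold", 0.0)
    return CoreResult(
        core=core,
        cancer_length=total,
        per_lesion_lengths=per,
        positive=total > thresh,
        longest_run=longest,
        gland_miss=miss,
    )


def segment_in_gland_length(core: BiopsyCore, model) -> float:
    """Length of the core's sampled segment inside the gland (QC metric)."""
    from .reconstruct import VoxelModel

    voxel = getattr(model, "voxel", model if isinstance(model, VoxelModel) else None)
    if voxel is not None:
        pts, dt = _sample_points(core, voxel.spacing / 2.0)
        return float(np.count_nonzero(_mask_lookup(voxel, voxel.gland_mask, pts))) * dt
    return chord_length_ellipsoid(core, model.gland)
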