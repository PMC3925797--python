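"""Synthetic prostate cohort generator.

Generates 3D gland/lesion models whose population statistics emulate a
whole-mount radical-prostatectomy series: gland volume median ~50.2 ml
(range 26.8-127.7), a median of 5 tumour foci per gland (range 1-21),
separate index and non-index lesion volume distributions, anterior/posterior
zone placement and a configurable fraction of benign "false-positive"
imaging targets.  Volume distributions are truncated lognormals whose
parameters are fitted from the published summary statistics (median plus
either mean/SD or range); the fits live in :class:`CohortSpec` fields so
alternative calibrations are one config edit away.

Lesions are ellipsoids.  Real tumour foci are irregular, sprawling shapes;
an ellipsoid of equal volume is more compact and therefore *easier* to hit
with a needle, which biases simulated detection upward relative to real
histology.  Moderately eccentric semi-axis ratios are drawn per lesion to
temper (not remove) that bias; see docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .contours import CAPSULE, ContourStack, Slice
from .geometry import Ellipsoid

__all__ = [
    "GLEASON_CATEGORIES",
    "CohortSpec",
    "Lesion",
    "ProstateModel",
    "InfeasibleSpecError",
    "sample_prostate",
    "build_cohort",
    "emit_contour_stack",
]

GLEASON_CATEGORIES = ("<=6", "7", ">=8")
ZONES = ("anterior", "posterior")


class InfeasibleSpecError(RuntimeError):
    """Rejection sampling could not place a lesion inside the gland."""


@dataclass(frozen=True)
class CohortSpec:
    """Calibration targets and distribution parameters for a synthetic cohort.

    All volumes are ml.  Each (median, sigma, range) triple parameterises a
    lognormal with the given median, log-space SD ``sigma``, truncated by
    rejection to the closed range.
    """

    n_prostates: int = 107
    seed: int = 0

    gland_volume_median: float = 50.2
    gland_volume_sigma: float = 0.31
    gland_volume_range: tuple[float, float] = (26.8, 127.7)

    lesion_count_median: float = 5.0
    lesion_count_sigma: float = 0.60
    lesion_count_range: tuple[int, int] = (1, 21)

    index_volume_median: float = 1.215
    index_volume_sigma: float = 0.92
    index_volume_range: tuple[float, float] = (0.015, 13.242)

    nonindex_volume_median: float = 0.019
    nonindex_volume_sigma: float = 1.71
    nonindex_volume_range: tuple[float, float] = (0.001, 1.842)

    zone_probs: dict = field(
        default_factory=lambda: {"anterior": 415 / 665, "posterior": 250 / 665}
    )
    gleason_probs: dict = field(
        default_factory=lambda: {"<=6": 0.57, "7": 0.35, ">=8": 0.08}
    )

    false_positive_rate: float = 0.34
    false_target_min_volume: float = 0.2

    # geometric modelling choices (documented in docs/methods.md)
    gland_axis_ratios: tuple[float, float, float] = (1.0, 0.70, 0.80)
    lesion_aspect_b: tuple[float, float] = (0.55, 0.95)
    lesion_aspect_c: tuple[float, float] = (0.35, 0.75)
    index_max_gland_fraction: float = 0.25
    containment_tol: float = 0.05
    placement_margin: float = 0.92
    max_placement_attempts: int = 500

    def validate(self) -> None:
        if self.n_prostates < 0:
            raise ValueError("n_prostates must be non-negative")
        for name, probs, keys in (
            ("zone_probs", self.zone_probs, ZONES),
            ("gleason_probs", self.gleason_probs, GLEASON_CATEGORIES),
        ):
            vals = [probs.get(k, 0.0) for k in keys]
            if any(not 0.0 <= v <= 1.0 for v in vals):
                raise ValueError(f"{name} entries must lie in [0, 1]")
            if abs(sum(vals) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        if not 0.0 <= self.false_positive_rate <= 1.0:
            raise ValueError("false_positive_rate must lie in [0, 1]")
        for name in ("gland_volume", "index_volume", "nonindex_volume"):
            lo, hi = getattr(self, f"{name}_range")
            if not 0 < lo <= hi:
                raise ValueError(f"{name}_range must satisfy 0 < lo <= hi")
        lo, hi = self.lesion_count_range
        if not 1 <= lo <= hi:
            raise ValueError("lesion_count_range must satisfy 1 <= lo <= hi")


@dataclass(frozen=True)
class Lesion:
    """A tumour focus (or benign imaging target) within the gland."""

    id: str
    volume_ml: float
    gleason: str
    zone: str
    ellipsoid: Ellipsoid
    is_index: bool = False
    is_false_target: bool = False

    def __post_init__(self):
        if self.volume_ml <= 0:
            raise ValueError("lesion volume must be positive")
        if self.gleason not in GLEASON_CATEGORIES:
            raise ValueError(f"gleason must be one of {GLEASON_CATEGORIES}")
        if self.zone not in ZONES:
            raise ValueError(f"zone must be one of {ZONES}")
        if abs(self.ellipsoid.volume_ml - self.volume_ml) > 1e-6 * self.volume_ml:
            raise ValueError("volume_ml inconsistent with ellipsoid semi-axes")

    @property
    def center(self) -> np.ndarray:
        return self.ellipsoid.center


@dataclass(frozen=True)
class ProstateModel:
    """An analytic 3D prostate: ellipsoidal gland plus ellipsoidal lesions.

    Coordinate frame (mm): x lateral (patient left positive), y
    anterior-posterior (anterior positive), z along the base-apex axis (base
    positive), origin at the gland centre.  ``urethra_xy`` is the in-plane
    position of the (z-parallel) urethra axis; ``anus_reference`` anchors the
    transrectal needle trajectories.
    """

    model_id: str
    gland: Ellipsoid
    lesions: tuple[Lesion, ...]
    urethra_xy: tuple[float, float]
    anus_reference: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lesions", tuple(self.lesions))
        object.__setattr__(
            self, "anus_reference", np.asarray(self.anus_reference, float)
        )
        true_vol = sum(l.volume_ml for l in self.true_lesions)
        if true_vol > self.gland.volume_ml:
            raise ValueError("total tumour volume exceeds gland volume")
        idx = [l for l in self.lesions if l.is_index]
        if self.lesions and len(idx) != 1:
            raise ValueError("exactly one lesion must be flagged as index")

    @property
    def true_lesions(self) -> tuple[Lesion, ...]:
        return tuple(l for l in self.lesions if not l.is_false_target)

    @property
    def is_benign_target_model(self) -> bool:
        return len(self.lesions) > 0 and len(self.true_lesions) == 0

    @property
    def index_lesion(self) -> Lesion | None:
        for l in self.lesions:
            if l.is_index:
                return l
        return None

    @property
    def gland_volume_ml(self) -> float:
        return self.gland.volume_ml


# ---------------------------------------------------------------------------
# sampling helpers


def _trunc_lognormal(rng, median, sigma, lo, hi, max_tries=1000):
    if sigma <= 0:
        return float(np.clip(median, lo, hi))
    mu = np.log(median)
    for _ in range(max_tries):
        v = float(np.exp(rng.normal(mu, sigma)))
        if lo <= v <= hi:
            return v
    raise InfeasibleSpecError(
        f"truncated lognormal(median={median}, sigma={sigma}) never landed in "
        f"[{lo}, {hi}]"
    )


def _lesion_count(rng, spec: CohortSpec) -> int:
    lo, hi = spec.lesion_count_range
    v = _trunc_lognormal(rng, spec.lesion_count_median, spec.lesion_count_sigma,
                         lo - 0.49, hi + 0.49)
    return int(np.clip(round(v), lo, hi))


def _random_rotation(rng) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _gland_ellipsoid(volume_ml: float, ratios) -> Ellipsoid:
    rx, ry, rz = ratios
    scale = (volume_ml * 1000.0 / (4.0 / 3.0 * np.pi * rx * ry * rz)) ** (1.0 / 3.0)
    return Ellipsoid(np.zeros(3), np.array([rx, ry, rz]) * scale)


def _lesion_semi_axes(rng, volume_ml: float, spec: CohortSpec) -> np.ndarray:
    b = rng.uniform(*spec.lesion_aspect_b)
    c = rng.uniform(*spec.lesion_aspect_c)
    a = (volume_ml * 1000.0 / (4.0 / 3.0 * np.pi * b * c)) ** (1.0 / 3.0)
    return np.array([a, a * b, a * c])


def _place_lesion(rng, gland: Ellipsoid, semi_axes, zone, urethra_y, spec: CohortSpec):
    """Rejection-sample a centre and orientation keeping the lesion inside
    the capsule and (while attempts remain) on the requested side of the
    urethra-level coronal plane."""
    attempts = spec.max_placement_attempts
    for attempt in range(attempts):
        rot = _random_rotation(rng)
        # shrink candidate radius over attempts so large lesions drift
        # toward the centre where they can fit
        shrink = spec.placement_margin * (1.0 - 0.5 * attempt / attempts)
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        r = rng.uniform() ** (1.0 / 3.0)
        center = u * r * gland.semi_axes * shrink
        enforce_zone = attempt < attempts // 2
        if enforce_zone:
            want_anterior = zone == "anterior"
            if (center[1] > urethra_y) != want_anterior:
                center[1] = 2.0 * urethra_y - center[1]  # mirror across plane
        ell = Ellipsoid(center, semi_axes, rot)
        if np.all(gland.contains(ell.surface_points(), tol=spec.containment_tol)):
            final_zone = zone if enforce_zone else (
                "anterior" if center[1] > urethra_y else "posterior"
            )
            return ell, final_zone
    raise InfeasibleSpecError(
        f"could not place a lesion with semi-axes {np.round(semi_axes, 2)} mm "
        f"inside a {gland.volume_ml:.1f} ml gland after {attempts} attempts"
    )


def _sample_categor(rng, probs: dict, keys) -> str:
    p = np.array([probs[k] for k in keys])
    return keys[int(rng.choice(len(keys), p=p / p.sum()))]


def sample_prostate(
    spec: CohortSpec, rng: np.random.Generator, model_id: str = "P000"
) -> ProstateModel:
    """Draw one cancer-bearing synthetic prostate.

    Deterministic given the generator state; exactly one index lesion (the
    largest focus) per gland.
    """
    spec.validate()
    gland_vol = _trunc_lognormal(
        rng, spec.gland_volume_median, spec.gland_volume_sigma, *spec.gland_volume_range
    )
    gland = _gland_ellipsoid(gland_vol, spec.gland_axis_ratios)
    urethra_y = -0.10 * gland.semi_axes[1]
    anus = np.array([0.0, -(gland.semi_axes[1] + 30.0), -(gland.semi_axes[2] + 30.0)])

    n_lesions = _lesion_count(rng, spec)
    gland_gleason = _sample_categor(rng, spec.gleason_probs, GLEASON_CATEGORIES)

    index_cap = min(spec.index_volume_range[1],
                    spec.index_max_gland_fraction * gland_vol)
    index_vol = _trunc_lognormal(
        rng, spec.index_volume_median, spec.index_volume_sigma,
        spec.index_volume_range[0], index_cap,
    )
    volumes = [index_vol]
    budget = 0.5 * gland_vol - index_vol
    for _ in range(n_lesions - 1):
        hi = min(spec.nonindex_volume_range[1], 0.999 * index_vol, max(budget, spec.nonindex_volume_range[0]))
        v = _trunc_lognormal(
            rng, spec.nonindex_volume_median, spec.nonindex_volume_sigma,
            spec.nonindex_volume_range[0], max(hi, spec.nonindex_volume_range[0]),
        )
        volumes.append(v)
        budget -= v

    lesions = []
    for i, vol in enumerate(volumes):
        is_index = i == 0
        zone = _sample_categor(rng, spec.zone_probs, ZONES)
        axes = _lesion_semi_axes(rng, vol, spec)
        ell, zone = _place_lesion(rng, gland, axes, zone, urethra_y, spec)
        lesions.append(
            Lesion(
                id=f"{model_id}-L{i + 1}",
                volume_ml=ell.volume_ml,
                gleason=gland_gleason if is_index else "<=6",
                zone=zone,
                ellipsoid=ell,
                is_index=is_index,
            )
        )
    return ProstateModel(
        model_id=model_id,
        gland=gland,
        lesions=tuple(lesions),
        urethra_xy=(0.0, urethra_y),
        anus_reference=anus,
    )


def _sample_benign_target_model(
    spec: CohortSpec, rng: np.random.Generator, model_id: str
) -> ProstateModel:
    """A gland whose only imaging target is a benign (cancer-free) region."""
    gland_vol = _trunc_lognormal(
        rng, spec.gland_volume_median, spec.gland_volume_sigma, *spec.gland_volume_range
    )
    gland = _gland_ellipsoid(gland_vol, spec.gland_axis_ratios)
    urethra_y = -0.10 * gland.semi_axes[1]
    anus = np.array([0.0, -(gland.semi_axes[1] + 30.0), -(gland.semi_axes[2] + 30.0)])
    vol = _trunc_lognormal(
        rng, spec.index_volume_median, spec.index_volume_sigma,
        max(spec.false_target_min_volume, spec.index_volume_range[0]),
        min(spec.index_volume_range[1], spec.index_max_gland_fraction * gland_vol),
    )
    zone = _sample_categor(rng, spec.zone_probs, ZONES)
    axes = _lesion_semi_axes(rng, vol, spec)
    ell, zone = _place_lesion(rng, gland, axes, zone, urethra_y, spec)
    lesion = Lesion(
        id=f"{model_id}-L1",
        volume_ml=ell.volume_ml,
        gleason="<=6",
        zone=zone,
        ellipsoid=ell,
        is_index=True,
        is_false_target=True,
    )
    return ProstateModel(
        model_id=model_id,
        gland=gland,
        lesions=(lesion,),
        urethra_xy=(0.0, urethra_y),
        anus_reference=anus,
    )


def n_benign_models(n_prostates: int, false_positive_rate: float) -> int:
    """Benign-target models to add so that the fraction of targeted sessions
    aimed at a benign region equals ``false_positive_rate``."""
    r = false_positive_rate
    if r >= 1.0:
        raise ValueError(
            "false_positive_rate=1 with cancer models present is unsatisfiable; "
            "use n_prostates=0 for an all-benign cohort"
        )
    return int(round(n_prostates * r / (1.0 - r)))


def build_cohort(spec: CohortSpec, rng: np.random.Generator | None = None):
    """Build the full simulation cohort: cancer models plus benign-target
    models at the configured false-positive session rate."""
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if spec.false_positive_rate >= 1.0:
        # every targeted session aims at a benign region
        return [
            _sample_benign_target_model(spec, rng, model_id=f"B{i + 1:03d}")
            for i in range(spec.n_prostates)
        ]
    models = [
        sample_prostate(spec, rng, model_id=f"P{i + 1:03d}")
        for i in range(spec.n_prostates)
    ]
    if spec.false_positive_rate > 0 and spec.n_prostates > 0:
        n_benign = n_benign_models(spec.n_prostates, spec.false_positive_rate)
        models += [
            _sample_benign_target_model(spec, rng, model_id=f"B{i + 1:03d}")
            for i in range(n_benign)
        ]
    return models


# ---------------------------------------------------------------------------
# contour emission


def emit_contour_stack(
    model: ProstateModel, slice_thickness: float = 5.0, n_vertices: int = 64
) -> ContourStack:
    """Step-section an analytic model into a 5-mm-style contour stack.

    Slices are planes at the centres of ``slice_thickness`` slabs spanning
    the gland's axial extent, ordered base-to-apex (increasing z here; the
    ordering is what matters).  Lesions thinner than one slice can fail to
    intersect any slice plane; such lesions are recorded in
    ``missing_structures`` and a warning is emitted — they are reported, not
    silently dropped.
    """
    if slice_thickness <= 0:
        raise ValueError("slice_thickness must be positive")
    zc = model.gland.center[2]
    half_extent = model.gland.semi_axes[2]
    z_lo, z_hi = zc - half_extent, zc + half_extent
    first = z_lo + 0.5 * slice_thickness
    if first > z_hi:  # thicker than the gland: emit the single mid slab
        z_planes = np.array([0.5 * (z_lo + z_hi)])
    else:
        n = int(np.floor((z_hi - first) / slice_thickness)) + 1
        z_planes = first + slice_thickness * np.arange(n)

    slices = []
    seen: set[str] = set()
    for z in z_planes:
        sl = Slice(float(z))
        cap = model.gland.section_polygon(z, n_vertices)
        if cap is not None:
            sl.structures[CAPSULE] = cap
        for les in model.lesions:
            poly = les.ellipsoid.section_polygon(z, n_vertices)
            if poly is not None:
                sl.structures[f"lesion:{les.id}"] = poly
                seen.add(les.id)
        slices.append(sl)

    missing = [f"lesion:{l.id}" for l in model.lesions if l.id not in seen]
    if missing:
        warnings.warn(
            f"{model.model_id}: structures thinner than one slice do not "
            f"appear in the contour stack: {missing}"
        )
    metadata = {f"lesion:{l.id}": {"gleason": l.gleason} for l in model.lesions}
    return ContourStack(
        float(slice_thickness), slices, metadata, missing_structures=missing
    )
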