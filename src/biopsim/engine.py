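"""Monte-Carlo biopsy simulation driver.

Targeting error model
---------------------
Every realised core is the planned core displaced by a random translation
(the needle is not bent: the midpoint of the effective segment moves, the
direction is preserved).  Displacement components are zero-mean normal in
three orthogonal directions.  Two sampling modes:

* ``combined`` (default): a single total displacement with per-axis variance
  ``total_sd**2 / 3``, so the summed per-axis variance of the sampled
  displacement equals the set total variance ``total_sd**2`` (25 mm^2 at the
  5 mm default).  Applied to every strategy, keeping strategies comparable.
* ``components``: needle deflection (per-axis SD ``deflection_sd``) and
  US-MRI registration error (per-axis SD ``registration_sd``, applied to
  targeted cores only unless ``apply_registration_to='all'``) are sampled
  separately, then rescaled so the targeted-core total variance equals
  ``total_sd**2``.  The set total deliberately exceeds the additive
  component variance, following the source error budget.

Repetition structure: per model and strategy, ``reps`` independent sessions
are simulated.  Systematic TRUS plans are re-drawn each repetition (probe /
insertion-site variability); targeted plans are fixed at planning time, with
error applied at realisation.  Seeding uses spawned substreams per (model,
strategy) so any subset of the cohort reruns bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import BiopsyCore, CoreResult, cancer_lengths_batch
from .schemes import (
    TRUS12,
    BiopsyPlan,
    TemplateGrid,
    TrusSchemeSpec,
    default_trus_scheme,
    eligible_targets,
    plan_targeted,
)

__all__ = [
    "ErrorModel",
    "SessionResult",
    "sample_error",
    "realize_core",
    "run_strategy",
    "run_cohort",
    "error_sweep",
]


@dataclass(frozen=True)
class ErrorModel:
    total_sd: float = 5.0
    deflection_sd: float = 3.0
    registration_sd: float = 3.0
    mode: str = "combined"  # "combined" | "components"
    apply_registration_to: str = "targeted_only"  # "targeted_only" | "all"
    sd_convention: str = "vector"  # "vector" | "per_axis"

    def __post_init__(self):
        if min(self.total_sd, self.deflection_sd, self.registration_sd) < 0:
            raise ValueError("error SDs must be non-negative")
        if self.mode not in ("combined", "components"):
            raise ValueError("mode must be 'combined' or 'components'")
        if self.apply_registration_to not in ("targeted_only", "all"):
            raise ValueError("apply_registration_to must be 'targeted_only' or 'all'")
        if self.sd_convention not in ("vector", "per_axis"):
            raise ValueError("sd_convention must be 'vector' or 'per_axis'")

    def with_total(self, total_sd: float) -> "ErrorModel":
        return replace(self, total_sd=total_sd)

    @property
    def axis_sd(self) -> float:
        """Per-axis SD of the sampled total displacement.

        Under the default ``"vector"`` convention the summed per-axis
        variance equals ``total_sd**2`` (set total variance 25 mm^2 at the
        5 mm default).  Under ``"per_axis"`` each orthogonal component has SD
        ``total_sd`` — the reading under which the additive component
        variance 9 + 9 mm^2 falls short of the set 25 mm^2 axis by axis.
        """
        if self.sd_convention == "per_axis":
            return self.total_sd
        return self.total_sd / np.sqrt(3.0)

    # -- samplers -------------------------------------------------------
    def sample_total(self, rng: np.random.Generator, n: int, targeted: bool = True):
        """(n, 3) total-displacement vectors for one core population."""
        if self.mode == "combined":
            return rng.normal(0.0, self.axis_sd, size=(n, 3))
        d = rng.normal(0.0, self.deflection_sd, size=(n, 3))
        use_reg = targeted or self.apply_registration_to == "all"
        r = rng.normal(0.0, self.registration_sd, size=(n, 3)) if use_reg else 0.0
        additive_axis_var = self.deflection_sd**2 + self.registration_sd**2
        scale = self.axis_sd / np.sqrt(additive_axis_var) if additive_axis_var > 0 else 0.0
        return (d + r) * scale

    def sample_deflection(self, rng: np.random.Generator, n: int):
        """(n, 3) needle-deflection component vectors (per-axis SD as set)."""
        return rng.normal(0.0, self.deflection_sd, size=(n, 3))


def sample_error(em: ErrorModel, rng: np.random.Generator,
                 targeted: bool = True) -> np.ndarray:
    """One total-displacement 3-vector (mm)."""
    return em.sample_total(rng, 1, targeted=targeted)[0]


def realize_core(core: BiopsyCore, err) -> BiopsyCore:
    """Translate the planned core by a sampled displacement."""
    return replace(core, realized_midpoint=core.planned_midpoint + np.asarray(err, float))


@dataclass(frozen=True)
class SessionResult:
    """Per-repetition outcome of one biopsy session."""

    model_id: str
    strategy: str
    repetition: int
    mccl: float
    pct_positive: float
    n_positive: int
    n_cores: int
    detected: bool
    mccl_contiguous: float = 0.0
    core_results: tuple[CoreResult, ...] | None = None
    seed_key: tuple | None = None


def _is_targeted(strategy: str) -> bool:
    return strategy.startswith("TARGETED_")


def _targeted_k(strategy: str) -> int:
    return int(strategy.split("_")[1])


def _planned_arrays(model, strategy, reps, rng, trus_spec, grid,
                    effective_length, target_threshold):
    """(midpoints (reps, n, 3), directions (reps, n, 3), plan) for a run."""
    if strategy == TRUS12:
        spec = trus_spec or default_trus_scheme()
        from .schemes import _gland_frame  # shared anatomy helper

        center, semi = _gland_frame(model)
        anus = np.asarray(model.anus_reference, float)
        slots = np.array(spec.core_slots, float)  # (12, 3)
        nominal = np.stack(
            [
                center[0] + slots[:, 0] * slots[:, 2] * semi[0],
                np.full(len(slots), center[1] - spec.posterior_depth_frac * semi[1]),
                center[2] + slots[:, 1] * semi[2],
            ],
            axis=1,
        )
        jitter = rng.normal(0.0, spec.jitter_sd_mm, size=(reps, 12, 3))
        mids = nominal[None] + jitter
        dirs = mids - anus
        dirs /= np.linalg.norm(dirs, axis=-1, keepdims=True)
        plan = BiopsyPlan(TRUS12, tuple(
            BiopsyCore.aimed(anus, d, m, spec.effective_length_mm)
            for m, d in zip(nominal, (nominal - anus) /
                            np.linalg.norm(nominal - anus, axis=-1, keepdims=True))
        ), target_ids=())
        return mids, dirs, plan, spec.effective_length_mm
    k = _targeted_k(strategy)
    plan = plan_targeted(model, k, grid=grid, effective_length=effective_length,
                         target_threshold=target_threshold)
    mids = np.stack([c.planned_midpoint for c in plan.cores])
    dirs = np.stack([c.direction for c in plan.cores])
    return (
        np.broadcast_to(mids, (reps, *mids.shape)).copy(),
        np.broadcast_to(dirs, (reps, *dirs.shape)).copy(),
        plan,
        effective_length,
    )


def _lesion_geoms(model):
    items = [(l.id, l.ellipsoid, not l.is_false_target) for l in model.lesions]
    return (
        [g for _, g, _ in items],
        [c for _, _, c in items],
        [i for i, _, _ in items],
    )


def _score_voxel(model, mids, dirs, effective_length):
    """Brute-force scoring for voxel-backed models (small runs only)."""
    voxel = model.voxel
    step = voxel.spacing / 2.0
    n_pts = max(2, int(np.ceil(effective_length / step)) + 1)
    t = np.linspace(-effective_length / 2, effective_length / 2, n_pts)
    pts = mids[:, None, :] + t[None, :, None] * dirs[:, None, :]
    idx = np.round((pts - voxel.origin) / voxel.spacing).astype(int)
    nz, ny, nx = voxel.gland_mask.shape
    ok = (
        (idx[..., 0] >= 0) & (idx[..., 0] < nx)
        & (idx[..., 1] >= 0) & (idx[..., 1] < ny)
        & (idx[..., 2] >= 0) & (idx[..., 2] < nz)
    )
    ic = np.where(ok[..., None], idx, 0)
    false_ids = getattr(model, "false_target_ids", frozenset())
    union = np.zeros(pts.shape[:2], bool)
    for name, mask in voxel.lesion_masks.items():
        if name in false_ids:
            continue
        inside = mask[ic[..., 2], ic[..., 1], ic[..., 0]] & ok
        union |= inside
    dt = t[1] - t[0]
    total = union.sum(axis=1) * dt
    # longest contiguous run per row
    longest = np.zeros(len(total))
    for i, row in enumerate(union):
        run = best = 0
        for f in row:
            run = run + 1 if f else 0
            best = max(best, run)
        longest[i] = best * dt
    return total, longest


def _simulate(model, strategy, em, reps, rng, *, trus_spec=None, grid=None,
              effective_length=17.0, target_threshold=0.2,
              positivity_threshold=0.0):
    """Vectorised simulation of one (model, strategy) pair.

    Returns per-repetition arrays and the plan.
    """
    mids, dirs, plan, eff_len = _planned_arrays(
        model, strategy, reps, rng, trus_spec, grid, effective_length,
        target_threshold,
    )
    n_cores = mids.shape[1]
    err = em.sample_total(rng, reps * n_cores, targeted=_is_targeted(strategy))
    realized = mids.reshape(-1, 3) + err
    flat_dirs = dirs.reshape(-1, 3)
    if getattr(model, "voxel", None) is not None:
        total, longest = _score_voxel(model, realized, flat_dirs, eff_len)
    else:
        geoms, cancer_flags, _ = _lesion_geoms(model)
        total, longest, _ = cancer_lengths_batch(
            realized, flat_dirs, eff_len, geoms, cancer_flags
        )
    total = total.reshape(reps, n_cores)
    longest = longest.reshape(reps, n_cores)
    positive = total > positivity_threshold
    return {
        "plan": plan,
        "cancer_length": total,
        "longest_run": longest,
        "positive": positive,
        "mccl": total.max(axis=1),
        "mccl_contiguous": longest.max(axis=1),
        "n_positive": positive.sum(axis=1),
        "pct_positive": 100.0 * positive.mean(axis=1),
        "detected": positive.any(axis=1),
        "realized": realized.reshape(reps, n_cores, 3),
        "directions": dirs,
        "effective_length": eff_len,
    }


def run_strategy(
    model,
    strategy: str,
    em: ErrorModel,
    reps: int,
    rng: np.random.Generator,
    *,
    trus_spec: TrusSchemeSpec | None = None,
    grid: TemplateGrid | None = None,
    effective_length: float = 17.0,
    target_threshold: float = 0.2,
    positivity_threshold: float = 0.0,
    plan: BiopsyPlan | None = None,
) -> list[SessionResult]:
    """Simulate ``reps`` sessions of one strategy on one model.

    With an all-zero error model and a fixed (targeted) plan every
    repetition is identical; TRUS plans are re-drawn per repetition.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    out = _simulate(
        model, strategy, em, reps, rng, trus_spec=trus_spec, grid=grid,
        effective_length=effective_length, target_threshold=target_threshold,
        positivity_threshold=positivity_threshold,
    )
    results = []
    for r in range(reps):
        results.append(
            SessionResult(
                model_id=model.model_id,
                strategy=strategy,
                repetition=r,
                mccl=float(out["mccl"][r]),
                pct_positive=float(out["pct_positive"][r]),
                n_positive=int(out["n_positive"][r]),
                n_cores=out["positive"].shape[1],
                detected=bool(out["detected"][r]),
                mccl_contiguous=float(out["mccl_contiguous"][r]),
            )
        )
    return results


def _strategy_rows(model, strategy, out, reps):
    return pd.DataFrame(
        {
            "model_id": model.model_id,
            "strategy": strategy,
            "rep": np.arange(reps),
            "mccl": out["mccl"],
            "mccl_contiguous": out["mccl_contiguous"],
            "pct_positive": out["pct_positive"],
            "n_positive": out["n_positive"],
            "n_cores": out["positive"].shape[1],
            "detected": out["detected"],
        }
    )


def run_cohort(
    cohort: Sequence,
    strategies: Sequence[str],
    em: ErrorModel,
    reps: int,
    seed: int,
    *,
    trus_spec: TrusSchemeSpec | None = None,
    effective_length: float = 17.0,
    target_threshold: float = 0.2,
    positivity_threshold: float = 0.0,
) -> pd.DataFrame:
    """Tidy long-format results: one row per repetition x strategy x model.

    Models with no eligible target silently skip targeted strategies (no
    imaging target: the case reverts to systematic biopsy only); their
    absence is visible in the output table.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(cohort) * len(strategies))
    frames = []
    for i, model in enumerate(cohort):
        has_target = bool(eligible_targets(model, target_threshold))
        for j, strategy in enumerate(strategies):
            if _is_targeted(strategy) and not has_target:
                continue
            rng = np.random.default_rng(children[i * len(strategies) + j])
            out = _simulate(
                model, strategy, em, reps, rng, trus_spec=trus_spec,
                effective_length=effective_length,
                target_threshold=target_threshold,
                positivity_threshold=positivity_threshold,
            )
            frames.append(_strategy_rows(model, strategy, out, reps))
    if not frames:
        return pd.DataFrame(
            columns=["model_id", "strategy", "rep", "mccl", "mccl_contiguous",
                     "pct_positive", "n_positive", "n_cores", "detected"]
        )
    return pd.concat(frames, ignore_index=True)


def error_sweep(
    cohort: Sequence,
    strategies: Sequence[str],
    totals: Sequence[float],
    reps: int,
    seed: int,
    em: ErrorModel | None = None,
    **kwargs,
) -> pd.DataFrame:
    """All-cancer sensitivity per strategy over a range of total errors.

    Sensitivity here is the per-repetition detection rate averaged over the
    cancer-bearing models (benign-target models are excluded from the
    denominator).
    """
    from .metrics import sensitivity  # late import: metrics depends on engine types

    if em is None:
        em = ErrorModel()
    if any(t < 0 for t in totals):
        raise ValueError("total errors must be non-negative")
    rows = []
    for t in totals:
        df = run_cohort(cohort, strategies, em.with_total(float(t)), reps, seed,
                        **kwargs)
        for strategy in strategies:
            sub = df[df["strategy"] == strategy]
            if sub.empty:
                continue
            rows.append(
                {
                    "strategy": strategy,
                    "total_error_mm": float(t),
                    "sensitivity_all": sensitivity(sub, cohort, stratum="all"),
                }
            )
    return pd.DataFrame(rows)
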