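"""Risk attribution and between-strategy statistics.

Risk stratification follows the conventional biopsy criteria: a session is
high risk when MCCL >= 6 mm and/or >= 50% of deployed cores are positive.
Clinically significant disease is a gland with any true lesion >= 0.5 ml
and/or Gleason >= 7.

Case-level aggregation across repetitions is configurable:

* ``"mean"`` (default) — the Table-1-style thresholds are applied to the
  per-case mean MCCL and mean %-positive over repetitions, yielding one
  classification per case, consistent with reporting one risk class
  alongside per-case summary statistics.
* ``"majority"`` — a case is high risk when more than half of its
  repetitions classify high.

Per-repetition classifications are always derivable from the tidy results
table, so any other rule can be applied post hoc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RiskCriteria",
    "SignificanceCriteria",
    "CohortSummary",
    "classify_risk",
    "case_is_significant",
    "sensitivity",
    "attribution_rate",
    "summarize",
    "compare_strategies",
]

GLEASON_ORDER = {"<=6": 6, "7": 7, ">=8": 8}


@dataclass(frozen=True)
class RiskCriteria:
    """High/low biopsy risk thresholds (boundary inclusive, OR-combined)."""

    mccl_threshold: float = 6.0
    pct_positive_threshold: float = 50.0

    def __post_init__(self):
        if self.mccl_threshold < 0 or self.pct_positive_threshold < 0:
            raise ValueError("risk thresholds must be non-negative")


@dataclass(frozen=True)
class SignificanceCriteria:
    """Clinically significant disease: volume and/or Gleason (OR-combined)."""

    volume_threshold: float = 0.5
    gleason_threshold: int = 7

    def __post_init__(self):
        if self.volume_threshold <= 0:
            raise ValueError("volume_threshold must be positive")


@dataclass
class CohortSummary:
    """Aggregated per-strategy, per-stratum statistics."""

    table: pd.DataFrame
    sensitivities: pd.DataFrame
    aggregation: str
    criteria: RiskCriteria
    significance: SignificanceCriteria
    comparisons: dict = field(default_factory=dict)


def classify_risk(mccl: float, pct_positive: float,
                  c: RiskCriteria | None = None) -> str:
    """'high' iff MCCL >= threshold OR %positive >= threshold, else 'low'."""
    if mccl < 0 or pct_positive < 0:
        raise ValueError("inputs must be non-negative")
    if c is None:
        c = RiskCriteria()
    high = mccl >= c.mccl_threshold or pct_positive >= c.pct_positive_threshold
    return "high" if high else "low"


def case_is_significant(model, sc: SignificanceCriteria | None = None) -> bool:
    """True iff any *true* lesion meets the volume or Gleason criterion."""
    if sc is None:
        sc = SignificanceCriteria()
    for lesion in model.true_lesions:
        if lesion.volume_ml >= sc.volume_threshold:
            return True
        if GLEASON_ORDER[lesion.gleason] >= sc.gleason_threshold:
            return True
    return False


class EmptyStratumError(ValueError):
    """The requested stratum contains no cancer-bearing models."""


def _stratum_ids(cohort: Sequence, stratum: str,
                 sc: SignificanceCriteria | None = None) -> list[str]:
    if stratum not in ("all", "significant", "insignificant"):
        raise ValueError(f"unknown stratum {stratum!r}")
    ids = []
    for model in cohort:
        if model.is_benign_target_model:
            continue
        if stratum == "all":
            ids.append(model.model_id)
        else:
            sig = case_is_significant(model, sc)
            if (stratum == "significant") == sig:
                ids.append(model.model_id)
    return ids


def _single_strategy(results: pd.DataFrame) -> pd.DataFrame:
    strategies = results["strategy"].unique()
    if len(strategies) != 1:
        raise ValueError(
            "results must cover a single strategy; filter the table first "
            f"(got {sorted(strategies)})"
        )
    return results


def sensitivity(
    results: pd.DataFrame,
    cohort: Sequence,
    stratum: str = "all",
    sc: SignificanceCriteria | None = None,
    rule: str = "per_repetition",
) -> float:
    """Detection sensitivity of one strategy over a cohort stratum.

    Default rule: per-repetition detection (a 0/1 per repetition per model)
    averaged over repetitions, then over the stratum's cancer-bearing
    models.  ``rule='ever'`` instead counts a model detected if any
    repetition detected it (saturating; kept for comparison).
    """
    _single_strategy(results)
    ids = _stratum_ids(cohort, stratum, sc)
    if not ids:
        raise EmptyStratumError(f"stratum {stratum!r} holds no cancer-bearing models")
    sub = results[results["model_id"].isin(ids)]
    per_model = sub.groupby("model_id")["detected"].mean()
    per_model = per_model.reindex(ids, fill_value=0.0)  # undetectable => 0
    if rule == "ever":
        return float((per_model > 0).mean())
    if rule != "per_repetition":
        raise ValueError("rule must be 'per_repetition' or 'ever'")
    return float(per_model.mean())


def _case_classifications(
    results: pd.DataFrame,
    c: RiskCriteria,
    aggregation: str,
) -> pd.Series:
    """Per-model 'high'/'low' classification for one strategy's results."""
    _single_strategy(results)
    g = results.groupby("model_id")
    if aggregation == "mean":
        mccl = g["mccl"].mean()
        pct = g["pct_positive"].mean()
        high = (mccl >= c.mccl_threshold) | (pct >= c.pct_positive_threshold)
    elif aggregation == "majority":
        per_rep_high = (results["mccl"] >= c.mccl_threshold) | (
            results["pct_positive"] >= c.pct_positive_threshold
        )
        high = per_rep_high.groupby(results["model_id"]).mean() > 0.5
    else:
        raise ValueError("aggregation must be 'mean' or 'majority'")
    return high.map({True: "high", False: "low"})


def attribution_rate(
    results: pd.DataFrame,
    cohort: Sequence,
    c: RiskCriteria | None = None,
    sc: SignificanceCriteria | None = None,
    stratum: str = "significant",
    aggregation: str = "mean",
) -> float:
    """Fraction of the stratum's cases whose case-level class is high risk."""
    if c is None:
        c = RiskCriteria()
    ids = _stratum_ids(cohort, stratum, sc)
    if not ids:
        raise EmptyStratumError(f"stratum {stratum!r} holds no cancer-bearing models")
    sub = results[results["model_id"].isin(ids)]
    cls = _case_classifications(sub, c, aggregation) if len(sub) else pd.Series(dtype=object)
    cls = cls.reindex(ids, fill_value="low")  # never-biopsied cases carry no risk
    return float((cls == "high").mean())


def _order_stats(x: pd.Series) -> dict:
    v = x.to_numpy(float)
    return {
        "mean": float(np.mean(v)),
        "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
        "median": float(np.median(v)),
        "p90": float(np.percentile(v, 90)),  # inclusive linear interpolation
    }


def summarize(
    results: pd.DataFrame,
    cohort: Sequence,
    c: RiskCriteria | None = None,
    sc: SignificanceCriteria | None = None,
    strata: Sequence[str] = ("all", "significant", "insignificant"),
    aggregation: str = "mean",
) -> CohortSummary:
    """Per stratum and strategy: mean+/-SD, median and 90th percentile of the
    per-case mean MCCL and %-positive, sensitivity, and the high-risk
    attribution fraction."""
    if c is None:
        c = RiskCriteria()
    if sc is None:
        sc = SignificanceCriteria()
    rows, sens_rows = [], []
    for strategy in sorted(results["strategy"].unique()):
        sres = results[results["strategy"] == strategy]
        for stratum in strata:
            ids = _stratum_ids(cohort, stratum, sc)
            if not ids:
                continue
            sub = sres[sres["model_id"].isin(ids)]
            if sub.empty:
                continue
            per_case = sub.groupby("model_id")[["mccl", "pct_positive"]].mean()
            per_case = per_case.reindex(ids, fill_value=0.0)
            row = {"strategy": strategy, "stratum": stratum, "n_cases": len(ids)}
            for metric, col in (("mccl", "mccl"), ("pct_positive", "pct_positive")):
                for k, v in _order_stats(per_case[col]).items():
                    row[f"{metric}_{k}"] = v
            row["attribution_high"] = attribution_rate(
                sres, cohort, c, sc, stratum=stratum, aggregation=aggregation
            )
            rows.append(row)
            sens_rows.append(
                {
                    "strategy": strategy,
                    "stratum": stratum,
                    "sensitivity": sensitivity(sres, cohort, stratum, sc),
                }
            )
    return CohortSummary(
        table=pd.DataFrame(rows),
        sensitivities=pd.DataFrame(sens_rows),
        aggregation=aggregation,
        criteria=c,
        significance=sc,
    )


def compare_strategies(
    res_a: pd.DataFrame,
    res_b: pd.DataFrame,
    metrics: Sequence[str] = ("mccl", "pct_positive"),
) -> dict:
    """Paired comparison of two strategies on the same cohort.

    Pairs per-case means by model id and reports, per metric: the paired
    Student t test, the two-sample Kolmogorov-Smirnov statistic on the
    matched per-case values, and a KS test of the paired differences against
    their sign-flipped mirror (a symmetry check) — both defensible readings
    of a "paired KS test" are computed and labelled.  Raw p-values, no
    multiplicity correction.
    """
    _single_strategy(res_a)
    _single_strategy(res_b)
    a = res_a.groupby("model_id")[list(metrics)].mean()
    b = res_b.groupby("model_id")[list(metrics)].mean()
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise ValueError("paired tests need at least 3 common models")
    out: dict[str, dict] = {
        "n_pairs": int(len(common)),
        "strategy_a": str(res_a["strategy"].iloc[0]),
        "strategy_b": str(res_b["strategy"].iloc[0]),
    }
    for m in metrics:
        x = a.loc[common, m].to_numpy(float)
        y = b.loc[common, m].to_numpy(float)
        d = y - x
        if np.allclose(d, 0.0):
            t_stat, t_p = 0.0, 1.0
        else:
            t_stat, t_p = stats.ttest_rel(y, x)
        ks2 = stats.ks_2samp(x, y, method="asymp")
        if np.allclose(d, 0.0):
            ks_sym_stat, ks_sym_p = 0.0, 1.0
        else:
            ks_sym = stats.ks_2samp(d, -d, method="asymp")
            ks_sym_stat, ks_sym_p = float(ks_sym.statistic), float(ks_sym.pvalue)
        out[m] = {
            "mean_diff": float(np.mean(d)),
            "t_stat": float(t_stat),
            "t_p": float(t_p),
            "ks_stat": float(ks2.statistic),
            "ks_p": float(ks2.pvalue),
            "ks_paired_symmetry_stat": ks_sym_stat,
            "ks_paired_symmetry_p": ks_sym_p,
        }
    return out
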