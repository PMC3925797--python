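"""Risk classification, sensitivity, attribution and paired statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from biopsim.engine import ErrorModel, run_cohort
from biopsim.metrics import (
    EmptyStratumError,
    attribution_rate,
    case_is_significant,
    classify_risk,
    compare_strategies,
    sensitivity,
    summarize,
)

from conftest import make_model, spherical_lesion


def results_frame(rows):
    """rows: (model_id, strategy, rep, mccl, pct_positive, detected)"""
    return pd.DataFrame(
        rows,
        columns=["model_id", "strategy", "rep", "mccl", "pct_positive", "detected"],
    )


class TestClassifyRisk:
    @pytest.mark.parametrize(
        "mccl,pct,expected",
        [
            (6.0, 0.0, "high"),    # MCCL boundary inclusive
            (0.0, 50.0, "high"),   # %positive boundary inclusive
            (5.9, 49.0, "low"),    # both below
            (12.0, 80.0, "high"),
            (0.0, 0.0, "low"),
        ],
    )
    def test_threshold_boundaries(self, mccl, pct, expected):
        assert classify_risk(mccl, pct) == expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_risk(-1.0, 10.0)

    @given(
        st.floats(0, 20), st.floats(0, 100),
        st.floats(0, 5), st.floats(0, 50),
    )
    def test_monotone_in_both_inputs(self, mccl, pct, dm, dp):
        base = classify_risk(mccl, pct)
        if base == "high":
            assert classify_risk(mccl + dm, pct + dp) == "high"


class TestCaseSignificance:
    def test_volume_boundary_inclusive(self):
        m = make_model([spherical_lesion([0, -3, 0], 1.0, gleason="<=6")])
        big = make_model(
            [spherical_lesion([0, -3, 0], (0.5 * 750 / np.pi) ** (1 / 3), gleason="<=6")]
        )
        assert case_is_significant(big)  # exactly 0.5 ml
        assert not case_is_significant(m)  # ~0.004 ml, Gleason <=6

    def test_gleason_alone_is_sufficient(self):
        m = make_model([spherical_lesion([0, -3, 0], 4.57, gleason="7")])  # 0.4 ml
        assert case_is_significant(m)

    def test_false_targets_never_significant(self):
        m = make_model(
            [spherical_lesion([0, -3, 0], 6.2, gleason=">=8", is_false_target=True)]
        )
        assert not case_is_significant(m)


class TestSensitivity:
    def _cohort(self):
        return [
            make_model([spherical_lesion([0, -3, 0], 6.2)], model_id="A"),
            make_model([spherical_lesion([0, -3, 0], 6.2)], model_id="B"),
        ]

    def test_all_positive_gives_one(self):
        cohort = self._cohort()
        df = results_frame(
            [(m, "TRUS12", r, 5.0, 10.0, True) for m in "AB" for r in range(4)]
        )
        assert sensitivity(df, cohort, "all") == 1.0

    def test_exact_average_over_models(self):
        cohort = self._cohort()
        rows = [("A", "TRUS12", r, 5.0, 10.0, True) for r in range(4)]
        rows += [("B", "TRUS12", r, 0.0, 0.0, False) for r in range(4)]
        assert sensitivity(results_frame(rows), cohort, "all") == 0.5

    def test_benign_only_cohort_is_undefined(self):
        cohort = [
            make_model(
                [spherical_lesion([0, -3, 0], 6.2, is_false_target=True)],
                model_id="Bg",
            )
        ]
        df = results_frame([("Bg", "TARGETED_3", 0, 0.0, 0.0, False)])
        with pytest.raises(EmptyStratumError):
            sensitivity(df, cohort, "all")

    def test_ever_rule_saturates(self):
        cohort = self._cohort()
        rows = [("A", "TRUS12", r, 5.0, 10.0, r == 0) for r in range(10)]
        rows += [("B", "TRUS12", r, 5.0, 10.0, True) for r in range(10)]
        df = results_frame(rows)
        assert sensitivity(df, cohort, "all", rule="ever") == 1.0
        assert sensitivity(df, cohort, "all") == pytest.approx(0.55)


class TestAttributionRate:
    def _cohort(self):
        return [
            make_model([spherical_lesion([0, -3, 0], 6.2, gleason="7")], model_id="A"),
            make_model([spherical_lesion([0, -3, 0], 6.2, gleason="7")], model_id="B"),
        ]

    def test_all_high_gives_one(self):
        df = results_frame(
            [(m, "TARGETED_4", r, 9.0, 75.0, True) for m in "AB" for r in range(4)]
        )
        assert attribution_rate(df, self._cohort()) == 1.0

    def test_majority_rule_definition(self):
        # 251 of 500 high repetitions -> counted high under majority rule
        rows = [("A", "TARGETED_4", r, 9.0 if r < 251 else 0.0, 0.0, True)
                for r in range(500)]
        rows += [("B", "TARGETED_4", r, 0.0, 0.0, False) for r in range(500)]
        df = results_frame(rows)
        assert attribution_rate(df, self._cohort(), aggregation="majority") == 0.5

    def test_mean_rule_uses_per_case_means(self):
        # mean MCCL 3.0 (< 6) but every rep detected: low under mean rule
        rows = [("A", "TARGETED_4", r, 3.0, 25.0, True) for r in range(10)]
        rows += [("B", "TARGETED_4", r, 8.0, 25.0, True) for r in range(10)]
        df = results_frame(rows)
        assert attribution_rate(df, self._cohort(), aggregation="mean") == 0.5

    def test_forced_high_by_geometry(self):
        # zero error, 13 mm-chord lesion: every repetition has MCCL >= 6
        model = make_model([spherical_lesion([0, -2, 0], 6.5, gleason="7")],
                           model_id="G")
        df = run_cohort([model], ["TARGETED_1"], ErrorModel(total_sd=0.0), 10, seed=0)
        assert df.mccl.min() >= 6.0
        assert attribution_rate(df, [model]) == 1.0


class TestSummarize:
    def test_constant_results_collapse_order_stats(self):
        model = make_model([spherical_lesion([0, -3, 0], 6.2, gleason="7")],
                           model_id="A")
        df = results_frame([("A", "TRUS12", r, 4.0, 25.0, True) for r in range(5)])
        s = summarize(df, [model], strata=("all",))
        row = s.table.iloc[0]
        assert row.mccl_mean == row.mccl_median == row.mccl_p90 == 4.0
        assert row.mccl_sd == 0.0

    def test_order_statistics_match_direct_sort(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 15, 10)
        cohort = [
            make_model([spherical_lesion([0, -3, 0], 6.2)], model_id=f"M{i}")
            for i in range(10)
        ]
        df = results_frame(
            [(f"M{i}", "TRUS12", 0, v, 10.0, True) for i, v in enumerate(values)]
        )
        s = summarize(df, cohort, strata=("all",))
        row = s.table.iloc[0]
        assert row.mccl_median == pytest.approx(np.median(values))
        assert row.mccl_p90 == pytest.approx(np.percentile(values, 90))
        assert row.mccl_mean == pytest.approx(values.mean())

    def test_insignificant_stratum_all_low_under_trus(self, small_cohort):
        # the systematic scheme does not concentrate cores on the lesion, so
        # insignificant cases must classify low risk
        df = run_cohort(small_cohort, ["TRUS12"], ErrorModel(), 50, seed=9)
        try:
            rate = attribution_rate(df, small_cohort, stratum="insignificant")
        except EmptyStratumError:
            pytest.skip("no insignificant case in this cohort draw")
        assert rate == 0.0


class TestCompareStrategies:
    def _frames(self, shift=0.0, n=50):
        rng = np.random.default_rng(1)
        base = rng.uniform(0, 10, n)
        a = results_frame(
            [(f"M{i}", "TRUS12", 0, base[i], 10.0, True) for i in range(n)]
        )
        b = results_frame(
            [(f"M{i}", "TARGETED_4", 0, base[i] + shift, 10.0, True) for i in range(n)]
        )
        return a, b

    def test_identical_samples_give_null_statistics(self):
        a, b = self._frames(0.0)
        out = compare_strategies(a, b)
        assert out["mccl"]["t_stat"] == 0.0
        assert out["mccl"]["t_p"] == 1.0
        assert out["mccl"]["ks_stat"] == 0.0

    def test_shifted_pairs_highly_significant(self):
        a, b = self._frames(5.0)
        out = compare_strategies(a, b)
        assert out["mccl"]["t_p"] < 1e-4
        assert out["mccl"]["mean_diff"] == pytest.approx(5.0)

    def test_t_statistic_matches_textbook_formula(self):
        rng = np.random.default_rng(2)
        a, b = self._frames(2.0)
        noise = rng.normal(0, 1, 50)
        b.loc[:, "mccl"] = b.mccl + noise
        out = compare_strategies(a, b)
        d = (b.mccl.to_numpy() - a.mccl.to_numpy())
        t_direct = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert out["mccl"]["t_stat"] == pytest.approx(t_direct, abs=1e-10)

    def test_fewer_than_three_pairs_refused(self):
        a, b = self._frames(0.0, n=2)
        with pytest.raises(ValueError, match="at least 3"):
            compare_strategies(a, b)


class TestPerAxisConventionProperty:
    def test_insignificant_low_under_per_axis_error_convention(self, paper_cohort):
        """Under the per-axis reading of the 5 mm total error (per-axis SD
        5 mm), targeted sampling never lifts an insignificant case into the
        high-risk class at full cohort scale."""
        em = ErrorModel(sd_convention="per_axis")
        df = run_cohort(paper_cohort, ["TRUS12", "TARGETED_3", "TARGETED_4"], em,
                        100, seed=99)
        for strategy in ("TRUS12", "TARGETED_3", "TARGETED_4"):
            sub = df[df.strategy == strategy]
            assert attribution_rate(sub, paper_cohort, stratum="insignificant") == 0.0
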