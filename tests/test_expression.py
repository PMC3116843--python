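import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mirmeth.expression import (
    Concordance,
    DifferentialResult,
    ExpressionMatrix,
    classify_concordance,
    differential_expression,
    fdr_adjust,
    normalize_matrix,
    welch_test,
)
from mirmeth.intervals import GenomicInterval
from mirmeth.proximity import ProximityCall


def matrix(values, lines):
    df = pd.DataFrame(values)
    meta = pd.DataFrame({"cell_line": lines}, index=df.columns)
    return ExpressionMatrix(values=df, sample_meta=meta)


class TestNormalize:
    def _random(self, seed=0):
        rng = np.random.default_rng(seed)
        vals = {f"s{i}": rng.lognormal(4, 1, 50) for i in range(4)}
        return matrix(vals, ["A", "A", "B", "B"])

    def test_equal_medians_is_fixed_point(self):
        m = matrix({"s1": [1.0, 2, 3], "s2": [3.0, 2, 1]}, ["A", "B"])
        out = normalize_matrix(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_restores_scaled_sample_to_common_scale(self):
        m = self._random()
        scaled = ExpressionMatrix(
            m.values.assign(s0=m.values["s0"] * 2), m.sample_meta
        )
        out = normalize_matrix(scaled)
        ref = normalize_matrix(m)
        # the doubled sample is brought back to the others' scale: its
        # values relative to any untouched sample match the unscaled run
        assert np.allclose(
            out.values["s0"] / out.values["s1"],
            ref.values["s0"] / ref.values["s1"],
            rtol=1e-9,
        )
        medians = out.values.median(axis=0)
        assert np.allclose(medians, medians.iloc[0], rtol=1e-9)

    def test_per_sample_medians_equal_after_normalization(self):
        out = normalize_matrix(self._random(3))
        medians = out.values.median(axis=0)
        assert np.allclose(medians, medians.iloc[0])
        assert out.normalized_by == "median_scaling"

    def test_all_zero_sample_fails_with_name(self):
        m = matrix({"good": [1.0, 2, 3], "dead": [0.0, 0, 0]}, ["A", "B"])
        with pytest.raises(ValueError, match="dead"):
            normalize_matrix(m)


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_test([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0 and p == pytest.approx(1.0)

    def test_matches_textbook_formulas(self):
        x, y = np.array([1.0, 2, 3]), np.array([2.0, 3, 4])
        # independent hand computation of the Welch statistic
        se2 = x.var(ddof=1) / 3 + y.var(ddof=1) / 3
        t_hand = (x.mean() - y.mean()) / math.sqrt(se2)
        df_hand = se2**2 / (
            (x.var(ddof=1) / 3) ** 2 / 2 + (y.var(ddof=1) / 3) ** 2 / 2
        )
        p_hand = 2 * stats.t.sf(abs(t_hand), df_hand)
        t, df, p = welch_test(x, y)
        assert t == pytest.approx(t_hand)
        assert df == pytest.approx(df_hand)  # = 4 exactly here
        assert p == pytest.approx(p_hand)

    def test_degenerate_zero_variance(self):
        assert welch_test([2.0, 2, 2], [2.0, 2, 2])[2] == 1.0
        assert welch_test([2.0, 2, 2], [3.0, 3, 3])[2] == 0.0

    def test_null_type_one_error_calibrated(self):
        """Size within 0.05 +/- 0.01 at n=10; conservative (never above
        nominal) at the triplicate scale, where Welch's approximation
        under-rejects by construction."""
        rng = np.random.default_rng(42)
        n_sim = 10_000
        x = rng.normal(size=(n_sim, 10))
        y = rng.normal(size=(n_sim, 10))
        rejections = sum(welch_test(x[i], y[i])[2] < 0.05 for i in range(n_sim))
        assert abs(rejections / n_sim - 0.05) < 0.01
        x3 = rng.normal(size=(2000, 3))
        y3 = rng.normal(size=(2000, 3))
        rate3 = np.mean([welch_test(x3[i], y3[i])[2] < 0.05 for i in range(2000)])
        assert rate3 <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / 2000)


class TestFDR:
    def test_single_p_unchanged(self):
        assert fdr_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_enumeration_example(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_matches_direct_step_up_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.random(rng.integers(1, 40))
            n = len(p)
            order = np.argsort(p)
            # direct step-up: q_(i) = min_{j>=i} p_(j) * n / j
            q_sorted = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
            expected = np.empty(n)
            expected[order] = np.minimum(q_sorted, 1.0)
            assert np.allclose(fdr_adjust(p), expected)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_q_bounds(self, p):
        q = fdr_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-12) and np.all(q <= 1.0)

    def test_all_null_false_discovery_bounded(self):
        rng = np.random.default_rng(9)
        called = sum(
            (fdr_adjust(rng.random(50)) < 0.05).sum() for _ in range(400)
        )
        assert called / (400 * 50) <= 0.05


def call(mid="m1", retained=False):
    return ProximityCall(
        mirna_id=mid,
        methylated_in_reference=True,
        distance_reference=0,
        methylated_in_demethylated=retained,
        nearest_region=GenomicInterval("chr1", 0, 500),
    )


def dr(mid="m1", fold=2.0, p=0.001, q=0.01):
    return DifferentialResult(
        mirna_id=mid, mean_ref=100, mean_demeth=100 * fold,
        fold_change=fold, t_stat=5, df=4, p_value=p, q_value=q,
    )


class TestConcordance:
    def test_lost_methylation_with_upregulation(self):
        assert (
            classify_concordance(call(retained=False), dr(fold=1.6, p=0.01))
            == Concordance.CONSISTENT_UPREGULATED
        )

    def test_fold_boundary_inclusive(self):
        assert (
            classify_concordance(call(retained=False), dr(fold=1.5, p=0.01))
            == Concordance.CONSISTENT_UPREGULATED
        )

    def test_demethylated_but_still_silenced_is_inconsistent(self):
        # the screen's negative-control pattern: methylation lost in the
        # demethylated derivative yet expression unchanged
        assert (
            classify_concordance(call(retained=False), dr(fold=1.02, p=0.9, q=0.95))
            == Concordance.INCONSISTENT
        )

    def test_retained_and_silenced_is_consistent(self):
        assert (
            classify_concordance(call(retained=True), dr(fold=1.1, p=0.6, q=0.9))
            == Concordance.CONSISTENT_RETAINED_SILENCED
        )

    def test_retained_but_upregulated_is_inconsistent(self):
        assert (
            classify_concordance(call(retained=True), dr(fold=2.5, p=0.001))
            == Concordance.INCONSISTENT
        )

    def test_missing_expression_marks_untested(self):
        assert classify_concordance(call(), None) == Concordance.UNTESTED

    def test_fdr_gate_optional(self):
        borderline = dr(fold=3.0, p=0.01, q=0.11)
        assert (
            classify_concordance(call(), borderline)
            == Concordance.CONSISTENT_UPREGULATED
        )
        assert (
            classify_concordance(call(), borderline, use_fdr=True)
            == Concordance.INCONSISTENT
        )

    def test_mismatched_ids_rejected(self):
        with pytest.raises(ValueError):
            classify_concordance(call("a"), dr("b"))


class TestSensitivity:
    def test_planted_three_fold_reversal_detected(self):
        """Sensitivity >= 0.9 for fold 3, CV 0.1, triplicates (Monte-Carlo)."""
        rng = np.random.default_rng(12)
        sigma = np.sqrt(np.log1p(0.01))
        n_sim, hits = 400, 0
        for _ in range(n_sim):
            ref = 100 * rng.lognormal(-sigma**2 / 2, sigma, 3)
            dem = 300 * rng.lognormal(-sigma**2 / 2, sigma, 3)
            t, df, p = welch_test(ref, dem)
            fold = dem.mean() / ref.mean()
            result = classify_concordance(
                call(retained=False), dr(fold=fold, p=p, q=p)
            )
            hits += result == Concordance.CONSISTENT_UPREGULATED
        assert hits / n_sim >= 0.9


class TestDifferentialExpression:
    def test_group_means_and_q_values_join_up(self):
        m = matrix(
            {
                "a1": [10.0, 100], "a2": [12.0, 110], "a3": [11.0, 105],
                "b1": [30.0, 100], "b2": [33.0, 108], "b3": [31.0, 103],
            },
            ["A"] * 3 + ["B"] * 3,
        )
        m.values.index = ["up", "flat"]
        res = differential_expression(m, "A", "B")
        assert res["up"].fold_change == pytest.approx((94 / 3) / (33 / 3), rel=1e-9)
        assert res["flat"].fold_change == pytest.approx(1.0, rel=0.05)
        assert 0 <= res["up"].p_value <= res["up"].q_value <= 1

    def test_too_few_replicates_rejected(self):
        m = matrix({"a1": [1.0], "b1": [2.0]}, ["A", "B"])
        with pytest.raises(ValueError, match="replicates"):
            differential_expression(m, "A", "B")
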