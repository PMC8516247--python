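"""Behavioral statistics: baseline subtraction, tests and Bayes factors."""

import numpy as np
import pytest
from scipy import stats as sps

from tokensim.stats import (
    analyze_study,
    attach_decision_times,
    bayes_factor_paired,
    bayes_factor_ttest,
    decision_time,
    decision_times,
    normality_check,
    paired_comparison,
    summarize_subjects,
    two_sample_distribution_test,
)


def grid_bayes_factor(t, n, scale, width=60.0, num=200_001):
    """Independent dense-grid oracle for the JZS Bayes factor.

    Trapezoid integration of the noncentral-t likelihood against the
    Cauchy(0, scale) prior over the standardized effect size.
    """
    delta = np.linspace(-width * scale, width * scale, num)
    prior = sps.cauchy.pdf(delta, 0.0, scale)
    like = sps.nct.pdf(t, n - 1, delta * np.sqrt(n))
    marginal = np.trapezoid(like * prior, delta)
    return marginal / sps.t.pdf(t, n - 1)


class TestDecisionTime:
    def test_simple_subtraction(self):
        assert decision_time(1.812, 0.347) == pytest.approx(1.465)

    def test_zero_or_negative_is_invalid(self):
        with pytest.raises(ValueError):
            decision_time(0.347, 0.347)

    def test_vectorized_invalid_becomes_nan(self):
        out = decision_times([1.0, 0.3], [0.347, 0.347])
        assert out[0] == pytest.approx(0.653)
        assert np.isnan(out[1])


class TestPairedComparison:
    def test_identical_pairs_give_null(self):
        t, p = paired_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_constant_shift_detected(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1.5, 0.3, 15)
        t, p = paired_comparison(a + 0.2, a)
        assert t > 0 and p < 1e-10

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_comparison([1.0, 2.0], [1.0])
        with pytest.raises(ValueError):
            paired_comparison([1.0], [2.0])


class TestBayesFactor:
    @pytest.mark.parametrize("scale", [3.0, 0.707])
    def test_matches_dense_grid_oracle(self, scale):
        rng = np.random.default_rng(1)
        for _ in range(10):
            d = rng.normal(rng.uniform(-0.8, 0.8), 1.0, 15)
            t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
            bf = bayes_factor_ttest(float(t), 15, scale)
            oracle = grid_bayes_factor(float(t), 15, scale)
            assert bf == pytest.approx(oracle, rel=1e-4)

    def test_null_data_favor_null(self):
        rng = np.random.default_rng(2)
        d = rng.normal(0.0, 1.0, 15)
        d = d - d.mean() + 0.01  # nearly zero effect
        assert bayes_factor_paired(d, scale=3.0) < 1.0

    def test_strong_effect_favors_alternative(self):
        d = np.array([1.0, 1.2, 0.9, 1.1, 1.05, 0.95, 1.15, 0.9, 1.0, 1.1,
                      1.2, 0.85, 1.0, 1.05, 0.95])
        assert bayes_factor_paired(d, scale=0.707) > 3.0

    def test_prior_collapse_approaches_one(self):
        d = np.array([0.3, -0.2, 0.5, 0.1, -0.4, 0.2, 0.0, 0.3, -0.1, 0.25])
        assert bayes_factor_paired(d, scale=1e-4) == pytest.approx(1.0, abs=1e-3)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            bayes_factor_paired(np.full(10, 0.3))

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        d = rng.normal(0.4, 1.0, 15)
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        ours = bayes_factor_ttest(float(t), 15, 0.707)
        theirs = float(pingouin.bayesfactor_ttest(t, 15, paired=True, r=0.707))
        assert ours == pytest.approx(theirs, rel=1e-3)


class TestDistributionTests:
    def test_shapiro_wrapper(self):
        rng = np.random.default_rng(4)
        w, p = normality_check(rng.normal(size=100))
        assert 0 <= p <= 1 and w <= 1

    def test_skewed_samples_rejected_as_normal(self):
        rng = np.random.default_rng(5)
        rejections = sum(
            normality_check(rng.exponential(size=80))[1] < 0.05 for _ in range(20)
        )
        assert rejections >= 18

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            normality_check([1.0, 2.0])  # n < 3
        with pytest.raises(ValueError):
            normality_check(np.full(10, 2.0))  # constant

    def test_ks_identical_and_disjoint(self):
        a = np.arange(10.0)
        d0, _ = two_sample_distribution_test(a, a)
        assert d0 == 0.0
        d1, p1 = two_sample_distribution_test(a, a + 100.0)
        assert d1 == 1.0 and p1 < 1e-4

    def test_ks_matches_ecdf_sweep(self):
        rng = np.random.default_rng(6)
        a = rng.exponential(1.0, 200)
        b = rng.exponential(1.5, 150) + 0.1
        d, _ = two_sample_distribution_test(a, b)
        grid = np.sort(np.concatenate([a, b]))
        ecdf_a = np.searchsorted(np.sort(a), grid, side="right") / len(a)
        ecdf_b = np.searchsorted(np.sort(b), grid, side="right") / len(b)
        assert d == pytest.approx(np.max(np.abs(ecdf_a - ecdf_b)), abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            two_sample_distribution_test([], [1.0])


class TestSummaries:
    def _toy_decisions(self):
        import pandas as pd

        rng = np.random.default_rng(7)
        rows = []
        for subject in range(4):
            for condition in ("all_stay", "all_away"):
                for ttype, base in (("easy", 1.2), ("ambiguous", 1.6)):
                    for _ in range(30):
                        dt = rng.normal(base, 0.1)
                        rows.append(
                            {
                                "subject_id": subject,
                                "condition": condition,
                                "trial_type": ttype,
                                "dt_ms": dt * 1000,
                                "raw_rt_s": dt + 0.35,
                                "correct": rng.random() < 0.8,
                                "sp_at_dt": rng.uniform(0.55, 0.95),
                            }
                        )
        decisions = pd.DataFrame(rows)
        baseline = pd.DataFrame(
            {"subject_id": range(4), "baseline_rt_s": [0.35] * 4}
        )
        return decisions, baseline

    def test_summary_invariant_to_trial_order(self):
        decisions, baseline = self._toy_decisions()
        withdt = attach_decision_times(decisions, baseline)
        s1 = summarize_subjects(withdt)
        s2 = summarize_subjects(
            withdt.sample(frac=1.0, random_state=11).reset_index(drop=True)
        )
        key = ["subject_id", "condition", "trial_type", "n_trials"]
        assert s1[key].equals(s2[key])
        for col in ("mean_dt_s", "sem_dt_s", "mean_sp", "sem_sp"):
            # summation order may differ; values agree to float tolerance
            np.testing.assert_allclose(s1[col], s2[col], rtol=1e-12)

    def test_baseline_subtraction_recovers_model_dts(self):
        decisions, baseline = self._toy_decisions()
        withdt = attach_decision_times(decisions, baseline)
        assert np.allclose(withdt["dt_s"], withdt["dt_ms"] / 1000.0)

    def test_analysis_battery_detects_easy_ambiguous_gap(self):
        decisions, baseline = self._toy_decisions()
        report = analyze_study(decisions, baseline)
        gaps = [
            c for c in report["contrasts"]
            if c["type_a"] == "easy" and c["measure"] == "mean_dt_s"
        ]
        assert len(gaps) == 2  # one per condition
        for c in gaps:
            assert c["mean_a"] < c["mean_b"] and c["p"] < 0.01
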