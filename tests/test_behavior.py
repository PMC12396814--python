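"""Licking/velocity metrics and trial-wise ITI statistics."""

import numpy as np
import pandas as pd
import pytest

from ramplight.behavior import (
    anticipatory_lick_rate,
    average_prev_iti_beta,
    condition_comparison,
    delta_iti_analysis,
    filter_iri_outliers,
    lick_rate,
    lick_slope,
    onset_velocity_change,
    pooled_zscore_beta,
    pre_reward_velocity,
    previous_iti_beta,
    velocity_trace,
)


class TestLicking:
    def test_two_licks_one_bin(self):
        t, r = lick_rate([0.52, 0.58], t_end=1.0)
        assert r[5] == pytest.approx(20.0)

    def test_no_licks_all_zero(self):
        _, r = lick_rate([], t_end=2.0)
        assert np.all(r == 0)

    def test_poisson_rate_recovered(self):
        rng = np.random.default_rng(2)
        licks = np.cumsum(rng.exponential(1 / 7.0, 5000))  # 7 Hz
        _, r = lick_rate(licks)
        assert r.mean() == pytest.approx(7.0, rel=0.05)

    def test_anticipatory_subtraction(self):
        t = np.arange(0.05, 20, 0.1)
        r = np.where((t >= 12) & (t < 13), 6.0, 2.0)  # cue at 4, reward at 13
        assert anticipatory_lick_rate(t, r, 4.0) == pytest.approx(4.0)

    def test_uniform_licking_zero_anticipation(self):
        t = np.arange(0.05, 20, 0.1)
        assert anticipatory_lick_rate(t, np.full(t.size, 3.0), 4.0) == pytest.approx(0.0)

    def test_incomplete_coverage_dropped(self):
        t = np.arange(0.05, 5, 0.1)
        with pytest.warns(UserWarning):
            assert anticipatory_lick_rate(t, np.zeros(t.size), 4.0) is None

    def test_lick_slope_linear_and_constant(self):
        t = np.arange(0.05, 20, 0.1)
        assert lick_slope(t, 2.0 * t, 4.0) == pytest.approx(2.0)
        assert lick_slope(t, np.ones(t.size), 4.0) == pytest.approx(0.0)


class TestVelocity:
    def test_constant_speed(self):
        t = np.arange(0, 5, 0.05)
        vt, v = velocity_trace(10 * t, t)
        np.testing.assert_allclose(v, 10.0)

    def test_stationary(self):
        t = np.arange(0, 5, 0.05)
        _, v = velocity_trace(np.ones(t.size), t)
        np.testing.assert_allclose(v, 0.0)

    def test_nonuniform_sampling_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            velocity_trace([0, 1, 2], [0.0, 0.05, 0.2])

    def test_onset_change_and_pre_reward(self):
        t = np.arange(0, 10, 0.05)
        v = np.where(t >= 5, 8.0, 0.0)
        vt = t
        assert onset_velocity_change(vt, v, 5.0) == pytest.approx(8.0)
        assert onset_velocity_change(vt, np.full(t.size, 3.0), 5.0) == pytest.approx(0.0)
        assert pre_reward_velocity(vt, v, 9.0) == pytest.approx(8.0)


def _table(itis, slopes):
    return pd.DataFrame({"previous_iti_s": itis, "ramp_slope": slopes})


class TestPreviousITIRegression:
    def test_noiseless_beta_recovery(self):
        itis = np.linspace(6, 12, 50)
        rep = previous_iti_beta(_table(itis, 0.1 - 0.05 * itis))
        assert rep.beta == pytest.approx(-0.05, abs=1e-12)
        assert rep.intercept == pytest.approx(0.1, abs=1e-10)

    def test_null_world_beta_near_zero(self):
        rng = np.random.default_rng(5)
        itis = rng.uniform(6, 12, 400)
        rep = previous_iti_beta(_table(itis, rng.standard_normal(400)))
        assert abs(rep.beta) < 3 * rep.se

    def test_degenerate_iti_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            previous_iti_beta(_table(np.full(10, 8.0), np.arange(10.0)))

    def test_first_trial_nan_excluded(self):
        itis = np.array([np.nan, 6, 8, 10, 12.0])
        rep = previous_iti_beta(_table(itis, 1 - 0.1 * np.nan_to_num(itis)))
        assert rep.n == 4


class TestPooledZScore:
    def test_common_standardized_relation(self):
        """Two animals with the same standardized dependence but different
        raw means pool to that same standardized slope."""
        rng = np.random.default_rng(6)
        itis = rng.uniform(6, 12, 300)
        z_rel = -(itis - itis.mean()) / itis.std()  # standardized slope -1... in z units
        tables = {
            "m1": _table(itis, 5.0 + 2.0 * z_rel),
            "m2": _table(itis, -3.0 + 0.5 * z_rel),
        }
        rep = pooled_zscore_beta(tables)
        per_animal = previous_iti_beta(
            _table(itis, (z_rel - z_rel.mean()) / z_rel.std())
        )
        assert rep.beta == pytest.approx(per_animal.beta, rel=1e-9)

    def test_zscore_normalization(self):
        rng = np.random.default_rng(7)
        itis = rng.uniform(6, 12, 100)
        slopes = rng.standard_normal(100)
        z = (slopes - slopes.mean()) / slopes.std(ddof=0)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=0) == pytest.approx(1.0)

    def test_zero_variance_animal_excluded(self):
        rng = np.random.default_rng(8)
        itis = rng.uniform(6, 12, 50)
        tables = {
            "ok1": _table(itis, -0.04 * itis + 0.01 * rng.standard_normal(50)),
            "ok2": _table(itis, -0.04 * itis + 0.01 * rng.standard_normal(50)),
            "flat": _table(itis, np.full(50, 1.0)),
        }
        with pytest.warns(UserWarning, match="excluded"):
            rep = pooled_zscore_beta(tables)
        assert rep.n == 100

    def test_single_animal_rejected(self):
        with pytest.raises(ValueError):
            pooled_zscore_beta({"m1": _table(np.arange(10.0), np.arange(10.0))})


class TestDeltaAnalysis:
    def test_noiseless_delta_beta(self):
        itis = np.array([6, 10, 7, 11, 6, 9.0])
        out = delta_iti_analysis(_table(itis, -0.04 * itis))
        assert out["beta_delta"] == pytest.approx(-0.04, abs=1e-12)

    def test_category_means_ordering(self):
        rng = np.random.default_rng(9)
        itis = rng.uniform(6, 12, 500)
        out = delta_iti_analysis(_table(itis, -0.05 * itis + 0.02 * rng.standard_normal(500)))
        assert out["mean_delta_slope_decrease"] > out["mean_delta_slope_increase"]

    def test_null_world(self):
        rng = np.random.default_rng(10)
        out = delta_iti_analysis(
            _table(rng.uniform(6, 12, 600), rng.standard_normal(600))
        )
        assert abs(out["beta_delta"]) < 3 * out["report"].se

    def test_empty_category_is_nan(self):
        itis = np.array([8.0, 8.1, 8.2, 8.05, 8.15])
        out = delta_iti_analysis(_table(itis, itis * 0.1), category_threshold_s=1.0)
        assert np.isnan(out["mean_delta_slope_decrease"])
        assert np.isnan(out["mean_delta_slope_increase"])


class TestAveragePrevITI:
    def test_k1_equals_previous_iti_beta(self):
        rng = np.random.default_rng(11)
        itis = rng.uniform(6, 12, 80)
        tab = _table(itis, -0.03 * itis + 0.01 * rng.standard_normal(80))
        a = average_prev_iti_beta(tab, 1)
        b = previous_iti_beta(tab)
        assert a.beta == pytest.approx(b.beta)

    def test_attenuation_for_deeper_history(self):
        """If slope depends only on the single previous ITI, regressing on a
        k-back average attenuates beta by var(x)/var(mean_k) scaling.

        Oracle: with i.i.d. ITIs, cov(slope, mean_k) = beta*var(x)/k and
        var(mean_k) = var(x)/k, so the fitted coefficient stays ~beta, but
        the fit explains less variance; with correlated history the
        empirical check is that |beta_k| does not exceed |beta_1| much.
        """
        rng = np.random.default_rng(12)
        itis = rng.uniform(6, 12, 4000)
        tab = _table(itis, -0.04 * itis)
        b1 = average_prev_iti_beta(tab, 1).beta
        b3 = average_prev_iti_beta(tab, 3)
        # same point estimate scale, but much larger uncertainty
        assert abs(b1 - (-0.04)) < 1e-12
        assert b3.se > 2 * average_prev_iti_beta(tab, 1).se

    def test_k_exceeding_session_rejected(self):
        with pytest.raises(ValueError):
            average_prev_iti_beta(_table(np.arange(5.0), np.arange(5.0)), 10)


class TestIRIOutlierFilter:
    def test_all_equal_none_removed(self):
        assert filter_iri_outliers(np.full(20, 9.0)).size == 20

    def test_gross_outlier_removed(self):
        # oracle: mean = (100*10 + 1000)/101 = 19.80..., SD ~ 98.5;
        # |1000 - 19.8| ~ 9.9 SD -> removed; |10 - 19.8| ~ 0.1 SD -> kept
        iris = np.concatenate([np.full(100, 10.0), [1000.0]])
        kept = filter_iri_outliers(iris)
        assert kept.size == 100
        assert np.all(kept == 10.0)

    def test_within_one_sd_untouched(self):
        rng = np.random.default_rng(13)
        iris = 10 + rng.uniform(-0.5, 0.5, 50)
        assert filter_iri_outliers(iris).size == 50

    def test_single_pass_idempotent(self):
        rng = np.random.default_rng(14)
        # bounded scatter (max ~1.7 SD) so a second pass provably removes
        # nothing once the gross outliers are gone
        iris = np.concatenate([10 + rng.uniform(-1, 1, 200), [30.0, 40.0]])
        once = filter_iri_outliers(iris)
        twice = filter_iri_outliers(once)
        # idempotent under the original-distribution convention used here:
        # re-filtering the retained set removes nothing further at 3 SD
        assert twice.size == once.size


class TestConditionComparison:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0])
        out = condition_comparison(a, a.copy())
        assert out["mean_difference"] == 0.0
        assert np.isnan(out["p_value"]) or out["p_value"] > 0.9

    def test_large_effect_significant_at_n9(self):
        rng = np.random.default_rng(15)
        a = rng.normal(0.3, 0.05, 9)
        b = rng.normal(0.0, 0.05, 9)
        assert condition_comparison(a, b)["p_value"] < 0.05

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(16)
        a, b = rng.normal(1, 1, 9), rng.normal(0, 1, 9)
        ab = condition_comparison(a, b)
        ba = condition_comparison(b, a)
        assert ab["statistic"] == pytest.approx(-ba["statistic"])
        assert ab["p_value"] == pytest.approx(ba["p_value"])

    def test_too_few_animals_rejected(self):
        with pytest.raises(ValueError):
            condition_comparison([1.0], [2.0])
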