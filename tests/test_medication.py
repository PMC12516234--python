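import numpy as np
import pytest
from scipy import stats

from seizuresim.config import ConfigError, EffectModel
from seizuresim.medication import (
    apply_effect,
    build_outcomes,
    compute_outcome,
    sample_effect,
)


class TestSampleEffect:
    def test_degenerate_gaussian_is_constant(self, rng):
        model = EffectModel(mean_reduction=0.20, sd_reduction=0.0)
        e = sample_effect(model, rng, size=100)
        assert np.all(e == 0.20)

    def test_negative_fraction_matches_normal_cdf(self):
        # P(e < 0) = Phi(-mean/sd) = Phi(-2) at the default model
        model = EffectModel()
        e = sample_effect(model, np.random.default_rng(8), size=1_000_000)
        p = stats.norm.cdf(-2)
        se = np.sqrt(p * (1 - p) / e.size)
        assert abs(np.mean(e < 0) - p) < 3 * se

    def test_mean_matches_truncated_normal_moment(self):
        model = EffectModel()
        e = sample_effect(model, np.random.default_rng(9), size=1_000_000)
        se = model.sd_reduction / np.sqrt(e.size)
        assert abs(e.mean() - 0.20) < 3 * se
        assert e.max() <= 1.0


class TestApplyEffect:
    @pytest.mark.parametrize("mode", ["scale", "thin"])
    def test_zero_effect_is_identity(self, rng, mode):
        cf = rng.poisson(1.0, size=200)
        treated = apply_effect(cf, 0.0, rng, mode=mode)
        assert np.array_equal(np.asarray(treated, dtype=float), cf.astype(float))

    @pytest.mark.parametrize("mode", ["scale", "thin"])
    def test_full_suppression_gives_zero_diary(self, rng, mode):
        cf = rng.poisson(2.0, size=200)
        treated = apply_effect(cf, 1.0, rng, mode=mode)
        assert np.all(np.asarray(treated) == 0)

    def test_effect_above_one_rejected(self, rng):
        with pytest.raises(ConfigError):
            apply_effect(np.ones(10, dtype=int), 1.5, rng)

    @pytest.mark.parametrize("e", [0.0, 0.2, 0.5, 1.0])
    def test_thinning_conservation(self, e):
        # mean treated/counterfactual ratio -> 1 - e within 3 binomial SE
        rng = np.random.default_rng(31)
        cf = rng.poisson(1.0, size=(400, 84))
        total = cf.sum()
        treated = apply_effect(cf, e, rng, mode="thin")
        se = np.sqrt(total * e * (1 - e))
        assert abs(treated.sum() - (1 - e) * total) <= 3 * se + 1e-9

    def test_scale_mode_is_exact(self, rng):
        cf = rng.poisson(1.0, size=(5, 84))
        e = np.array([0.0, 0.2, 0.5, 1.0, -0.3])
        treated = apply_effect(cf, e, max_per_day=10)
        assert np.allclose(treated, np.minimum((1 - e)[:, None] * cf, 10))

    def test_negative_effect_augments_with_right_expectation(self):
        # e = -0.5 must add 50% extra events on average (thin mode)
        rng = np.random.default_rng(17)
        cf = rng.poisson(1.0, size=(2000, 84))
        treated = apply_effect(cf, -0.5, rng, mode="thin")
        total = cf.sum()
        se = np.sqrt(0.5 * total)  # Poisson augmentation SE
        assert abs(treated.sum() - 1.5 * total) < 3 * se
        assert np.all(treated >= cf)

    def test_thin_mode_requires_rng(self):
        with pytest.raises(ConfigError):
            apply_effect(np.ones(5, dtype=int), 0.2, mode="thin")


class TestComputeOutcome:
    def test_worked_example_4_to_6_vs_8_per_month(self):
        # baseline 4/28d, observed 6/28d, counterfactual 8/28d:
        # +50% vs baseline yet -25% vs counterfactual
        baseline = np.zeros(56, dtype=int)
        baseline[:8] = 1  # 8 seizures / 56 d = 4 per 28 d
        treated = np.zeros(84, dtype=int)
        treated[:18] = 1  # 18 / 84 d = 6 per 28 d
        cf = np.zeros(84, dtype=int)
        cf[:24] = 1  # 24 / 84 d = 8 per 28 d
        out = compute_outcome(baseline, treated, cf, e=0.25)
        assert out.baseline_sf == pytest.approx(4.0)
        assert out.observed_sf == pytest.approx(6.0)
        assert out.counterfactual_sf == pytest.approx(8.0)
        assert out.pct_change_baseline == pytest.approx(0.50)
        assert out.pct_change_cf == pytest.approx(-0.25)

    def test_observed_equals_counterfactual_gives_zero_change(self, rng):
        base = rng.poisson(0.3, size=56) + 1
        cf = rng.poisson(0.3, size=84)
        out = compute_outcome(base, cf, cf, e=0.0)
        assert out.pct_change_cf == 0.0

    def test_halving_gives_minus_fifty_percent(self):
        base = np.zeros(56, dtype=int)
        base[:20] = 1  # 10 per 28 d
        treated = np.zeros(84, dtype=int)
        treated[:15] = 1  # 5 per 28 d
        out = compute_outcome(base, treated, treated, e=0.0)
        assert out.pct_change_baseline == pytest.approx(-0.50)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            compute_outcome(np.zeros(56, dtype=int), np.ones(84, dtype=int),
                            np.ones(84, dtype=int), e=0.0)

    def test_cf_zero_observed_positive_is_inf_sentinel(self):
        base = np.ones(56, dtype=int)
        treated = np.zeros(84, dtype=int)
        treated[0] = 1
        out = compute_outcome(base, treated, np.zeros(84, dtype=int), e=-0.1)
        assert np.isinf(out.pct_change_cf)


class TestBuildOutcomes:
    def test_pairing_with_zero_effect(self, rng):
        counts = rng.poisson(0.5, size=(50, 140)) + (rng.random((50, 140)) < 0.1)
        out = build_outcomes(counts, np.zeros(50), rng)
        assert np.allclose(out["observed_sf"], out["counterfactual_sf"])
        assert np.allclose(out["pct_change_cf"], 0.0)
        assert np.allclose(
            out["pct_change_baseline"], out["pct_change_baseline_cf"]
        )

    def test_scale_mode_true_change_equals_minus_e(self, rng):
        counts = rng.poisson(0.5, size=(200, 140)) + 1
        e = rng.normal(0.2, 0.1, size=200)
        out = build_outcomes(counts, e, rng, mode="scale")
        assert np.allclose(out["pct_change_cf"], -e)

    def test_effect_recovery_across_patients(self, rng):
        # mean of (1 - observed/counterfactual) recovers mean_reduction
        # within 2 SE at n = 10,000 (thin mode: stochastic application)
        n = 10_000
        counts = rng.poisson(0.4, size=(n, 140)) + 1
        model = EffectModel()
        e = sample_effect(model, rng, size=n)
        out = build_outcomes(counts, e, rng, mode="thin")
        ok = out["counterfactual_sf"] > 0
        est = np.mean(1 - out.loc[ok, "observed_sf"] / out.loc[ok, "counterfactual_sf"])
        se = np.std(1 - out.loc[ok, "observed_sf"] / out.loc[ok, "counterfactual_sf"],
                    ddof=1) / np.sqrt(ok.sum())
        assert abs(est - model.mean_reduction) < 2 * se
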