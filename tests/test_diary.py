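import numpy as np
import pytest

from seizuresim.config import PopulationConfig
from seizuresim.diary import (
    PatientParams,
    dispersion_for_rate,
    generate_diary,
    generate_population,
    sample_patient_params,
)

from conftest import fit_l_line


def _point_mass_config(**kw):
    """Degenerate population: every patient identical, no modulation."""
    defaults = dict(
        rate_log_sd=0.0,
        rate_log_mean=np.log(0.1),
        weekly_cycle_prob=0.0,
        monthly_cycle_prob=0.0,
        slow_cycle_prob=0.0,
        cluster_prob=0.0,
        l_jitter_sd=0.0,
    )
    defaults.update(kw)
    return PopulationConfig(**defaults)


class TestSamplePatientParams:
    def test_point_mass_rate_distribution(self, rng):
        cfg = _point_mass_config()
        params = [sample_patient_params(cfg, rng) for _ in range(20)]
        assert all(np.isclose(p.base_rate, 0.1) for p in params)
        assert all(p.cycle_set == [] for p in params)
        assert all(p.cluster_boost == 1.0 for p in params)

    def test_determinism_under_fixed_seed(self):
        cfg = PopulationConfig()
        a = [sample_patient_params(cfg, np.random.default_rng(7)) for _ in range(5)]
        b = [sample_patient_params(cfg, np.random.default_rng(7)) for _ in range(5)]
        assert a == b

    def test_invalid_params_rejected(self):
        with pytest.raises(Exception):
            PatientParams(base_rate=-1.0, dispersion=1.0).validate()
        with pytest.raises(Exception):
            PatientParams(base_rate=1.0, dispersion=1.0,
                          cycle_set=[(7.0, 1.0, 0.0)]).validate()


class TestGenerateDiary:
    def test_zero_rate_limit_gives_all_zero_diary(self, rng):
        p = PatientParams(base_rate=1e-12, dispersion=np.inf)
        diary = generate_diary(p, 500, rng)
        assert diary.counts.sum() == 0

    def test_poisson_limit_mean_matches_closed_form(self, rng):
        # dispersion -> inf reduces the law to Poisson(base_rate): the sample
        # mean over n days must sit within 3 closed-form standard errors.
        lam, n_days = 0.5, 10_000
        p = PatientParams(base_rate=lam, dispersion=np.inf, max_per_day=1000)
        diary = generate_diary(p, n_days, rng)
        se = np.sqrt(lam / n_days)
        assert abs(diary.counts.mean() - lam) < 3 * se

    def test_cap_enforced_every_day(self, rng):
        p = PatientParams(base_rate=5.0, dispersion=0.5, max_per_day=1)
        diary = generate_diary(p, 300, rng)
        assert set(np.unique(diary.counts)) <= {0, 1}

    def test_null_config_has_no_autocorrelation(self):
        # no cycles + no clustering => i.i.d. daily counts; ACF at lags 1..5
        # indistinguishable from 0 (alpha=0.01, Bonferroni over 5 lags)
        from scipy import stats

        p = PatientParams(base_rate=0.3, dispersion=2.0, max_per_day=10)
        diary = generate_diary(p, 10_000, np.random.default_rng(3))
        x = diary.counts.astype(float) - diary.counts.mean()
        denom = (x**2).sum()
        z_crit = stats.norm.ppf(1 - 0.01 / (2 * 5))
        for lag in range(1, 6):
            r = (x[:-lag] * x[lag:]).sum() / denom
            assert abs(r) < z_crit / np.sqrt(len(x)), f"lag {lag}: r={r}"

    def test_clustering_induces_positive_lag1_autocorrelation(self):
        p = PatientParams(base_rate=0.3, dispersion=2.0, cluster_boost=3.0,
                          max_per_day=10)
        diary = generate_diary(p, 10_000, np.random.default_rng(3))
        x = diary.counts.astype(float) - diary.counts.mean()
        r1 = (x[:-1] * x[1:]).sum() / (x**2).sum()
        assert r1 > 3 / np.sqrt(len(x))


class TestGeneratePopulation:
    def test_empty_population(self):
        cfg = PopulationConfig(n_patients=0)
        pop = generate_population(cfg, 1)
        assert len(pop) == 0

    def test_determinism_bit_identical(self):
        cfg = PopulationConfig(n_patients=200)
        a = generate_population(cfg, np.random.default_rng(11))
        b = generate_population(cfg, np.random.default_rng(11))
        assert np.array_equal(a.counts, b.counts)
        assert a.params_table.equals(b.params_table)

    def test_shapes_cap_and_pairing(self):
        cfg = PopulationConfig(n_patients=300, n_days=140)
        pop = generate_population(cfg, 5)
        assert pop.counts.shape == (300, 140)
        assert pop.counts.min() >= 0
        assert pop.counts.max() <= cfg.max_per_day
        params, diary = pop[17]
        assert diary.patient_id == 17
        assert np.array_equal(diary.counts, pop.counts[17])
        params.validate()

    def test_long_frame_roundtrip(self):
        cfg = PopulationConfig(n_patients=4, n_days=60)
        pop = generate_population(cfg, 0)
        long = pop.to_long_frame()
        assert len(long) == 4 * 60
        wide = long.pivot(index="patient_id", columns="day_index", values="count")
        assert np.array_equal(wide.to_numpy(), pop.counts)


class TestLRelationship:
    def test_dispersion_solver_hits_target_variance(self):
        # closed form: Var(28d) = M + M^2 / (28 r) must equal the L-line target
        lam = np.array([0.05, 0.2, 1.0])
        r = dispersion_for_rate(lam, 0.7, 0.14)
        m = 28 * lam
        target = (10**0.14 * m**0.7) ** 2
        achieved = m + m**2 / (28 * r)
        assert np.allclose(achieved, target)

    def test_slope_and_intercept_recovered_on_output(self):
        # Core count law (cap non-binding, no cycles/clusters): the OLS fit
        # on simulated 28-day counts must recover the configured line within
        # 2 fitted standard errors.
        cfg = PopulationConfig(
            n_patients=5000,
            n_days=28 * 50,
            weekly_cycle_prob=0.0,
            monthly_cycle_prob=0.0,
            slow_cycle_prob=0.0,
            cluster_prob=0.0,
            l_jitter_sd=0.0,
            max_per_day=10_000,
        )
        pop = generate_population(cfg, np.random.default_rng(7))
        intercept, slope, se_i, se_s = fit_l_line(pop.counts, 50)
        assert abs(slope - cfg.l_slope) < 2 * se_s
        assert abs(intercept - cfg.l_intercept) < 2 * se_i
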