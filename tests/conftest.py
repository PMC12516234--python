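import numpy as np
import pytest

import seizuresim as ss


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_study():
    """A reduced study run shared across tests: 10k patients, 200 trials."""
    cfg = ss.StudyConfig()
    cfg.population.n_patients = 10_000
    cfg.trials.n_trials = 200
    return ss.run_study(cfg, seed=99)


@pytest.fixture(scope="session")
def full_study():
    """The full-scale study (100k diaries, 10k trials); takes ~10-30 s."""
    return ss.run_study(seed=20)


def fit_l_line(counts: np.ndarray, n_windows: int):
    """Independent OLS oracle for the L-relationship on diary output.

    Splits each diary into 28-day windows, estimates each patient's
    mean/variance of window counts, and regresses log10(SD) on
    log10(mean) with a delta-method correction for the small-sample bias
    of the log variance.  Returns (intercept, slope, se_intercept,
    se_slope).
    """
    import statsmodels.api as sm

    k = n_windows
    w = counts[:, : 28 * k].reshape(counts.shape[0], k, 28).sum(axis=2).astype(float)
    m = w.mean(axis=1)
    s2 = w.var(axis=1, ddof=1)
    dev = w - m[:, None]
    m4 = (dev**4).mean(axis=1)
    var_s2 = (m4 - (k - 3) / (k - 1) * s2**2) / k
    ok = (m > 0) & (s2 > 0)
    y = 0.5 * (np.log10(s2[ok]) + var_s2[ok] / (2 * s2[ok] ** 2) / np.log(10))
    X = sm.add_constant(np.log10(m[ok]))
    fit = sm.OLS(y, X).fit()
    return fit.params[0], fit.params[1], fit.bse[0], fit.bse[1]
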