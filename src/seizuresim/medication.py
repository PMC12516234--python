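"""Heterogeneous medication effect and paired counterfactual outcomes.

The drug-free diary is generated once per patient and kept as the
counterfactual.  The on-drug treatment-period series is derived from it,
so both trajectories share realized noise and the paired comparison
isolates the drug effect from natural SF variability.  Two application
mechanisms are provided:

* ``"scale"`` (default): the effect acts on the seizure frequency itself —
  every counterfactual daily count is multiplied by ``1 - e``
  deterministically.  The true percent change vs the counterfactual is
  then exactly ``-e``.
* ``"thin"``: event-level binomial thinning — each counterfactual seizure
  is independently retained with probability ``1 - e``; for ``e < 0``
  (true drug-induced worsening) each day is augmented with extra Poisson
  events of expectation ``|e|`` times the realized counterfactual count,
  re-capped at the daily maximum.  This keeps the treated diary integer-
  valued at the cost of binomial noise in the true comparison.

Both satisfy ``E[treated] = (1 - e) * E[counterfactual]`` day by day.

Seizure frequencies are normalized to per-28-day rates: the 8-week
baseline contains two 28-day windows, the 12-week treatment period three.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigError, EffectModel

__all__ = [
    "EffectModel",
    "PatientOutcome",
    "sample_effect",
    "apply_effect",
    "compute_outcome",
    "build_outcomes",
]

BASELINE_DAYS = 56
TREATMENT_DAYS = 84
_WINDOW = 28.0


@dataclass
class PatientOutcome:
    """Per-patient endpoint summary, observed and counterfactual."""

    patient_id: int
    true_effect: float
    baseline_sf: float  # seizures per 28 days, days 0..55
    observed_sf: float  # per 28 days on drug, days 56..139
    counterfactual_sf: float  # per 28 days without drug, days 56..139
    pct_change_baseline: float  # (observed - baseline) / baseline
    pct_change_cf: float  # (observed - counterfactual) / counterfactual


def sample_effect(
    model: EffectModel, rng: np.random.Generator, size: int | None = None
) -> float | np.ndarray:
    """Draw per-patient fractional SF reductions.

    Normal(mean_reduction, sd_reduction) truncated above at 1 by rejection
    (under the default model the mass above 1 is ~1e-15, so the truncation
    is a formality of the retention-probability constraint).  Negative
    draws — true worsening — are allowed.
    """
    model.validate()
    n = 1 if size is None else int(size)
    e = rng.normal(model.mean_reduction, model.sd_reduction, size=n)
    bad = e > 1.0
    while bad.any():
        e[bad] = rng.normal(model.mean_reduction, model.sd_reduction, size=int(bad.sum()))
        bad = e > 1.0
    return float(e[0]) if size is None else e


def apply_effect(
    counterfactual_counts: np.ndarray,
    e: float | np.ndarray,
    rng: np.random.Generator | None = None,
    max_per_day: int | None = None,
    mode: str = "scale",
) -> np.ndarray:
    """Derive the on-drug counts from the realized counterfactual counts.

    Accepts a single diary (1-D) or a (patients x days) matrix with a
    per-patient effect vector.  ``mode="scale"`` multiplies counts by
    ``1 - e`` deterministically (float output); ``mode="thin"`` performs
    binomial thinning / Poisson augmentation (integer output, needs
    ``rng``).  Expectation contract before capping, either way:
    ``E[treated] = (1 - e) * E[counterfactual]`` day by day.
    """
    cf = np.asarray(counterfactual_counts)
    single = cf.ndim == 1
    cf2 = np.atleast_2d(cf)
    ev = np.atleast_1d(np.asarray(e, dtype=float)).reshape(-1, 1)
    if np.any(ev > 1.0):
        raise ConfigError("effect e must be <= 1")
    if ev.shape[0] == 1 and cf2.shape[0] > 1:
        ev = np.broadcast_to(ev, (cf2.shape[0], 1))

    if mode == "scale":
        treated = (1.0 - ev) * cf2
        if max_per_day is not None:
            np.minimum(treated, float(max_per_day), out=treated)
        return treated[0] if single else treated
    if mode != "thin":
        raise ConfigError(f"unknown effect application mode {mode!r}")
    if rng is None:
        raise ConfigError("mode='thin' requires an rng")

    treated = cf2.copy()
    pos = ev[:, 0] >= 0
    if pos.any():
        keep = 1.0 - ev[pos]
        treated[pos] = rng.binomial(cf2[pos], np.broadcast_to(keep, cf2[pos].shape))
    neg = ~pos
    if neg.any():
        extra = rng.poisson(np.abs(ev[neg]) * cf2[neg])
        treated[neg] = cf2[neg] + extra
        if max_per_day is not None:
            np.minimum(treated[neg], max_per_day, out=treated[neg])
    return treated[0] if single else treated


def _sf(total: np.ndarray, days: float) -> np.ndarray:
    return np.asarray(total, dtype=float) * (_WINDOW / days)


def _pct_change_cf(observed_sf, counterfactual_sf) -> np.ndarray:
    obs = np.asarray(observed_sf, dtype=float)
    cf = np.asarray(counterfactual_sf, dtype=float)
    out = np.zeros_like(obs)
    nz = cf > 0
    out[nz] = (obs[nz] - cf[nz]) / cf[nz]
    # counterfactual-free patient who seized on drug: unambiguous worsening
    out[~nz & (obs > 0)] = np.inf
    return out


def compute_outcome(
    baseline_counts: np.ndarray,
    treated_counts: np.ndarray,
    counterfactual_counts: np.ndarray,
    e: float,
    patient_id: int = 0,
) -> PatientOutcome:
    """Summarize one patient: SF per 28 days and percent changes."""
    baseline_counts = np.asarray(baseline_counts)
    b = float(_sf(baseline_counts.sum(), baseline_counts.shape[0]))
    if b <= 0:
        raise ValueError("baseline_sf must be > 0 (eligibility guarantees it)")
    obs = float(_sf(np.sum(treated_counts), len(treated_counts)))
    cf = float(_sf(np.sum(counterfactual_counts), len(counterfactual_counts)))
    return PatientOutcome(
        patient_id=patient_id,
        true_effect=float(e),
        baseline_sf=b,
        observed_sf=obs,
        counterfactual_sf=cf,
        pct_change_baseline=(obs - b) / b,
        pct_change_cf=float(_pct_change_cf([obs], [cf])[0]),
    )


def build_outcomes(
    counts: np.ndarray,
    effects: np.ndarray,
    rng: np.random.Generator | None = None,
    baseline_days: int = BASELINE_DAYS,
    max_per_day: int | None = None,
    patient_ids: np.ndarray | None = None,
    mode: str = "scale",
) -> pd.DataFrame:
    """Vectorized outcome table for an eligible pool.

    ``counts`` is the full drug-free diary matrix (patients x n_days);
    days ``baseline_days..`` form the counterfactual treatment period.
    Returns one row per patient with observed (on-drug), counterfactual and
    baseline SF plus both percent changes, and the placebo-arm percent
    change ``pct_change_baseline_cf`` (counterfactual vs own baseline).
    """
    counts = np.asarray(counts)
    n, n_days = counts.shape
    t_days = n_days - baseline_days
    cf_treat = counts[:, baseline_days:]
    treated = apply_effect(cf_treat, effects, rng, max_per_day=max_per_day, mode=mode)

    baseline_sf = _sf(counts[:, :baseline_days].sum(axis=1), baseline_days)
    observed_sf = _sf(treated.sum(axis=1), t_days)
    cf_sf = _sf(cf_treat.sum(axis=1), t_days)
    if np.any(baseline_sf <= 0):
        raise ValueError("baseline_sf must be > 0 for every patient in the pool")

    if patient_ids is None:
        patient_ids = np.arange(n)
    return pd.DataFrame(
        {
            "patient_id": np.asarray(patient_ids),
            "e": np.broadcast_to(np.asarray(effects, dtype=float), (n,)),
            "baseline_sf": baseline_sf,
            "observed_sf": observed_sf,
            "counterfactual_sf": cf_sf,
            "pct_change_baseline": (observed_sf - baseline_sf) / baseline_sf,
            "pct_change_cf": _pct_change_cf(observed_sf, cf_sf),
            "pct_change_baseline_cf": (cf_sf - baseline_sf) / baseline_sf,
        }
    )
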