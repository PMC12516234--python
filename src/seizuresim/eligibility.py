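"""Regulatory-trial inclusion screen on the 8-week baseline window.

A diary is eligible when the baseline window (days 0..baseline_days-1)
contains at least ``min_baseline_seizures`` events and no seizure-free run
strictly longer than ``max_seizure_free_days`` consecutive zero-count days.
Runs touching either edge of the baseline window count: a leading or
trailing gap is an observable seizure-free period.  Treatment-period days
are never consulted — enrollment cannot see the future.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import EligibilityRule
from .diary import Population, SeizureDiary

__all__ = [
    "EligibilityRule",
    "is_eligible",
    "max_zero_run",
    "screen_counts",
    "filter_population",
]

REASON_ELIGIBLE = "eligible"
REASON_TOO_FEW = "too_few_seizures"
REASON_LONG_GAP = "long_gap"


def max_zero_run(counts: np.ndarray) -> np.ndarray:
    """Longest run of consecutive zero-count days, per row.

    Accepts a 1-D diary or an (n_patients, n_days) matrix; returns a scalar
    array or a length-n vector.
    """
    arr = np.atleast_2d(np.asarray(counts))
    run = np.zeros(arr.shape[0], dtype=np.int64)
    best = np.zeros(arr.shape[0], dtype=np.int64)
    for t in range(arr.shape[1]):
        run = np.where(arr[:, t] == 0, run + 1, 0)
        np.maximum(best, run, out=best)
    return best if np.asarray(counts).ndim == 2 else best[0]


def screen_counts(
    counts: np.ndarray, rule: EligibilityRule
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized screen: (eligible mask, reason codes) for a counts matrix.

    When a diary fails both criteria the seizure-count criterion is
    reported (it is the one a coordinator checks first).
    """
    rule.validate()
    counts = np.asarray(counts)
    if counts.ndim != 2:
        raise ValueError("counts must be 2-D (patients x days)")
    if counts.shape[1] < rule.baseline_days:
        raise ValueError(
            f"diaries have {counts.shape[1]} days; "
            f"baseline needs {rule.baseline_days}"
        )
    base = counts[:, : rule.baseline_days]
    too_few = base.sum(axis=1) < rule.min_baseline_seizures
    long_gap = max_zero_run(base) > rule.max_seizure_free_days
    eligible = ~(too_few | long_gap)
    reason = np.where(
        eligible, REASON_ELIGIBLE, np.where(too_few, REASON_TOO_FEW, REASON_LONG_GAP)
    )
    return eligible, reason


def is_eligible(diary: SeizureDiary, rule: EligibilityRule) -> tuple[bool, str]:
    """Screen one diary; returns (eligible, reason_code)."""
    if diary.n_days < rule.baseline_days:
        raise ValueError(
            f"diary has {diary.n_days} days; baseline needs {rule.baseline_days}"
        )
    ok, reason = screen_counts(diary.counts[None, :], rule)
    return bool(ok[0]), str(reason[0])


def filter_population(
    population: Population, rule: EligibilityRule
) -> tuple[Population, pd.DataFrame]:
    """Apply the screen to a whole population.

    Returns the eligible subset (input order preserved) and a screening log
    with one row per input patient: (patient_id, eligible, reason_code).
    """
    if len(population) == 0:
        log = pd.DataFrame(columns=["patient_id", "eligible", "reason_code"])
        return population, log
    eligible, reason = screen_counts(population.counts, rule)
    log = pd.DataFrame(
        {
            "patient_id": population.params_table.index.to_numpy(),
            "eligible": eligible,
            "reason_code": reason,
        }
    )
    return population.subset(eligible), log
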