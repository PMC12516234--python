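"""Monte-Carlo randomized-trial engine.

Each simulated trial draws ``n_per_trial`` distinct patients from the
eligible pool without replacement, assigns every patient independently to
the ASM or placebo arm (Bernoulli with the configured allocation; a config
switch forces exactly balanced arms instead), and summarizes each arm on
the standard regulatory endpoints computed from percent change in 28-day
seizure frequency relative to the patient's own baseline:

* median percent reduction (median of ``-pct_change_baseline``),
* 50% responder rate (fraction with a reduction of at least 50%),
* fraction with any SF increase (``pct_change_baseline > 0``).

ASM-arm patients contribute their on-drug percent change; placebo-arm
patients contribute their drug-free (counterfactual) percent change —
the placebo "response" is pure regression to the mean induced by the
eligibility screen.  Patients may recur across trials, never within one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import TrialConfig

__all__ = ["TrialConfig", "ArmSummary", "TrialResult", "run_trial", "run_many"]

ARM_COLUMNS = [
    "median_pct_reduction",
    "responder_rate_50",
    "frac_any_increase",
    "n",
]


@dataclass
class ArmSummary:
    """Endpoint summary for one trial arm; NaN fields mean 'empty arm'."""

    n: int
    median_pct_reduction: float
    responder_rate_50: float
    frac_any_increase: float


@dataclass
class TrialResult:
    asm: ArmSummary
    placebo: ArmSummary


def _summarize_arm(pct_change: np.ndarray) -> ArmSummary:
    n = pct_change.shape[0]
    if n == 0:
        return ArmSummary(0, np.nan, np.nan, np.nan)
    return ArmSummary(
        n=n,
        median_pct_reduction=float(np.median(-pct_change)),
        responder_rate_50=float(np.mean(pct_change <= -0.50)),
        frac_any_increase=float(np.mean(pct_change > 0.0)),
    )


def _draw_trial(
    n_pool: int, config: TrialConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    idx = rng.choice(n_pool, size=config.n_per_trial, replace=False)
    if config.forced_balance:
        n_asm = int(round(config.allocation * config.n_per_trial))
        asm_mask = np.zeros(config.n_per_trial, dtype=bool)
        asm_mask[rng.choice(config.n_per_trial, size=n_asm, replace=False)] = True
    else:
        asm_mask = rng.random(config.n_per_trial) < config.allocation
    return idx, asm_mask


def run_trial(
    outcomes: pd.DataFrame, config: TrialConfig, rng: np.random.Generator
) -> TrialResult:
    """Simulate one randomized trial from the eligible outcome pool.

    ``outcomes`` must carry ``pct_change_baseline`` (on drug) and
    ``pct_change_baseline_cf`` (drug-free) columns, one row per eligible
    patient (see :func:`seizuresim.medication.build_outcomes`).
    """
    config.validate()
    n_pool = len(outcomes)
    if n_pool < config.n_per_trial:
        raise ValueError(
            f"eligible pool ({n_pool}) smaller than n_per_trial ({config.n_per_trial})"
        )
    asm_pc = outcomes["pct_change_baseline"].to_numpy()
    pbo_pc = outcomes["pct_change_baseline_cf"].to_numpy()
    idx, asm_mask = _draw_trial(n_pool, config, rng)
    return TrialResult(
        asm=_summarize_arm(asm_pc[idx[asm_mask]]),
        placebo=_summarize_arm(pbo_pc[idx[~asm_mask]]),
    )


def run_many(
    outcomes: pd.DataFrame, config: TrialConfig, rng: np.random.Generator | int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Simulate ``config.n_trials`` independent trials.

    Returns a per-trial table (one row per trial, per-arm endpoint columns
    prefixed ``asm_`` / ``placebo_``) and an aggregate dict with the mean
    of each endpoint across trials (NaN-empty arms excluded).
    """
    config.validate()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    rows = []
    for trial_id in range(config.n_trials):
        res = run_trial(outcomes, config, rng)
        row: dict = {"trial_id": trial_id}
        for arm_name, arm in (("asm", res.asm), ("placebo", res.placebo)):
            for col in ARM_COLUMNS:
                row[f"{arm_name}_{col}"] = getattr(arm, col)
        rows.append(row)
    table = pd.DataFrame(
        rows,
        columns=["trial_id"]
        + [f"{a}_{c}" for a in ("asm", "placebo") for c in ARM_COLUMNS],
    )
    aggregate = {
        col: float(np.nanmean(table[col])) if len(table) else np.nan
        for col in table.columns
        if col != "trial_id"
    }
    aggregate["n_trials"] = int(len(table))
    return table, aggregate
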