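"""Apparent-vs-true outcome classification and misclassification report.

"Apparent" outcomes compare the on-drug treatment SF with the patient's own
baseline — all a clinic can observe.  "True" outcomes compare it with the
paired counterfactual (the same window without the drug) — observable only
in simulation.  Default cut-offs:

* apparent worsening: SF increase of at least 25% from baseline;
* apparent response: SF reduction of at least 50% from baseline;
* true improvement: SF reduction of at least 10% vs the counterfactual
  (the minimal clinically meaningful drug benefit);
* true worsening: any SF increase (> 0%) vs the counterfactual.

True improvement / true non-response partition every pool; true worseners
are a subset of true nonresponders.  Fractions are computed over the full
eligible on-drug pool, not within individual trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ClassificationThresholds
from .medication import PatientOutcome

__all__ = [
    "ClassificationThresholds",
    "MisclassificationReport",
    "classify",
    "classify_table",
    "summarize",
]

FLAG_COLUMNS = [
    "apparent_worsener",
    "apparent_responder",
    "true_improver",
    "true_nonresponder",
    "true_worsener",
]


@dataclass
class MisclassificationReport:
    """Population fractions of apparent/true outcome categories.

    Conditional fractions are NaN when the conditioning set is empty.
    """

    n_total: int
    frac_apparent_worseners: float
    frac_true_improvers_among_apparent_worseners: float
    frac_true_worseners_among_apparent_worseners: float
    frac_apparent_responders: float
    frac_true_nonresponders_among_apparent_responders: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def classify(
    outcome: PatientOutcome,
    thresholds: ClassificationThresholds | None = None,
) -> set[str]:
    """Flag one patient; returns the set of category names that apply."""
    row = pd.DataFrame(
        {
            "pct_change_baseline": [outcome.pct_change_baseline],
            "pct_change_cf": [outcome.pct_change_cf],
        }
    )
    flags = classify_table(row, thresholds)
    return {c for c in FLAG_COLUMNS if bool(flags[c].iloc[0])}


def classify_table(
    outcomes: pd.DataFrame,
    thresholds: ClassificationThresholds | None = None,
) -> pd.DataFrame:
    """Vectorized classification: one boolean column per category.

    ``outcomes`` needs ``pct_change_baseline`` and ``pct_change_cf``
    columns; a ``+inf`` counterfactual change (seizures on drug, none
    without) classifies as a true worsener.
    """
    if thresholds is None:
        thresholds = ClassificationThresholds()
    thresholds.validate()
    pb = outcomes["pct_change_baseline"].to_numpy(dtype=float)
    pc = outcomes["pct_change_cf"].to_numpy(dtype=float)
    flags = pd.DataFrame(index=outcomes.index)
    flags["apparent_worsener"] = pb >= thresholds.apparent_worsening_min_increase
    flags["apparent_responder"] = pb <= -thresholds.apparent_response_min_reduction
    flags["true_improver"] = pc <= -thresholds.true_improvement_min_reduction
    flags["true_nonresponder"] = ~flags["true_improver"]
    flags["true_worsener"] = pc > thresholds.true_worsening_strict_increase
    return flags


def _cond_frac(flag: np.ndarray, given: np.ndarray) -> float:
    denom = int(given.sum())
    if denom == 0:
        return float("nan")
    return float((flag & given).sum() / denom)


def summarize(
    outcomes: pd.DataFrame,
    thresholds: ClassificationThresholds | None = None,
) -> MisclassificationReport:
    """Misclassification fractions over an eligible on-drug pool."""
    if len(outcomes) == 0:
        raise ValueError("outcome pool must be nonempty")
    flags = classify_table(outcomes, thresholds)
    aw = flags["apparent_worsener"].to_numpy()
    ar = flags["apparent_responder"].to_numpy()
    ti = flags["true_improver"].to_numpy()
    tn = flags["true_nonresponder"].to_numpy()
    tw = flags["true_worsener"].to_numpy()
    n = len(flags)
    return MisclassificationReport(
        n_total=n,
        frac_apparent_worseners=float(aw.mean()),
        frac_true_improvers_among_apparent_worseners=_cond_frac(ti, aw),
        frac_true_worseners_among_apparent_worseners=_cond_frac(tw, aw),
        frac_apparent_responders=float(ar.mean()),
        frac_true_nonresponders_among_apparent_responders=_cond_frac(tn, ar),
    )
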