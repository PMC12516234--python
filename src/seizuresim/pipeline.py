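"""End-to-end study orchestration, file products, and run manifest.

``run_study`` chains the stages — generate population, eligibility screen,
medication effect with paired counterfactual, Monte-Carlo trials,
misclassification report — under stage-scoped RNG streams spawned from one
root seed, so e.g. changing the trial count never perturbs diary
generation.  ``write_outputs`` persists every data product as CSV/JSON plus
a manifest with checksums; ``make_figures`` emits the plotting data
(per-trial any-increase histogram; apparent-vs-true percent-change scatter).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import MisclassificationReport, classify_table, summarize
from .config import StudyConfig, load_config, save_config
from .diary import Population, generate_population
from .eligibility import filter_population
from .medication import build_outcomes, sample_effect
from .trials import run_many

__all__ = ["StudyResult", "run_study", "write_outputs", "make_figures", "headline_stats"]

logger = logging.getLogger("seizuresim")

_STAGES = ("population", "effects", "trials")


@dataclass
class StudyResult:
    """Everything one study run produced, in memory."""

    config: StudyConfig
    population: Population
    screen_log: pd.DataFrame
    outcomes: pd.DataFrame  # one row per eligible patient
    trial_table: pd.DataFrame  # one row per simulated trial
    trial_aggregate: dict
    report: MisclassificationReport

    @property
    def n_eligible(self) -> int:
        return len(self.outcomes)


def _stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: np.random.default_rng(s) for name, s in zip(_STAGES, children)}


def run_study(
    config: StudyConfig | str | Path | None = None,
    seed: int | None = None,
) -> StudyResult:
    """Run the full simulation study and return all results in memory.

    ``config`` may be a StudyConfig, a YAML path, or None (calibrated
    defaults).  ``seed`` overrides ``config.rng_seed`` when given.
    """
    if config is None or isinstance(config, (str, Path)):
        config = load_config(config)
    config.validate()
    if seed is not None:
        config = dataclasses.replace(config, rng_seed=int(seed))
    rngs = _stage_rngs(config.rng_seed)

    logger.info("generating %d diaries (%d days)", config.population.n_patients,
                config.population.n_days)
    population = generate_population(config.population, rngs["population"])

    eligible, screen_log = filter_population(population, config.eligibility)
    logger.info("eligibility screen: %d / %d eligible", len(eligible), len(population))

    effects = sample_effect(config.effect, rngs["effects"], size=len(eligible))
    outcomes = build_outcomes(
        eligible.counts,
        effects,
        rngs["effects"],
        baseline_days=config.eligibility.baseline_days,
        max_per_day=config.population.max_per_day,
        patient_ids=eligible.params_table.index.to_numpy(),
        mode=config.effect.application,
    )

    trial_table, trial_aggregate = run_many(outcomes, config.trials, rngs["trials"])
    logger.info("simulated %d trials of %d patients", config.trials.n_trials,
                config.trials.n_per_trial)

    report = summarize(outcomes, config.thresholds)
    return StudyResult(
        config=config,
        population=population,
        screen_log=screen_log,
        outcomes=outcomes,
        trial_table=trial_table,
        trial_aggregate=trial_aggregate,
        report=report,
    )


def headline_stats(result: StudyResult) -> dict[str, float]:
    """The study's headline numbers, on the percent scale where applicable."""
    agg = result.trial_aggregate
    rep = result.report
    return {
        "n_eligible": result.n_eligible,
        "asm_median_reduction_pct": 100.0 * agg["asm_median_pct_reduction"],
        "placebo_median_reduction_pct": 100.0 * agg["placebo_median_pct_reduction"],
        "asm_responder_rate_pct": 100.0 * agg["asm_responder_rate_50"],
        "placebo_responder_rate_pct": 100.0 * agg["placebo_responder_rate_50"],
        "asm_any_increase_pct": 100.0 * agg["asm_frac_any_increase"],
        "placebo_any_increase_pct": 100.0 * agg["placebo_frac_any_increase"],
        "apparent_worsening_pct": 100.0 * rep.frac_apparent_worseners,
        "true_improvers_among_apparent_worseners_pct": 100.0
        * rep.frac_true_improvers_among_apparent_worseners,
        "true_worseners_among_apparent_worseners_pct": 100.0
        * rep.frac_true_worseners_among_apparent_worseners,
        "apparent_responders_pct": 100.0 * rep.frac_apparent_responders,
        "true_nonresponders_among_apparent_responders_pct": 100.0
        * rep.frac_true_nonresponders_among_apparent_responders,
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_outputs(
    result: StudyResult, out_dir: str | Path, write_diaries: bool = False
) -> Path:
    """Persist all study products under ``out_dir``; returns manifest path.

    Diaries are large (n_patients x n_days) and are only written on request.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    save_config(result.config, out / "config.yaml")
    result.screen_log.to_csv(out / "screen_log.csv", index=False)
    result.outcomes.to_csv(out / "outcomes.csv", index=False)
    result.trial_table.to_csv(out / "trials.csv", index=False)
    (out / "trial_aggregate.json").write_text(
        json.dumps(result.trial_aggregate, indent=2)
    )
    (out / "misclassification.json").write_text(
        json.dumps(result.report.to_dict(), indent=2)
    )
    flags = classify_table(result.outcomes, result.config.thresholds)
    pd.concat([result.outcomes[["patient_id"]], flags], axis=1).to_csv(
        out / "flags.csv", index=False
    )
    (out / "headline.json").write_text(json.dumps(headline_stats(result), indent=2))
    if write_diaries:
        result.population.to_long_frame().to_csv(
            out / "diaries_long.csv.gz", index=False, compression="gzip"
        )

    files = sorted(p for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "package_version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "rng_seed": result.config.rng_seed,
        "stage_seeds": {name: result.config.rng_seed for name in _STAGES},
        "config": str(out / "config.yaml"),
        "outputs": {p.name: _sha256(p) for p in files},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def make_figures(out_dir: str | Path, render: bool = False) -> list[Path]:
    """Emit figure data files from a completed run directory.

    * ``fig_any_increase_hist.csv`` — per-trial fraction of patients with
      any SF increase, per arm (histogram data across trials);
    * ``fig_apparent_vs_true_scatter.csv`` — per-patient apparent vs true
      percent change with misclassification flags.

    With ``render=True`` (requires matplotlib) PNG renderings are written
    alongside the data.
    """
    out = Path(out_dir)
    trials_path = out / "trials.csv"
    outcomes_path = out / "outcomes.csv"
    if not trials_path.exists() or not outcomes_path.exists():
        raise FileNotFoundError(
            f"run outputs not found under {out} (need trials.csv and outcomes.csv)"
        )
    written: list[Path] = []

    trials = pd.read_csv(trials_path)
    hist = trials[["trial_id", "asm_frac_any_increase", "placebo_frac_any_increase"]]
    hist_path = out / "fig_any_increase_hist.csv"
    hist.to_csv(hist_path, index=False)
    written.append(hist_path)

    outcomes = pd.read_csv(outcomes_path)
    flags = classify_table(outcomes)
    scatter = pd.concat(
        [outcomes[["patient_id", "pct_change_baseline", "pct_change_cf"]], flags],
        axis=1,
    )
    scatter_path = out / "fig_apparent_vs_true_scatter.csv"
    scatter.to_csv(scatter_path, index=False)
    written.append(scatter_path)

    if render:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        if len(hist):
            bins = np.linspace(0, 1, 41)
            ax.hist(hist["asm_frac_any_increase"], bins=bins, alpha=0.6, label="ASM")
            ax.hist(
                hist["placebo_frac_any_increase"], bins=bins, alpha=0.6, label="placebo"
            )
        ax.set_xlabel("fraction of arm with any SF increase")
        ax.set_ylabel("trials")
        ax.legend()
        p = out / "fig_any_increase_hist.png"
        fig.savefig(p, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(p)

        fig, ax = plt.subplots(figsize=(6, 6))
        finite = np.isfinite(scatter["pct_change_cf"])
        sc = scatter[finite]
        misw = sc["apparent_worsener"] & sc["true_improver"]
        misr = sc["apparent_responder"] & sc["true_nonresponder"]
        other = ~(misw | misr)
        for mask, color, label in (
            (other, "0.7", "other"),
            (misw, "tab:blue", "apparent worsener, true improver"),
            (misr, "tab:orange", "apparent responder, true nonresponder"),
        ):
            ax.scatter(
                100 * sc.loc[mask, "pct_change_baseline"],
                100 * sc.loc[mask, "pct_change_cf"],
                s=4,
                c=color,
                label=label,
            )
        ax.set_xlabel("% change vs baseline (apparent)")
        ax.set_ylabel("% change vs counterfactual (true)")
        ax.legend(markerscale=3, fontsize=8)
        p = out / "fig_apparent_vs_true_scatter.png"
        fig.savefig(p, dpi=150, bbox_inches="tight")
        plt.close(fig)
        written.append(p)

    return written
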