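"""Study configuration objects and flat YAML round-tripping.

Every knob of the simulation study lives in one of the dataclasses below.
``StudyConfig`` bundles them; :func:`load_config` / :func:`save_config`
round-trip a flat key-value YAML file in which any subset of fields may be
overridden (section names mirror the dataclass fields of ``StudyConfig``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "PopulationConfig",
    "EligibilityRule",
    "EffectModel",
    "TrialConfig",
    "ClassificationThresholds",
    "StudyConfig",
    "load_config",
    "save_config",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class PopulationConfig:
    """Parameters of the synthetic diary population.

    The population emulates the statistical fingerprint of self-reported
    seizure diaries: strong between-patient rate heterogeneity (log-normal
    daily base rates), within-patient overdispersion tied to the empirical
    "L-relationship" ``log10(SD) = l_slope * log10(mean) + l_intercept``
    of per-patient 28-day seizure counts, optional weekly and monthly
    multiplicative risk cycles, one-day seizure clustering, and a hard cap
    on daily counts.

    Defaults are calibrated so that the full downstream pipeline
    (eligibility screen -> drug effect -> randomized trials) reproduces the
    endpoint statistics observed in adjunctive ASM regulatory trials; see
    ``docs/methods.md`` and ``scripts/calibrate.py``.
    """

    n_patients: int = 100_000
    n_days: int = 140
    baseline_days: int = 56

    # Between-patient heterogeneity: base_rate ~ LogNormal(mu, sd) (per day).
    rate_log_mean: float = -2.15
    rate_log_sd: float = 1.0

    # L-relationship of 28-day counts, log10 scale.
    l_slope: float = 0.7
    l_intercept: float = 0.14
    l_jitter_sd: float = 0.15

    # Multiplicative sinusoidal risk cycles (weekly / monthly / slow slots).
    # Slow cycles span months, so a patient can sit in a trough during the
    # 8-week baseline and near a peak during the 12-week treatment window —
    # the source of the rare extreme (>500%) apparent SF increases.
    weekly_cycle_prob: float = 0.5
    weekly_period_range: tuple[float, float] = (6.0, 8.0)
    monthly_cycle_prob: float = 0.5
    monthly_period_range: tuple[float, float] = (25.0, 35.0)
    slow_cycle_prob: float = 0.4
    slow_period_range: tuple[float, float] = (60.0, 180.0)
    cycle_amp_max: float = 0.5
    slow_amp_max: float = 0.7

    # One-day-memory clustering: rate on the day after any seizure day is
    # multiplied by a per-patient boost.
    cluster_prob: float = 0.5
    cluster_boost_range: tuple[float, float] = (1.2, 2.0)
    cluster_days: int = 1

    max_per_day: int = 10

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        if self.n_days < 1:
            raise ConfigError("n_days must be >= 1")
        if self.rate_log_sd < 0:
            raise ConfigError("rate_log_sd must be >= 0")
        if not 0.0 <= self.cycle_amp_max < 1.0:
            raise ConfigError("cycle_amp_max must lie in [0, 1)")
        if not 0.0 <= self.slow_amp_max < 1.0:
            raise ConfigError("slow_amp_max must lie in [0, 1)")
        for p in (self.weekly_cycle_prob, self.monthly_cycle_prob,
                  self.slow_cycle_prob, self.cluster_prob):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("cycle/cluster probabilities must lie in [0, 1]")
        lo, hi = self.cluster_boost_range
        if lo < 1.0 or hi < lo:
            raise ConfigError("cluster_boost_range must satisfy 1 <= lo <= hi")
        if self.max_per_day < 1:
            raise ConfigError("max_per_day must be >= 1")
        if self.l_jitter_sd < 0:
            raise ConfigError("l_jitter_sd must be >= 0")


@dataclass
class EligibilityRule:
    """Regulatory-trial inclusion screen applied to the baseline window."""

    baseline_days: int = 56
    min_baseline_seizures: int = 8
    max_seizure_free_days: int = 21

    def validate(self) -> None:
        if self.max_seizure_free_days < 1:
            raise ConfigError("max_seizure_free_days must be >= 1")
        if self.baseline_days < self.max_seizure_free_days:
            raise ConfigError("baseline_days must be >= max_seizure_free_days")
        if self.min_baseline_seizures < 0:
            raise ConfigError("min_baseline_seizures must be >= 0")


@dataclass
class EffectModel:
    """Heterogeneous medication effect: per-patient fractional SF reduction.

    ``e`` is drawn from Normal(mean_reduction, sd_reduction) truncated above
    at 1 (a retention probability cannot be negative); ``e < 0`` represents
    true drug-induced worsening.
    """

    mean_reduction: float = 0.20
    sd_reduction: float = 0.10
    family: str = "gaussian"
    #: how the effect acts on the counterfactual counts: "scale" multiplies
    #: them by 1-e deterministically (effect on the SF itself); "thin" uses
    #: event-level binomial thinning / Poisson augmentation
    application: str = "scale"

    def validate(self) -> None:
        if self.sd_reduction < 0:
            raise ConfigError("sd_reduction must be >= 0")
        if self.mean_reduction > 1.0:
            raise ConfigError("mean_reduction must be <= 1 (full suppression)")
        if self.family != "gaussian":
            raise ConfigError(
                f"unknown effect family {self.family!r}; only 'gaussian' is implemented"
            )
        if self.application not in ("scale", "thin"):
            raise ConfigError("effect application must be 'scale' or 'thin'")


@dataclass
class TrialConfig:
    """Monte-Carlo randomized-trial machinery."""

    n_trials: int = 10_000
    n_per_trial: int = 400
    allocation: float = 0.5
    #: if True force equal arm sizes (block randomization) instead of
    #: independent per-patient Bernoulli assignment
    forced_balance: bool = False

    def validate(self) -> None:
        if self.n_trials < 0:
            raise ConfigError("n_trials must be >= 0")
        if self.n_per_trial < 1:
            raise ConfigError("n_per_trial must be >= 1")
        if not 0.0 <= self.allocation <= 1.0:
            raise ConfigError("allocation must lie in [0, 1]")


@dataclass
class ClassificationThresholds:
    """Apparent (vs baseline) and true (vs counterfactual) outcome cut-offs."""

    apparent_worsening_min_increase: float = 0.25
    apparent_response_min_reduction: float = 0.50
    true_improvement_min_reduction: float = 0.10
    true_worsening_strict_increase: float = 0.0

    def validate(self) -> None:
        for name in (
            "apparent_worsening_min_increase",
            "apparent_response_min_reduction",
            "true_improvement_min_reduction",
            "true_worsening_strict_increase",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass
class StudyConfig:
    """Top-level bundle: everything needed for one end-to-end study run."""

    population: PopulationConfig = field(default_factory=PopulationConfig)
    eligibility: EligibilityRule = field(default_factory=EligibilityRule)
    effect: EffectModel = field(default_factory=EffectModel)
    trials: TrialConfig = field(default_factory=TrialConfig)
    thresholds: ClassificationThresholds = field(default_factory=ClassificationThresholds)
    rng_seed: int = 0

    def validate(self) -> None:
        self.population.validate()
        self.eligibility.validate()
        self.effect.validate()
        self.trials.validate()
        self.thresholds.validate()
        if self.population.baseline_days != self.eligibility.baseline_days:
            raise ConfigError("population and eligibility baseline_days disagree")
        if self.population.n_days < self.eligibility.baseline_days:
            raise ConfigError("n_days must cover the baseline window")


_TUPLE_FIELDS = {
    "weekly_period_range",
    "monthly_period_range",
    "slow_period_range",
    "cluster_boost_range",
}


def _to_dict(cfg: StudyConfig) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for f in dataclasses.fields(cfg):
        value = getattr(cfg, f.name)
        if dataclasses.is_dataclass(value):
            sub = dataclasses.asdict(value)
            out[f.name] = {
                k: list(v) if k in _TUPLE_FIELDS else v for k, v in sub.items()
            }
        else:
            out[f.name] = value
    return out


def save_config(cfg: StudyConfig, path: str | Path) -> None:
    """Write a StudyConfig to a YAML file (flat sections, all keys explicit)."""
    Path(path).write_text(yaml.safe_dump(_to_dict(cfg), sort_keys=False))


def load_config(path: str | Path | None = None) -> StudyConfig:
    """Load a StudyConfig, applying overrides from a YAML file if given.

    Unknown keys raise :class:`ConfigError` rather than being silently
    ignored.
    """
    cfg = StudyConfig()
    if path is None:
        cfg.validate()
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    sections = {f.name: f for f in dataclasses.fields(cfg)}
    for section, values in raw.items():
        if section == "rng_seed":
            cfg.rng_seed = int(values)
            continue
        if section not in sections:
            raise ConfigError(f"unknown config section {section!r}")
        target = getattr(cfg, section)
        if not isinstance(values, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        known = {f.name for f in dataclasses.fields(target)}
        for key, value in values.items():
            if key not in known:
                raise ConfigError(f"unknown key {section}.{key}")
            if key in _TUPLE_FIELDS:
                value = tuple(value)
            setattr(target, key, value)
    cfg.validate()
    return cfg
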