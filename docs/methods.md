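# Methods

## Overview

`seizuresim` is a Monte-Carlo study of how natural seizure-frequency (SF)
variability misclassifies anti-seizure-medication (ASM) benefit. The
pipeline is: synthetic diary population → regulatory eligibility screen →
heterogeneous drug effect applied against a retained drug-free
counterfactual → randomized trials → apparent-vs-true outcome
classification. Everything is driven by one `StudyConfig`; a single root
seed is split into stage-scoped RNG streams (population, effects, trials)
so that changing, say, the trial count never perturbs diary generation.

## Diary generation

Each patient has a latent daily base rate λ, drawn log-normally across
the population (`rate_log_mean = -2.15`, `rate_log_sd = 1.0`, i.e. a
median of ~0.12 seizures/day ≈ 3.3 per 28 days with a long right tail).
Daily counts are gamma-mixed Poisson — negative binomial with per-patient
shape r — whose rate on day *t* is multiplied by

* up to three sinusoidal risk cycles `1 + A·sin(2πt/T + φ)`: a weekly
  slot (T ∈ 6–8 d), a monthly slot (T ∈ 25–35 d), each present with
  probability 0.5 and amplitude A ~ U(0, 0.5); and a slow slot
  (T ∈ 60–180 d, probability 0.4, A ~ U(0, 0.7)). Slow cycles let a
  patient sit in a trough during the 8-week baseline and near a peak
  during the 12-week treatment window — they are what produces the rare
  several-hundred-percent apparent SF increases seen in trial data
  (under the defaults, apparent increases beyond +500% occur at a rate
  of roughly one per full-scale study);
* a clustering boost: if any seizure occurred the previous day, the rate
  is multiplied by a per-patient factor (probability 0.5 of having the
  trait, boost ~ U(1.2, 2.0)) — a minimal one-day-memory self-exciting
  mechanism;

and the resulting count is truncated at `max_per_day = 10`.

**Dispersion is not a free parameter.** Per-patient r is solved so that
the implied mean/SD of 28-day counts lies on the configured
L-relationship `log10(SD) = 0.7·log10(mean) + 0.14`, the linear
log-mean/log-SD relation observed across seizure-diary datasets, plus
per-patient log-normal jitter (sd 0.15 in log10) around the line. The
solve uses the closed form `Var(28d) = M + κM²/(28r)` with a first-order
correction κ = Π(1 + A²/2) for cycle modulation. Two deliberate edges:

* **Poisson floor.** Where the line (after jitter) demands less than
  Poisson variance, the law degrades to Poisson (r = ∞). With the default
  jitter this clamps part of the low-rate population, lifting realized
  scatter slightly above the line at small means.
* **Cap truncation.** The daily cap physically bounds attainable 28-day
  variance, so the realized line bends below the configured one at high
  rates (fitted slope ≈ 0.66 vs 0.70 configured under the defaults).
  Both effects are inherited by any capped count process; the
  line-recovery test therefore exercises the core law (no
  cycles/clusters/jitter, cap non-binding), where slope and intercept are
  recovered within two fitted standard errors. The test oracle applies a
  delta-method correction for the small-sample bias of log-SD.

## Eligibility

The screen reads only the 56-day baseline: at least 8 seizures, and no
run of 22+ consecutive zero days (a strict reading of "no seizure-free
period longer than 21 days"; runs touching either end of the window
count, since a leading or trailing gap is an observable seizure-free
period). Both thresholds are configurable. Under the defaults ~29–30% of
100,000 patients qualify.

## Drug effect and counterfactual pairing

Each eligible patient draws one effect e ~ Normal(0.20, 0.10²), truncated
above at 1 by rejection (the retention probability 1−e cannot be
negative; the truncated mass is ~10⁻¹⁵, so the mean is unchanged to
double precision). Negative e — about Φ(−2) ≈ 2.3% of patients — is true
drug-induced worsening.

The drug-free diary is generated once and kept; the treated
treatment-period series is derived from it, so the pair shares realized
noise and the true comparison isolates the drug effect. Two application
mechanisms:

* **scale** (default): every counterfactual daily count is multiplied by
  (1−e) deterministically — the effect acts on the seizure frequency
  itself, and the true percent change vs counterfactual is exactly −e.
* **thin**: event-level binomial thinning (each seizure retained with
  probability 1−e; for e < 0, per-day Poisson augmentation with
  expectation |e|× the realized count, re-capped). This keeps treated
  diaries integer-valued at the cost of binomial noise of sd
  √(e(1−e)/N) in the true comparison (N = treatment-period total).

Deterministic scaling is the default because the conditional
misclassification statistics are sensitive to noise in the true
comparison: with event-level thinning at the count totals typical of an
eligible pool (N ≈ 10–30), the fraction of apparent responders who are
true nonresponders roughly doubles relative to the noise-free value, and
no population calibration can undo it. Both modes satisfy
E[treated] = (1−e)·E[counterfactual] day by day and both are covered by
the test suite.

Seizure frequencies are per 28 days (baseline sum × 28/56, treatment sums
× 28/84). If the counterfactual treatment SF is zero, the true percent
change is 0 when the observed SF is also zero and +∞ (classified as true
worsening) otherwise. The placebo arm receives the counterfactual diary
unchanged — no placebo-effect term is modeled; apparent placebo response
emerges entirely from eligibility-induced regression to the mean.

## Trials

Each of the 10,000 trials samples 400 distinct patients from the eligible
pool without replacement (patients may recur across trials) and assigns
each independently to ASM or placebo with probability ½, so arm sizes are
Binomial(400, ½) around 200 — a config switch (`forced_balance`) gives
exact 200/200 blocks instead. Per arm and trial: median percent reduction
from baseline, 50% responder rate (reduction ≥ 50%, inclusive), and the
fraction with any SF increase. Empty arms report NaN, not zero. The
primary aggregate is the mean of per-trial endpoints across trials.

## Classification

Over the full eligible on-drug pool (not within trials): apparent
worsening is a ≥ 25% SF increase vs baseline, apparent response a ≥ 50%
reduction vs baseline (both inclusive); true improvement is a ≥ 10%
reduction vs the paired counterfactual — 10% being the margin over
placebo of a standard adjunctive ASM at its approved dose — and true
worsening any increase vs counterfactual. True improvement / true
non-response partition every pool; true worseners are a subset of true
nonresponders. The 10% threshold is configurable (setting it to 0
recovers the stricter "any benefit" definition).

## Calibration

The upstream diary simulator this generator emulates is described in the
literature only by its feature list, not its parameter values, so the
free population knobs (rate distribution, L-line placement, jitter,
cycle/cluster strengths) were tuned by grid search
(`scripts/calibrate.py`) to minimize the squared percentage-point
distance of the full pipeline's eleven headline statistics from the
reference values observed in adjunctive-ASM regulatory-trial populations
(median reductions 36/17%, responder rates 35/20%, any-increase 21/36%,
apparent-worsening 12%, conditional true-improver/worsener 76/4%,
responder-misclassification 12%, eligible yield ~30%). The shipped
defaults land every statistic within ~3 points at full scale. The
misclassification conditionals are dominated by the effect model (fixed a
priori), not the calibrated knobs: with a noise-free true comparison they
are approximately Φ-expressions in the effect mean and SD.

## Problem sizes and determinism

The full study (100,000 × 140-day diaries, 10,000 trials) is fully
vectorized across patients (a 140-step day loop carries the clustering
feedback) and completes in well under a minute on a single core; the test
suite uses a mixture of full-scale and reduced runs (5,000–20,000
patients, 200–1,000 trials) sized so that Monte-Carlo error stays well
inside each assertion's tolerance. Identical config + seed reproduces
every product bit-exactly; run manifests record checksums of all outputs.

## Limitations

* Daily resolution; no seizure type, severity, duration or
  under-reporting model.
* No pharmacokinetics, titration, adherence, dropout or explicit placebo
  effect; trial machinery has no interim analyses or hypothesis tests.
* The Gaussian effect family is the only implemented one (the
  `EffectModel.family` tag is the extension point).
* Cycles are sinusoidal and at most three; clustering has one-day memory.
  Real diaries show richer multidien structure.
* Synthetic populations reproduce the variability fingerprint (rate
  heterogeneity, L-relationship, cycles, clustering, cap) but passing
  tests demonstrates internal consistency of this model, not fidelity to
  any individual patient's dynamics.
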