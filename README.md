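# seizuresim

Synthetic seizure diaries, counterfactual anti-seizure-medication (ASM)
trials, and responder-misclassification analysis.

## The problem

Seizure frequency (SF) fluctuates naturally, independent of treatment.
When a patient starts a new ASM and their SF rises, clinic and patient
usually conclude the drug failed — yet the rise may simply be natural
variability masking a real benefit. The counterfactual (what the same
patient would have experienced *without* the drug over the same weeks) is
unobservable in life, but trivially observable in simulation.

`seizuresim` quantifies the resulting misclassification. It

1. generates daily seizure-count diaries with realistic natural
   variability: log-normal between-patient rates; per-patient
   overdispersion tied to the empirical **L-relationship**
   `log10(SD) = 0.7 · log10(mean) + c` of 28-day counts; weekly, monthly
   and slow (2–6 month) multiplicative risk cycles; one-day seizure
   clustering; a hard daily cap;
2. applies the standard regulatory inclusion screen to the 8-week
   baseline (≥ 8 seizures, no seizure-free gap > 21 days);
3. draws a heterogeneous drug effect `e ~ N(0.20, 0.10²)` per patient (a
   20% mean SF reduction; negative draws are true drug-induced
   worsening) and applies it to the treatment period (weeks 9–20) of the
   retained drug-free counterfactual diary, so both trajectories share
   realized noise;
4. runs 10,000 randomized 400-patient trials (ASM arm = on-drug
   outcomes, placebo arm = untouched counterfactuals — placebo "response"
   is pure regression to the mean induced by the entry criteria);
5. classifies every eligible on-drug patient by **apparent** outcome
   (percent change vs own baseline) and **true** outcome (percent change
   vs paired counterfactual) and reports the misclassification fractions.

All SF values are per 28 days. Default cut-offs: apparent worsening
≥ +25% vs baseline; apparent response ≥ 50% reduction vs baseline; true
improvement ≥ 10% reduction vs counterfactual; true worsening any
increase vs counterfactual.

## Worked example

`examples/03_counterfactual_worked_example.py`:

```
baseline SF:        4 per 28 days
observed SF (drug): 6 per 28 days
counterfactual SF:  8 per 28 days
change vs baseline:       +50%  (what the clinic sees)
change vs counterfactual: -25%  (the true drug effect)
classification: ['apparent_worsener', 'true_improver']
```

The patient looks 50% worse and would be labeled a treatment failure, yet
the drug truly cut their SF by a quarter. At population scale
(`examples/05_full_study.py`, 20,000 diaries / 1,000 trials):

```
eligible patients: 5918 / 20000
apparent worsening (>=25% increase vs baseline): 13% of the pool
  ... of whom TRUE improvers (>=10% below counterfactual): 74%
  ... of whom TRUE worseners (above counterfactual): 5%
apparent responders who are true nonresponders: 11%
```

About three quarters of the patients who appear to worsen significantly
on the drug are in fact receiving a clinically meaningful benefit, and
only ~5% are truly being harmed; conversely ~one in nine apparent
responders owes the response to luck, not drug.

## Library, examples, CLI

The package is used from Python (`import seizuresim`); `examples/` holds
one short narrative script per capability. A thin CLI reproduces the full
study in one command:

```bash
seizuresim all --seed 1 --out study_out          # full study + manifest
seizuresim all --n-patients 5000 --n-trials 200 --out quick_out
seizuresim figures --out study_out --render      # figure data (+ PNGs)
seizuresim init-config my_config.yaml            # dump editable defaults
```

Every product is CSV/JSON plus a `manifest.json` with checksums; a fixed
seed reproduces a run bit-exactly.

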