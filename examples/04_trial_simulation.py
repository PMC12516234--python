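"""Simulate randomized trials on an eligible synthetic pool.

Each trial draws 400 eligible patients, randomizes them 1:1, and compares
the standard endpoints.  The placebo arm receives no effect at all — its
apparent response is pure regression to the mean from the entry criteria.
"""

import numpy as np

import seizuresim as ss
from seizuresim.diary import generate_population
from seizuresim.eligibility import filter_population
from seizuresim.medication import build_outcomes, sample_effect
from seizuresim.trials import run_many

rng = np.random.default_rng(2)
pop = generate_population(ss.PopulationConfig(n_patients=20_000), rng)
eligible, _ = filter_population(pop, ss.EligibilityRule())
effects = sample_effect(ss.EffectModel(), rng, size=len(eligible))
outcomes = build_outcomes(eligible.counts, effects, rng, max_per_day=10)

table, agg = run_many(outcomes, ss.TrialConfig(n_trials=500), rng)
print(f"{agg['n_trials']} trials of 400 eligible patients")
print(f"median %-reduction:  ASM {100 * agg['asm_median_pct_reduction']:.0f}%  "
      f"placebo {100 * agg['placebo_median_pct_reduction']:.0f}%")
print(f"50% responder rate:  ASM {100 * agg['asm_responder_rate_50']:.0f}%  "
      f"placebo {100 * agg['placebo_responder_rate_50']:.0f}%")
print(f"any SF increase:     ASM {100 * agg['asm_frac_any_increase']:.0f}%  "
      f"placebo {100 * agg['placebo_frac_any_increase']:.0f}%")
print("-> a 20%-mean drug effect plus natural variability reproduces the")
print("   response pattern of adjunctive ASM regulatory trials.")
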