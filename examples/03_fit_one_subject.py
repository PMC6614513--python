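"""Fit the drift-only diffusion model to one subject and compare to truth.

The v-free scheme shares boundary separation and non-decision time across
the 8 condition cells and frees the drift rate per cell (10 parameters).
Estimation maximises the multinomial likelihood of RT-quantile bin counts
(quantiles .1/.3/.5/.7/.9 per response side).
"""

import numpy as np

from driftfit import default_scenario, fit_subject, generate_design, sample_cohort, simulate_subject

rng = np.random.default_rng(7)
scenario = default_scenario(between_subject_sd=0.0)
subject = sample_cohort(scenario, 1, rng)[0]
records = simulate_subject(generate_design(rng), subject, rng)

fit = fit_subject(records, model="v_free", starts=2)
print(f"model {fit.model}: loglik {fit.loglik:.1f}, k={fit.k}, n={fit.n}, BIC {fit.bic:.1f}")
print(f"shared boundary a: fitted {fit.params['a'].iloc[0]:.4f} (true 0.0800)")
print(f"shared Ter:        fitted {fit.params['ter'].iloc[0]:.4f} (true 0.9000)")
print()
print("cell drifts (log10):")
for cell, row in fit.params.iterrows():
    true_v = subject.params[tuple(cell)].v
    print(f"  {'/'.join(cell):26s} fitted {np.log10(row['v']):+.3f}  true {np.log10(true_v):+.3f}")

# Shared parameters are pinned down by all 832 trials and recover tightly;
# each cell drift rests on 104 trials, so individual cells scatter around
# the truth by roughly +/-0.08 log10 units (the information limit at this
# accuracy level) while their ordering reflects the generating structure.
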