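"""Generate one factorial session and simulate a subject playing it.

The design crosses Beneficiary (self/other) x Payoff (high/low) x
Difficulty (easy/difficult): 4 blocks of 208 trials, 26 trials per cell
per block, left/right motion balanced within block with at most three
consecutive trials sharing a direction, and a 2,000 ms response deadline.
"""

import numpy as np

from driftfit import default_scenario, generate_design, sample_cohort, simulate_subject

rng = np.random.default_rng(42)
scenario = default_scenario()
subject = sample_cohort(scenario, 1, rng)[0]
design = generate_design(rng)

print("trials:", len(design))
print("per cell:", design.groupby(["beneficiary", "payoff", "difficulty"]).size().unique())
print("per block and cell:", design.groupby(
    ["block", "beneficiary", "payoff", "difficulty"]).size().unique())

records = simulate_subject(design, subject, rng)
by_diff = records.groupby("difficulty").agg(
    accuracy=("correct", "mean"), mean_rt=("rt_ms", "mean"))
print(by_diff.round(3).to_string())
print("misses:", int(records["miss"].sum()))

# Easy trials (higher drift) are more accurate and slightly faster;
# misses are vanishingly rare because the non-decision time (900 ms) plus
# typical decision times (~140 ms) sits far below the 2,000 ms deadline.
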