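# Methods

## The process model

A trial is modelled as a one-dimensional Wiener process with drift,

    dX_t = v dt + s dW_t,   X_0 = z,

absorbed at 0 and `a` (evidence units).  The boundary reached is the
response; the first-passage time plus the non-decision time `Ter`
(seconds) is the RT.  `s` is not a free parameter: it sets the scale of
the evidence axis and is fixed at 0.1 throughout (the convention that
makes drift magnitudes comparable across the diffusion-modelling
literature; it is configurable but must be held constant within a fit —
only the ratios `v/s`, `a/s`, `z/s` are identified).

Closed forms used: the absorption probability
`P(upper) = (1 − e^{−2vz/s²}) / (1 − e^{−2va/s²})` with the analytic
`v → 0` limit `z/a`, and the unconditional mean decision time
`m(z) = (a·P(upper) − z)/v`, limit `z(a−z)/s²`.  Both are evaluated with
`expm1` and an explicit small-drift branch (`|2va/s²| < 1e−12` and
`< 1e−9` respectively), so the v→0 limits are continuous to ≤ 1e−6.

First-passage densities use the standard pair of series expansions for
the zero-drift unit-boundary kernel (image-charge sum for small times,
sine eigenfunction sum for large times), wrapped in the drift/scale
factor `exp(−vzw-ish terms)/...` obtained by Girsanov rescaling.  The
number of terms is bounded from an absolute tolerance of 1e−7 and the
expansion is switched per evaluation point to whichever needs fewer
terms.  The defective CDF integrates the large-time series term by term
(eigenvalues `λ_k = (v² + (kπs²/a)²·…)/2` grow like k², so the series
converges for every t > 0); its truncation tolerance is 1e−12 with the
term count capped at 10⁵.  CDF values are clipped into
`[0, P(boundary)]`; `t ≤ 0` returns 0 for the CDF and is a domain error
for the density.

## Trial simulator

Euler–Maruyama with a 0.5 ms default step and a Brownian-bridge
crossing correction: after each step that ends inside the corridor, the
probability that the path crossed either boundary *within* the step,
`exp(−2(a−x₀)(a−x₁)/(s²Δt))` (and the mirror expression at 0), is
sampled.  Plain discretely-monitored Euler at this step size biases
hitting probabilities by ~0.005–0.007 at the calibrated parameters (the
effective-boundary-shrinkage effect, of order 0.58·s·√Δt per boundary);
the bridge correction removes the leading-order bias, and bridge
crossings are stamped at the step midpoint so the residual timing bias
is below 0.3 ms.  Competing crossings within one step are resolved by a
single uniform against the two (individually tiny) bridge
probabilities.  Per-trial drift vectors are supported so one call
simulates a whole heterogeneous session; a `max_time` argument censors
walks for deadline handling.

## Synthetic sessions and the default scenario

The generator reproduces the combinatorial structure of the task: 4
blocks × 208 trials; each of the 8 Beneficiary × Payoff × Difficulty
cells exactly 26 times per block; left/right motion 50/50 within block;
no more than three consecutive trials share a direction (enforced across
block boundaries); inter-trial cue intervals uniform on 800–1,200 ms
(metadata only).  Balanced whole-block rejection sampling is infeasible
for the run-length bound (a balanced 208-trial block almost surely
contains a run of four), so directions are drawn sequentially from the
remaining-count urn with the run-capped direction excluded; dead ends
restart the block, with a bounded retry budget and a hard error rather
than a silently relaxed constraint.

The default (drift-only) scenario expresses cell drifts on a decimal-log
scale as a grand mean −0.80 with additive effects +/−0.04 for
easy/difficult, +/−0.02 for self/other, 0 for payoff — i.e. easy/difficult
means −0.76/−0.84 and self/other means −0.78/−0.82, the magnitudes this
kind of task produces — plus a single per-subject normal offset with SD
0.08 (between-subject variability).  All cells share `a` = 0.08,
`Ter` = 0.90 s, `s` = 0.1, `z` = `a`/2.  The boundary and non-decision
time are calibrated so that simulated sessions land in the descriptive
range typical of this paradigm: easy-trial accuracy ≈ 0.80 (analytic
0.801 at the mean easy drift), mean correct RT ≈ 1.04 s, and misses
(RT beyond the 2,000 ms deadline) of order 10⁻⁴ — a handful per
31,616-trial cohort.  Alternative generating schemes free the
non-decision time (±0.04 s by difficulty) or the boundary (±0.008) for
model-recovery experiments; a null scenario removes all condition
effects for calibration runs.  A starting-point fraction `z_frac ≠ 0.5`
simulates a left/right response bias in direction coding.

What the generator deliberately does **not** emulate: inter-trial
parameter variability (the extended model's drift SD, start-point range
and Ter range default to zero), RT contaminants/fast guesses, sequential
effects, fatigue or learning drifts, and any payoff-conditional strategy
shifts.  Passing tests therefore certify the estimation and inference
machinery under the model's own assumptions, not robustness of the
method to real-data contaminants.

## Estimation

Per subject and condition cell, scored (non-miss) RTs are split by
response side (correct = the boundary matching the stimulus direction)
and binned at the quantiles {.1, .3, .5, .7, .9} of that side's observed
RTs — six bins per side; a side with fewer than 12 observations
collapses to a single bin (its whole defective mass), so an all-correct
cell still contributes the error-side hitting probability.  The fitted
model's expected bin probability is the difference of its defective FPT
CDF at the bin edges (shifted by `Ter`), floored at 1e−10 before the
log; floor hits are counted and reported, never fatal.  The objective is
the multinomial log likelihood `Σ count · ln p_bin`, additive over cells,
with constant terms dropped.  Misses are excluded from the likelihood
and reported as a count (they are of order 10⁻⁴ here).

Four parameter-freeing schemes are fitted: `v_free` (drift per cell;
`a`, `Ter` shared; k = 10), `v_a_free` (k = 17), `v_ter_free` (k = 17)
and `full` (k = 24).  Every scheme fixes `z = a/2` exactly — returned
starting points are identically `a/2` — except the dedicated
`bias_check`, which fits each stimulus direction separately with a free
relative start `w` to test left/right symmetry (symmetric data return
`w ≈ 0.5` on both sides; a start shifted toward one boundary splits
them, and the per-subject `z_left`/`z_right` feed a one-way
repeated-measures comparison).

Optimisation is a nested profile search: cell-specific parameters are
optimised per cell (bounded golden-section in 1-D, L-BFGS-B with warm
starts in 2-/3-D) inside an outer bounded scalar or Nelder–Mead search
over the shared parameters, from moment-based (EZ-style closed-form)
starting values with multiplicative jitter across restarts.  Bounds:
`a ∈ (0.01, 0.5)`, `|v| < 1`, `Ter ∈ (0.1, min RT − 1 ms)` — the Ter
bound uses the *cell's own* minimum RT when Ter is free per cell, and
the subject-wide minimum when shared.  Two unit guards reject tables
whose RTs cannot be milliseconds (seconds stored in the ms column, or a
double conversion) before any optimisation runs.  When a richer scheme
is fitted, the nested simpler scheme's solution is always evaluated as a
candidate, which enforces the likelihood-nesting inequality by
construction; `fit_all_models` chains `v_free → {v_a_free, v_ter_free}
→ full` this way.

Model comparison uses `BIC = −2 log L + k ln n` with `n` the subject's
scored trial count, always per subject (never a pooled likelihood), at
two levels: the BIC sum across subjects and the per-subject best-model
tally.  |ΔBIC| < 0.01 is a tie, broken toward fewer parameters and
flagged.

## Statistics

Sensitivity is the proportion of correct direction judgments per cell,
with misses scored incorrect (this is the quantity the task's criterion
"0.6 = 60% correct" refers to); a true signal-detection d′ over
left/right responses is provided separately.  RTs are analysed as
decimal logs, correct and error responses separately, error-side means
absent (not zero) when a cell has no errors.

Because all factors have two levels, every repeated-measures effect is a
one-degree-of-freedom within-subject contrast: the per-subject score is
the difference of that subject's means over the +1 and −1 cells
(interaction signs multiply), and `F_{1,n−1}` is exactly the squared
paired t on those scores — asserted to machine precision in the tests
and cross-checked against an independent rmANOVA implementation.  This
also makes sphericity corrections moot.  Lilliefors' composite-normality
test computes the KS distance to a normal with estimated moments and
draws its p-value from a cached Monte-Carlo null (10⁴ standard-normal
samples of the same n, fixed seed, add-one estimator) — the null is
distribution-free, so the table depends only on n.  Post hocs follow
Fisher's LSD: unadjusted pairwise paired t tests, gated on a significant
omnibus effect, with the paired-difference SD as error term (the
repeated-measures-safe choice; a pooled between-cell MSE would be
anticonservative here).  Cohen's d defaults to the averaged-SD
convention `(m₁−m₂)/√((s₁²+s₂²)/2)`; the difference-score variant is
available, and the two deliberately diverge under high between-condition
correlation.  p-values are reported to six decimals; no multiplicity
correction is applied anywhere (faithful to the LSD procedure).

## Recovery experiments and what they show

`run_recovery_experiment` simulates cohorts with retained truth and
reports bias, RMSE and three truth–estimate correlations for log₁₀
drift: pooled over subject × cell, per subject (means over cells) and
per cell (means over subjects).  The three answer different questions.
At the default operating point (accuracy ≈ 0.75–0.83, `Ter` ≈ 0.9 s,
decision times ≈ 0.14 s), the choice outcome carries nearly all the
drift information: the binomial bound gives SE(v) ≈ 0.031 at 104
trials/cell, and the quantile-ML estimator attains ≈ 0.030 — per-cell
estimates cannot be less noisy than ~0.075 log10 units no matter the
estimator.  Since the generating spread across subjects and cells is
~0.09, the *pooled* correlation saturates near 0.8 by construction; the
subject-level and cell-level correlations average that noise away and
exceed 0.95 at the 38-subject scale.  Estimation is consistent: bias is
~0.001 log10 at 104 trials/cell and RMSE falls monotonically over
26 → 104 → 416 trials/cell.  The quantity the analysis interprets —
condition effects on drift — is therefore what recovers, and
inferences about *individual cell* drifts of *individual subjects*
should not be attempted at this session length.

`run_model_recovery` checks the selection logic in both directions:
drift-only cohorts are won by `v_free` (sum and per-subject majority),
and Ter-varying cohorts by `v_ter_free`.  The Ter effect size of the
alternative scheme (±0.04 s) was chosen a priori so that a real
per-cell Ter structure is worth more likelihood than the 7-parameter
BIC penalty `7·ln 832 ≈ 47` — i.e. the comparison is informative, not
trivially decided either way.  An `a_varying` scheme completes the grid
for offline confusion-matrix runs.

## Problem sizes and determinism

The shipped test suite runs the full pipeline at the study scale (38
subjects, 832 trials each, all four models, two optimiser starts),
model recovery under the Ter-varying scheme at 14 subjects, the
simulator/closed-form agreement grid at 3×3 × 30,000 trials, and both
type-I calibrations at 2,000 replicates — sizes chosen so the entire
suite completes in well under ten minutes on one CPU while keeping
Monte-Carlo bands (≈ 3 SE) meaningful.  All randomness flows through
named, seed-derived substreams (`SeedSequence([master, sha256(stage)])`),
so every experiment, the pipeline manifest round-trip, and the
acceptance script are bit-reproducible from a single integer seed.

## Known limitations

- Inter-trial variability parameters (drift SD `η`, start range `s_z`,
  Ter range `s_t`) are not estimated; the likelihood is the pure simple
  DDM.  Data generated with substantial inter-trial variability would
  bias the simple model's estimates, as is well documented for this
  model family.
- No contaminant/outlier mixture in the likelihood; real datasets
  usually need one.
- The multinomial objective conditions on the observed quantile edges
  (the standard quantile-fitting construction); edge estimation noise at
  small cell sizes is absorbed into the reported per-cell uncertainty.
- Sensitivity-as-proportion-correct is tied to this task's balanced
  two-alternative structure; for asymmetric designs use the provided
  signal-detection d′ instead.
- The bias check estimates one start fraction per direction subset;
  it tests symmetry, not a full trial-level bias model.
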