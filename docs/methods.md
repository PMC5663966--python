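# Methods

## Behavioral model

Choice on trial N is modeled as logistic in the current stimulus, three
exponentially discounted history regressors, and a constant:

* `O(N) = Σ_{k=1}^{N−1} outcome(k) · e^{−(N−1−k)/τ_o}` — outcome history;
* `C(N)` — same kernel over choices; `I(N)` — over outcome × choice
  (the win-stay/lose-switch axis);
* coding: stimulus/choice +1 forward, −1 downward; outcome +1 error,
  −1 reward; a no-response trial has choice 0 and outcome +1, so it
  contributes to `O` but not to `C` or `I`.

Every preceding trial of the session enters the history regressors,
including trials excluded from prediction (no-response trials); choices
are predicted only where a target was reached. The most recent trial
always carries kernel weight e⁰ = 1, and `|O(N)| ≤ 1/(1 − e^{−1/τ})`.
The kernels are computed by the exact recurrence
`O(N) = O(N−1)·e^{−1/τ} + outcome(N−1)`, verified against an O(N²)
double-loop oracle to 1e−12.

### Fitting

For a candidate set of time constants, the weights are the
maximum-likelihood logistic coefficients on the included trials. The
optimizer is L-BFGS on the analytic negative log-likelihood with a tiny
ridge (λ = 1e−6) on the weights — never the constant — purely as a
numerical guard for separable sessions; reported log-likelihoods are
unpenalized. A session whose included choices are single-class raises
`InestimableSessionError` rather than returning an unreliable estimate.

Cross-validation splits the included trials into 10 contiguous blocks in
trial order (contiguity preserves local history structure); each block is
predicted once by weights fit on the other nine, with prediction +1 iff
p > 0.5 and −1 otherwise (exact ties predict −1). Folds whose training
set is single-class are skipped with a warning.

Time constants are searched per history variable on a log-spaced grid
{0.01, 0.03, 0.1, 0.3, 1, 2, 3, 5, 10, 20, 50, 100} (configurable within
[0.01, 100]), maximizing CV accuracy. Because accuracy is a 0/1 loss,
exact ties across neighboring taus are pervasive; ties are broken by the
held-out log-likelihood and only then toward smaller taus. Without the
likelihood tie-break, tau estimates collapse onto the grid minimum
whenever neighboring taus yield identical predictions. Final weights are
refit on all included trials at the winning taus; the reported accuracy
is from the fold rotation.

The per-trial **internal bias** is the fitted log-odds excluding the
current-stimulus term: `w_o·O + w_c·C + w_oc·I + constant`.

### Model comparison and inactivation analyses

Likelihood-ratio tests compare nested refits (e.g., full vs
stimulus-plus-constant); the χ² degrees of freedom count only weight
parameters. Time constants are treated as model selection, not free
parameters at test time (a `count_taus` flag adds them for sensitivity
analysis). Under memoryless agents the resulting p-values are uniform
(KS-checked in the acceptance suite).

Strategy adaptiveness replays the fitted history-only model (stimulus
weight removed) under the task's stimulus rules 100 times; a session is
adaptive (maladaptive) if the correctly-discriminating fraction exceeds
(falls below) 0.5 in more than 95% of replays, else neutral. A useful
closed form for testing: a deterministic win-stay/lose-switch policy has
stationary discrimination 7/11 ≈ 0.636 under the rules (error → stimulus
repeat → guaranteed reward; each non-streak reward → coin flip; a third
consecutive reward → forced stimulus switch → error).

For light-on/light-off comparisons:

* **Transfer**: time constants are selected by CV restricted to light-off
  included trials; the light-off folds are then rotated, each fold's model
  predicting its held-out light-off trials and all light-on trials.
  History regressors always come from the true preceding trials. Note the
  tau selection maximizes the held-out light-off score itself, so the
  light-off reference accuracy carries a small optimistic bias; effect
  sizes, not null-hypothesis tests, should be used for control arms.
* **Weight-change z-scores**: time constants are fixed from a
  whole-session fit (re-searching them on ~45-trial subsets is unstable);
  weights are then refit on the light-on trials and on 100 random
  light-off subsets matched in trial count, and each parameter's light-on
  magnitude is z-scored against the light-off distribution. Sessions with
  single-class light-on choices are excluded.

Bootstrap tests of mean changes use 1000 percentile resamples; a mean is
significant when the 95% CI excludes zero.

## Task simulator

The stimulus engine repeats the stimulus after errors and switches
direction after three consecutive rewards on the same stimulus; otherwise
it draws fair Bernoulli. The reward-streak counter resets on any error
(including no-response trials) or stimulus change — the minimal reading
of the rule. Light-on flags are sampled uniformly among configurations
with exactly round(fraction·n) on-trials separated by at least 5
off-trials, via the gap bijection onto unconstrained combinations.
Chance-level discrimination estimates the session's constant choice
preference `½(P(forward|stim forward) + P(forward|stim downward))` and
replays a fixed-probability chooser under the rules 1000 times.

## Synthetic data generators

**Behaving agent** (stage 1): iterates stimulus rules → model log-odds →
Bernoulli choice, with optional lapse and no-response mixing and
per-weight multiplicative scaling on light-on trials (emulating
inactivation). Defaults used in validation — 300–400 trials per session,
weights of order 1 (w_o = 1.5, τ_o ≈ 0.5–2; w_c = −1, τ_c = 10), 15%
light-on trials with a 5-trial minimum gap — mirror the scale of real
sessions (≈280 trials, short outcome and long choice time constants,
15% light trials). Event times follow the task schedule (ITI 4 or 8 s,
1 s stimulus, 2 s memory, go cue, ~0.35 s reaction).

**Calcium traces** (stage 2): each cell draws transient events from an
inhomogeneous per-frame rate — baseline (events/min) plus additive gains
active in the tuning window (pre-stimulus ITI [−4, 0) s for history/bias
tuning; [−0.5, 1.5] s around movement onset for movement tuning),
multiplied by the signed variable value (continuous internal bias for
bias cells). Events are convolved with an instantaneous-rise exponential
kernel (0.3 s decay, GCaMP6f-like; amplitude 1 dF/F), white noise added
(σ = 0.03–0.05), and written back as raw = F₀·(1 + dF/F) + 0.7·background
so the preprocessing path is exercised end to end. Ground-truth specs are
stored apart from the analysis inputs (sidecar file, not the HDF5 the
analyses read).

What the generators do **not** emulate: slow drifts and neuropil
contamination in fluorescence, correlated (shared) noise across cells,
within-session drift of behavioral weights, reaction-time structure, or
imaging artifacts. Passing tests therefore demonstrate correctness of the
analysis chain against its own generative assumptions, not robustness to
every property of real recordings.

## Neural preprocessing

dF/F uses `adjusted = raw − 0.70·background` and a dynamic baseline equal
to the 8th percentile of `adjusted` in a 20 s window centered on each
frame; the window truncates at the trace edges (percentile over available
frames). Transients are local maxima of the zero-mean dF/F (plateaus take
their first frame; no pre-smoothing) passing an absolute floor of 0.5 and
3.3× the standard deviation of the per-frame dF/F velocity (first
difference over the whole trace). A cell is **active** when its transient
rate exceeds 1/min in both session halves and the mean transient
amplitude exceeds 5× sd(dF/F). A cell is **task-related** when its
trial-averaged trace (correct trials; alignments: stimulus −6..3 s,
movement −2..7 s, reward −4..5 s) exceeds the cell's 99.9th dF/F
percentile for ≥3 consecutive frames in any alignment; the false-positive
rate is estimated by re-running after circularly shifting the trace by an
independent random amount per trial.

A structural note on the task-related gate: since the threshold is a
quantile of the cell's own trace, a response can only clear it when the
frames carrying the response occupy less than 0.1% of the session —
otherwise the response itself sets the threshold. Sparse, reliable,
strongly bursting cells pass; dense responders do not. The constructed
positive fixtures live in that sparse regime, and the shift-shuffle
false-positive rate on null cells is bounded at 6% in the acceptance
suite.

## Tuning and decoding

Nine 1-s epochs tile [−4, 2) s around stimulus onset (six epochs) and
[−1.5, 1.5) s around movement onset (three); frames are assigned by
midpoint. ITI activity for tuning and decoding is the four pre-stimulus
epochs ([−4, 0) s; for 8 s ITIs this is the last half of the interval).
AUROCC is computed from the rank statistic; strength = 2·|AUROCC − 0.5|;
significance is strength above the 100·(1 − α/m) percentile of a
1000-shuffle label null with α = 0.01 and m = 9 epochs (≈ 99.9th
percentile). Conditioned tuning evaluates a variable within the four
combinations of the other two task variables, requiring ≥18 trials per
target class per condition.

Decoding features are cells × 4 ITI epochs. Feature selection is
forward-entry (partial-F p < 0.05) / backward-removal (p > 0.10) stepwise
linear selection, run by default once on all trials before
cross-validation — matching the original procedure, at the cost of a mild
selection leak — with a `strict` mode that reselects inside every
training fold. The bias is fit by OLS and scored as pooled held-out r²
over 10 contiguous folds (empty selections score 0 and are flagged);
binary variables use the same ridge-guarded logistic as the behavioral
model with the identical ±1 prediction rule. The decision-boundary
distance is `(w·x + const)/‖w‖`, invariant to positive rescaling of the
classifier, and the bias-conditioned psychometric bins z-scored distances
into equi-populated bins. Bias-independent history information is the
held-out accuracy difference between a classifier on the full features
and one on the 1-D projection onto the bias-regression axis, with
selection refit per decoder.

## Pipeline, seeds, problem sizes

`run-all` derives one child seed per stochastic stage from the master
seed (numpy SeedSequence), writes fixed-format CSV/JSON and
timestamp-free HDF5, and records SHA-256 hashes in a manifest; identical
configs are byte-identical. The validation experiments use 20 seeds for
recovery/comparison/inactivation, 200 seeds for the LRT null, 600 cells
for the ROC null, 3 populations for decoding, and a 200-trial demo
pipeline for the determinism check — sizes chosen to give stable pass
margins on one CPU. The default pipeline tau grid is {0.1, 1, 10} for the
same reason; the full 12-point grid is used where tau recovery itself is
measured.

## Known limitations

* Grid-search CV over three taus is O(grid³); the full default grid on a
  full model is expensive, so orchestration defaults use coarser grids.
* Accuracy-based tau selection is coarse at n ≈ 400; per-seed tau
  estimates scatter a grid step or two around the truth even with the
  likelihood tie-break (medians are well-centered).
* The pooled stepwise mode leaks selection information across folds by
  construction; use `strict` mode when unbiased decoding estimates matter
  more than fidelity to the original procedure.
* The adaptiveness label depends on the simulated session length; very
  weak history policies are labeled neutral at the default 250 trials.
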