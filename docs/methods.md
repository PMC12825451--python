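# Methods

This note documents the models, estimators, defaults and numerical
choices behind `tarstop`, and what its synthetic-data tests do and do
not demonstrate about real screening data.

## Screening model and notation

A dataset of N records contains R relevant ones (labels y_i ∈ {0,1}).
A screening trace is a permutation of the records together with the
labels in screening order; ρ_t denotes the cumulative number of
includes after t records. The first n₀ records are screened uniformly
at random (the initialization sample); thereafter a ranking model
reorders the unscreened records after each retraining, and a *score
snapshot* records its probability-calibrated scores s_u ∈ [0,1] over
the records still unseen at that point.

A stopping criterion sees only a *trace prefix*: the first t labels,
n₀, N, and the most recent snapshot with the records screened since
removed. Scores are deliberately **not** recomputed between
retrainings — mid-batch, a reviewer's tooling would also be working
from the last training round. Criteria are evaluated on a fixed
checkpoint grid t = n₀, n₀+Δ, n₀+2Δ, …, N (Δ = 15 records by
default; N is always the final checkpoint so "never fired" is well
defined). The grid starts at n₀ because stopping inside the random
phase is not meaningful for prioritized screening. The reported
stopping point T is the first checkpoint at which the criterion holds
— the end of the batch in which it became true.

## Evaluation metrics

For a recall target τ, the optimal stopping point is
t\*(τ) = min{t : ρ_t ≥ ⌈τR⌉}; the ceiling makes the required include
count integral and the "% target missed" statistic unambiguous. A stop
at T is scored by:

* achieved recall ρ_T/R;
* target missed: ρ_T < ⌈τR⌉, and the missed proportion
  (⌈τR⌉ − ρ_T)₊ / ⌈τR⌉;
* additional work (T − t\*)/(N − t\*): 0 at the optimum, 1 when the
  criterion never fired (T := N), negative when it fired early; 0 by
  convention when t\* = N;
* work saved 1 − T/N.

Aggregation per (method, τ) reports the percentage of runs that
missed the target, mean achieved recall with a 10th–90th percentile
range, and mean additional work (all ×100). Percentiles use linear
interpolation between order statistics throughout (including the
composite-curve envelopes), since range statistics depend on the
interpolation rule. Target-aware methods are scored against their own
configured τ; target-agnostic ones (consecutive-exclude rules, window
precision, knee, the 2399 rule) are replicated across the reference
targets {0.8, 0.9, 0.95, 0.99}.

## Stopping criteria

All criteria are pure functions of (prefix, config, seed); whenever a
required input is absent (no snapshot yet, no includes yet, too few
points to fit) they report *not applicable* — triggered false, value
absent — rather than raising, so a full sweep never aborts.
Degenerate guards: recall-style estimates are 0 when ρ_t = 0, except
estimates whose denominator is exactly ρ_t (nothing expected unseen),
which are vacuously 1; divisions by zero return not-applicable.

**CMH.** Null hypothesis: at least X_min = ⌊ρ_t(1−τ)/τ⌋ + 1 relevant
records remain unseen (the target is missed). For every candidate
start s ∈ {0,…,t−1}, the k_s = ρ_t − ρ_s includes observed in the
n_s = t − s most recent records are referred to a
Hypergeometric(N − s, X_min + k_s, n_s) distribution; the p-value is
min_s P(X ≤ k_s) and the rule fires when it drops below α = 1 − c.
Scanning *all* starts (rather than batch boundaries) is a superset
that can only strengthen the minimum; cost is one vectorized CDF call
per checkpoint. If X_min exceeds the number of unseen records the
null is impossible and p = 0. The hypergeometric kernel is SciPy's;
an exact rational-enumeration oracle verifies it to 1e-12 for all
N ≤ 30.

**HEURISTIC_SCORES (Quant) and QUANT_CI.** The expected unseen
relevant count is Ê = Σ_u s_u; Quant stops when ρ_t/(ρ_t + Ê) ≥ τ.
QUANT_CI treats the unseen scores as independent Bernoulli
probabilities, V̂ = Σ s_u(1 − s_u), inflates the estimate to
Ê + z_c√V̂ (one-sided normal quantile), and is therefore never less
conservative than Quant.

**CURVE_FITTING.** The cumulative curve is averaged within
`num_windows` equal windows and y = a(1 − e^(−bx)) is fitted by
Levenberg–Marquardt-style least squares (`scipy.optimize.curve_fit`,
a, b bounded positive; a initialized at ρ_t/τ, b from the last window
mean). The rule fires when the one-sided lower recall bound
ρ_t/(â + z_c·SE(â)) reaches τ, provided the fit converged with b̂ > 0
and â ≤ N (the â ≤ N guard also rejects the near-linear degenerate
ridge where â → ∞, b̂ → 0). Window-averaging biases the fit slightly;
at 10 windows the asymptote of an exact exponential is recovered
within 0.3%.

**HEURISTIC_FIX / HEURISTIC_FRAC.** Trailing run of consecutive
excludes ≥ n (or ≥ ⌈fN⌉).

**HEURISTIC_RANDOM.** R̂ = max(ρ_t, p̂N) with p̂ the inclusion rate of
the initialization sample; never fires if the sample held no includes.
The max(…) clamp keeps the recall estimate ≤ 1.

**BATCHPRECISION.** Inclusion rate of the last W screened records,
firing when it falls below the threshold; inactive until the window
clears the initialization sample. The window inclusion rate is used
(it coincides with classifier precision when the window is the
top-ranked batch).

**APRIORI.** The ranker's predicted remaining includes
B = |{u unseen : s_u ≥ 0.5}| gives the estimate ρ_t/(ρ_t + B); the
rule requires the estimate to hold above the threshold at `window`
consecutive checkpoints. A single prefix cannot see earlier
checkpoints, so the sustained-window state is reconstructed by the
harness from the checkpoint series; the criterion itself stays pure.
This reconstruction (predicted-remaining recall + sustained window)
is one of several defensible readings of the method's one-line
descriptions in the literature.

**KNEE.** The gain curve is normalized to the unit square, smoothed
with a degree-`poly_degree` polynomial fit, and the knee is the
argmax of the fitted curve minus the diagonal. A minimum
curve-to-diagonal distance (`curve_threshold`) rejects degenerate
near-diagonal curves; the rule fires when the pre-knee/post-knee
slope ratio (ρ_k/x_k) · (t − x_k)/(ρ_t − ρ_k + 1), in record units,
exceeds the configured ratio.

**METHOD2399.** Fires when t − κρ_t ≥ 2399; datasets with N < 2399
are therefore always screened completely.

**S-CAL.** The prioritized region is partitioned at the retraining
boundaries; from each segment of size B_j a uniform sub-sample of
min(sample_size, B_j) labels is drawn (seeded) and scaled by
B_j/(drawn), summed with the exact include count of the
initialization sample, and inflated by κ to give R̂. With exhaustive
sampling the estimate reduces to κ·ρ_t (recall 1/κ). Since simulation
labels are fully known, the sub-sampling emulates the method's
partial-labeling economics rather than a labeling cost.

**SAL_TAU.** From the two most recent snapshots, per-snapshot score
masses M are computed after a configurable normalization (identity,
min–max with an all-zeros guard for constant scores, or softmax); the
rule fires when ρ_t/(ρ_t + κM_j) ≥ τ while the relative change
(M_{j−1} − M_j)/max(M_{j−1}, 1e−9) is below 1 − c. The exact
adjustment used by the method's originators is not published in
closed form; this score-mass + rate-of-change gate is a documented
reconstruction.

**IPP.** Include occurrences in the prioritized region are binned
into `num_windows` windows and converted to per-record rates
(counts divided by window width, keeping the decay model
dimensionally consistent with its integral); λ(x) = a·e^(−bx) is
fitted with a, b > 0, the expected remaining count is
μ = (a/b)(e^(−bt) − e^(−bN)), and the rule fires when
P(X ≤ ⌊ρ_t(1−τ)/τ⌋) under Poisson(μ) reaches c. Flat rates (b̂ ≈ 0)
are not applicable.

**TM_QBCB.** n relevant records are drawn uniformly ahead of time and
hidden in the process; finding all n certifies recall ≥ τ at
confidence c provided τⁿ ≤ 1 − c. The minimal n is computed by direct
scan: n(0.95, 0.95) = 59, n(0.8, 0.95) = 14 (the rule-of-thumb "15"
sometimes quoted for the 80% target is one above the exact bound).
The harness draws the target set per (trace, seed), capped at R, so
the criterion stays pure; the extra annotation effort of building the
target set is not charged to the work metrics.

## Synthetic data

**Corpus generator** (for end-to-end simulator tests): N records
(default 3600) at inclusion rate 0.05 (⇒ R = round(N·rate));
abstracts are whitespace-joined tokens with Poisson(150) length drawn
from a Zipf-like background distribution over a 5000-word vocabulary;
each relevant record belongs to one of 3 topical clusters and draws a
fraction `topic_mix` (default 0.35) of its tokens from its cluster's
own vocabulary block. This creates linearly separable topical signal
whose strength `topic_mix` controls.

**Trace generator** (for fast stopping-method tests): the first n₀
labels (default 500) are a uniform draw without replacement from the
label multiset; the remaining relevant records are placed at
continuous times drawn from the gain law
g(u) = (1 − e^(−βu))/(1 − e^(−β)) over the normalized prioritized
region, interleaved with evenly spread excludes, so the stochastic
gain curve follows g. Plateaus — (start, width) fractions of the
prioritized region — are spliced in as zero-inclusion gaps, shifting
later includes right; they reproduce the "steps" that arise when a
ranker exhausts one cluster of relevant records before finding the
next, and that fool shape-based stopping rules. Score snapshots every
25 records draw unseen-record scores Beta(4,2) for includes and
Beta(1,6) for excludes; these are *not* calibrated probabilities,
which deliberately exposes the score-based estimators' sensitivity to
miscalibration (vary the shape pairs to probe it).

The default curve rate is β = 12, chosen so that on a plateau-free
default trace the 99%-recall point falls near half of the trace —
the mid-quartile behavior of well-ranked real screening runs (at
β = 12 the 0.99-quantile of g is u ≈ 0.38, i.e. ≈49% of a 3000-record
trace with n₀ = 500). Steeper β compresses includes toward the start
(β → ∞ recovers the ideal slope-one curve); β → 0 degenerates to
uniform placement. Note the relationship between β and the
high-recall point is strongly nonlinear: at β = 5 the 0.99-quantile
of g is still u ≈ 0.82, so moderately steep-looking curves place
their last includes very late.

All randomness flows from one explicit `numpy` generator per call; no
global state is touched, and identical parameters + seed give
byte-identical artifacts.

**What passing synthetic tests does not show.** The generator
produces exchangeable records within each phase, exact adherence to a
single parametric gain law, and label-conditional i.i.d. scores. Real
traces have correlated topical runs, ranking quality that drifts with
training-set size, and score distributions that are multimodal and
miscalibrated in structured ways. Conclusions about *relative*
method behavior (e.g. which rules a plateau fools) transfer;
absolute miss rates and work savings on real corpora do not.

## Ranking simulator

Records are vectorized as TF-IDF over concatenated title + abstract
(scikit-learn defaults: raw term counts, smoothed idf
ln((1+n)/(1+df)) + 1, l2-normalized rows). The model pool holds four
families: logistic regression, linear SVM, SGD logistic regression,
and LightGBM. Hyperparameters (regularization strength and class
weighting; for the GBM: trees, leaves, learning rate, minimum child
samples) are drawn by seeded random search — `tuning_budget` trials
per family (default 20) — scored by stratified `cv_folds`-fold
cross-validated recall of the 0.5-thresholded classifier on the seen
records; in-sample recall would saturate at 1 for high-capacity
models, and CV folds shrink automatically when includes are scarce
(falling back to in-sample recall below 2 per class). Ties break by
family order, then trial order. The winning configuration is reused
for 4 iterations (refit on all seen records each iteration) before
re-selection, which restarts fresh. Scores exposed in snapshots are
probability outputs; the linear SVM is Platt-calibrated on
cross-validated decision values, since score-based criteria read the
scores as inclusion probabilities.

The screening loop: after the n₀-record random phase (extended
randomly until both classes are present, if needed), each iteration
scores the unseen records, snapshots them, and screens in descending
score order until the batch closes — at the first of (a) at least 2
new includes found and the batch ≥ 25 records, (b) the batch reaching
200 records, (c) exhaustion. The nominal schedule
min(200, round(25·1.1^j)) documents the intended growth of retraining
intervals; under rule (a) a productive ranker keeps batches at the
lower bound (frequent retraining) while an exhausted one stretches to
the upper bound (cheap tail). Termination is unconditional: every
record is screened exactly once regardless of model behavior.

## Problem sizes used in the checks

The statistical reproduction of the zero-miss behavior of CMH uses 50
seeded traces at N = 3000, R = 150, one plateau (0.4, 0.05),
confidence 0.95, checkpoint stride 15 — at both τ = 0.8 and τ = 0.99
the rule missed the target in 0% of runs, stopping at recalls near 1
(characteristically conservative). Simulator sanity checks run on a
1200-record corpus at `topic_mix` 0.6 with two model families and 4
tuning trials; the checked properties (prioritized gain curve
dominating a random permutation per seed, batch bounds, the growth
formula) are size-independent. Kernel exactness is exhaustive for
N ≤ 30; estimator-recovery checks use discretized noiseless curves
(unit-step rounding adds ≲1% bias, reflected in tolerances).

## Known limitations

* APRIORI and SAL_TAU are reconstructions from one-sentence published
  descriptions; their exact original formulas are not public.
* BATCHPRECISION implements window inclusion rate, not thresholded-
  classifier precision; the two coincide for top-ranked windows.
* The CMH minimum over all starts is not multiplicity-corrected (by
  design, matching the published procedure's character); its observed
  conservatism on synthetic traces comes from the test, not from a
  union bound.
* Transformer or LLM ranking families are out of scope; the model
  pool accepts only the four built-in families, though the selection
  machinery is family-agnostic.
* Scores between retrainings are stale by construction; criteria that
  might benefit from per-checkpoint rescoring cannot be expressed.
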