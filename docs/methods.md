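# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the known limitations of `prosodecode`. It states
no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Gamma-mixture model of prosodic boundary strength

Prosodic boundary strength is a positive, right-skewed per-word scalar
(produced upstream by wavelet analysis of duration/energy/f0; this
package consumes it as a column). It is modelled as a two-component gamma
mixture. Fitting is by EM:

- **E-step** in log space (logsumexp) for numerical stability.
- **M-step**: weighted gamma MLE per component. The shape solves
  `log a − ψ(a) = log(mean_w x) − mean_w(log x)` by Newton iteration from
  the Minka-style moment start; the rate is `a / mean_w(x)`. A component
  whose responsibility mass vanishes (< 1e-10) keeps its previous
  parameters rather than producing NaNs.
- **Initialisation**: split the sample at the median (restarts jitter the
  split quantile uniformly in [0.2, 0.8]) and fit each side by the same
  weighted MLE; 5 restarts by default, best log-likelihood wins.
- **Convergence**: relative log-likelihood change below 1e-8, cap 500
  iterations; non-convergence is flagged, never raised.

Components are reported ordered by mean, so "component 2" is always the
strong-boundary (larger-mean) component.

The weak/strong **binarization boundary** is the crossing of the weighted
component densities between the two component means, found by Brent's
method to 1e-8 (with a grid-scan fallback to bracket the sign change if
the means themselves don't bracket one). At this point the posterior
membership is exactly 0.5/0.5. A strength exactly at the boundary is
classified *weak* — the conservative choice, since the weak pool feeds
the bias-free training set. Zero strengths must be filtered before
classification; `classify_strength` enforces this.

The association tests delegate to standard IRLS GLM machinery: binomial
family for closing ~ prosody-class, Gamma family with the inverse
(canonical) link for strength ~ closing. Note the sign convention of the
inverse link: a *positive* strength effect (closing words stronger)
appears as a *negative* coefficient on the linear predictor, because the
link maps to 1/mean. Direction checks in the tests therefore compare
group means rather than the raw coefficient sign.

## Syntax labels and token filters

Closing-node counts are computed by a post-order traversal: every node is
"closed" at its rightmost terminal, and the count includes the word's own
preterminal. Two consequences make this convention attractive: every word
closes at least one node, so "closes more than one node" (has a closing
phrase boundary) versus "closes only its preterminal" (does not)
partitions all words with no third class; and the count equals the run of
`)` after the word in the normalized bracket string, which the tests use
as an independent oracle. The alternative reading — dropping words that
close exactly one node — is not the default but the labeling is a single
threshold (`closing_count > 1`) and trivially switchable.

Filters are applied after counting (counts need the full tree):
out-of-dictionary markers, sentence-final words (to avoid end-of-sentence
positional confounds), and zero-strength words, each recorded with its
reason; when several apply, the first in that order is recorded.

## Split design

Cells of the prosody × syntax table: weak∧no, weak∧yes, strong∧no,
strong∧yes. The training pool is all weak tokens not reserved for
testing, with the majority closing-class downsampled (never upsampled —
duplicated training rows would leak across CV folds). Test sets: neutral
= weak∧no + weak∧yes, coherent = weak∧no + strong∧yes, incoherent =
weak∧yes + strong∧no, each with `test_size_per_class` tokens per class.
Per cell, the total demand across the sets using it is drawn without
replacement when possible; a too-small cell is dealt exhaustively across
its sets and each set's shortfall is topped up by resampling *within that
set*, so a token can repeat inside one test set but never across sets or
into training. The default `test_size_per_class` is the smallest cell
size, capped so the training pool keeps at least 70% of weak tokens.

## Epoching and dimensionality reduction

Epochs are `[tmin, tmax)` half-open around each word offset (defaults
−0.4 to 0.8 s), sample count `round((tmax−tmin)·fs)`. An offset closer
than 100 ms to its predecessor is discarded (the earlier one is kept);
epochs crossing the recording edge are dropped with a logged count. No
baseline correction is applied.

Reduction is an SVD of the channels × (epochs·samples) *training* matrix;
the smallest leading set of components whose cumulative **squared**
singular values reach 99% of the total is retained (interpreting the
spectrum cutoff as variance, the conventional reading; the cutoff is a
parameter). The projection is fitted on training epochs only and applied
unchanged to test epochs. In the original source-space setting such a
reduction acts on low-rank resolution operators; at sensor level with
full-rank noise it can retain nearly all channels — it is a contract
(train-only, energy-preserving), not a guaranteed compression.

## Decoding

Whole-window MVPA: features are all components × samples in a 400 ms
window, z-scored by the statistics of the fold's own training portion;
logistic regression with C = 1 (L2, solver tolerance 1e-6); tenfold
shuffled CV over the training pool, where each fold's model scores the
three *fixed* test sets (the held-out training tenth is not used for
scoring — it reconciles randomized CV with fixed, training-disjoint test
sets); per-condition AUC is the fold mean.

Temporal decoding: one classifier per sample, features = component
amplitudes at that sample. C is selected per timepoint by inner fivefold
CV on the training pool over an 11-point log grid (one value per decade,
1e-5…1e5), maximizing mean inner AUC; ties go to the smallest C
(strongest regularization). The winning C is refitted on the full pool
and scored on the test sets. The inner path is walked with a warm-started
solver, which cannot change the optimum (the penalized loss is strictly
convex) but saves iterations. One consequence of the AUC metric worth
knowing: on perfectly separable data *every* C attains inner AUC 1, so
the tie-break deterministically selects the grid minimum — selected-C
magnitude is not a monotone readout of separability.

AUC is the rank statistic (probability a random positive outscores a
random negative, ties ½); the tests verify it against pairwise
enumeration. No test-set information enters training, standardization, or
C selection.

## Group statistics

- **Paired permutation test**: statistic = mean paired difference; null
  by sign-flips. All 2^n patterns are enumerated whenever 2^n ≤ n_perm —
  with the default 2048 permutations this is exhaustive up to n = 11
  subjects, and the p-value is the exact count ratio; otherwise random
  flips with the add-one convention (p > 0 guaranteed). Tests are
  one-sided by default (the hypotheses are directional: AUC > chance,
  coherent > other conditions); a sidedness flag is provided.
  Multiple comparisons across the three conditions use Bonferroni–Holm.
- **Cluster permutation**: pointwise one-sample t against zero
  (zero-variance timepoints get t = 0 with a warning); cluster-forming
  threshold = the two-sided 0.05 t quantile at df = n−1 (the common
  default; configurable); clusters are maximal runs of adjacent
  supra-threshold samples, mass = summed t; null = maximum cluster mass
  over sign-flip permutations (sign flips leave per-subject squares
  unchanged, so the permuted t is computed from cached sums of squares).
  Cross-checked in the tests against an independent implementation.
- **Prevalence**: lower-bound model θ = α + γ(1−α), uniform prior,
  posterior Beta(k+1, n−k+1) on θ. MAP(γ) closed-form and truncated at 0;
  the 95% HPD interval is the shortest interval of posterior mass 0.95,
  found by bounded scalar minimization over the lower-tail mass (the
  posterior is unimodal), then mapped through γ = (θ−α)/(1−α) and clipped
  to [0, 1].

Within-subject significance for the prevalence counts comes from a
label-shuffle test on the fixed test sets: the decoder is fitted once on
the full training pool and the null AUC distribution is built by
permuting test labels over fixed scores (999 shuffles, add-one p).

## The synthetic cohort

The generator emulates the statistical structure the analysis assumes;
its defaults are the package's study conditions.

- **Word table**: latent prosody class first (strong with probability
  `w_strong` = 0.25 — a free simulation parameter, since the mixture
  weights of real stimuli are not part of the reference values), then the
  closing label from P(closing|strong) = 0.72 and P(closing|weak) = 0.44,
  then strength from the class's gamma component (shapes 1.1 / 14, rates
  2.8 / 10.7). Offset-to-offset gaps are shifted-exponential (0.12 s +
  Exp(0.25 s)) with 5% forced below 100 ms so the epoch discard rule is
  exercised; word duration is 80% of the gap.
- **Cohort**: 11 subjects by default; every subject hears the *same*
  word table (a fixed-stimulus listening design), with per-subject
  randomness from deterministic substreams of the master seed. A
  `shared_stimuli=False` switch generates independent tables per subject.
- **Recordings**: 60 channels at 100 Hz (dimensionality is what matters
  after reduction, not acquisition rate), Gaussian sensor noise
  (sd = 1). Each token adds a fixed per-subject spatial pattern — one
  pattern for closing tokens, a different one for no-closing tokens —
  times a raised-cosine profile of width 300 ms peaking 100 ms after the
  word offset, plus an anticipatory component (width 200 ms, peak
  −100 ms) at `pre_gain` = 0.5 relative amplitude, emulating above-chance
  pre-offset decodability. The amplitude is the token's cell gain:
  `gain_coherent` = 1.2 (strong∧closing), `gain_neutral` = 0.8
  (weak∧no-closing), `gain_incoherent` = 0.35 (the two mismatched cells).
  Both classes must carry (distinct) patterns: if only closing tokens
  carried signal, the neutral and incoherent sets — whose closing tokens
  come from the same weak∧yes cell — would be equally decodable and no
  coherence enhancement could be planted. With per-cell gains, the
  class separation available to a test set grows with the gains of both
  of its cells, yielding the planted ordering coherent > neutral >
  incoherent while keeping incoherent above chance.
- **Scale**: 600 words per subject by default. This keeps the full
  11-subject run, including per-timepoint nested-CV decoding at 120
  timepoints, in the minutes range on one CPU while leaving ~90 epochs
  per test set — enough for stable AUCs. The gains were chosen once, at
  design time, to give a clearly recoverable ordering at this scale.

What the generator does **not** emulate: source geometry and volume
conduction (no forward/inverse modeling — the SVD contract is applied at
sensor level), autocorrelated 1/f sensor noise, eye/cardiac artifacts,
talk- or sentence-level nonstationarity, lexical/acoustic confounds
between classes, and overlap-induced label correlation beyond what the
shared epoch window produces. Passing tests therefore demonstrate that
the pipeline recovers structure it is designed to detect under its own
assumptions — not that real MEG data contain such structure.

## Degenerate inputs and edge conventions

- Empty offset list → empty epoch set (not an error); empty word table is
  valid output for n_words = 0 but recordings require ≥ 1 token.
- EM on effectively one-component data: the fit's log-likelihood
  dominates the single-gamma MLE (nested models), but the two fitted
  components may legitimately be overlapping gammas with moderately
  different means; the boundary is then still defined if the weighted
  densities cross between the means, and an error is raised otherwise.
- Identical component means → boundary error (undefined).
- Single-class labels → errors in fitting and AUC, by construction.
- p-values exactly 0 cannot occur (exact ratios include the identity
  permutation; random draws use add-one).

## Reference values

Quantities computable without the restricted stimuli and recordings are
reproduced exactly by the package (prevalence MAP/HPDI closed forms;
exhaustive-permutation conventions; the Holm step-down). Quantities that
depend on the original audio and MEG — the fitted boundary 1.01, the
stimulus proportions, GLM z/t magnitudes, absolute AUC levels, cluster
windows — are treated as reference-only: the pipeline reproduces their
*form* (sign, ordering, timing of the planted effect) on synthetic data,
and parameter-recovery simulations check the estimators against the
printed mixture parameters.
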