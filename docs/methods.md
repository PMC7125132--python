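# Methods

This note documents the models, estimators and numerical choices behind
`metahistory`, and what the synthetic-data tests do and do not establish
about real data.

## Generative model of a session

Each simulated subject performs `n_blocks × trials_per_block` trials
(default 12 × 50 = 600, after discarding `warmup_trials` lead-in trials).
Per trial:

1. **Prospective decision** (made before the stimulus):
   `logit P(high) = β₀ + Σ_{k=1..4} Σ_f β_k,f (x_{f,t−k} − ½)`, with
   features f ∈ {correctness, awareness, confidence} and optional
   autoregressive weights on past prospective decisions (default 0).
   Centring the lagged predictors at ½ makes absent history contribute
   zero log-odds, so with β₀ = 0 the base rate is ≈ 0.5 regardless of the
   lag weights.
2. **Stimulus** s ∈ {left, right} equiprobable, coded ±1.
3. **Awareness** a ~ Bernoulli(`p_aware`, default 0.5), exogenous: the
   emulated task's luminance staircase holds the aware rate near 0.5 by
   construction, so awareness is drawn rather than derived from the
   evidence. This keeps the awareness–correctness association tunable
   purely through the sensitivity gap.
4. **Evidence** e ~ N(s·d/2, 1) with d = `dprime_aware` (1.2) on aware
   trials, `dprime_unaware` (0.3) otherwise; response = sign(e − c₁)
   with `type1_criterion` c₁ = 0.
5. **Confidence** is high when |e − c₁| + N(0, `conf_noise_sd`) exceeds
   `conf_threshold − a·conf_aware_shift` — absolute evidence plus noise,
   with a threshold that relaxes on aware trials. This is the simplest
   mechanism that produces all three pairwise Phi correlations among
   correctness/awareness/confidence at realistic magnitudes
   simultaneously.

Defaults `conf_threshold = 0.9`, `conf_noise_sd = 0.3`,
`conf_aware_shift = 0.3` (evidence units) were calibrated once, by a
coarse grid search on a large simulation, to put the three across-subject
mean Phi values near 0.17–0.23 with a confidence base rate near 0.5;
they are fixed package defaults, not free parameters of any analysis.
The default lag-weight profile assigns lag-1 odds ratios of 3 to
awareness and confidence and 1.2 to correctness — the two subjective
ratings dominate — decaying geometrically (factor ½ in log-odds) across
lags 1→4, which yields decoding accuracy that falls from ≈ 0.72 AUC at
lag 1 towards chance at lag 4.

Randomness uses `numpy` `SeedSequence` substreams: one child stream per
subject, so tables are byte-identical for identical (config, seed) and
subjects are statistically independent.

**What the generator does not emulate:** graded confidence/awareness
scales, reaction times, staircase dynamics and non-stationarity, learning
or fatigue trends, between-subject heterogeneity in the lag weights, and
any direct influence of the prospective state on subsequent perception or
confidence (it exists as a config hook but defaults to off). Passing
recovery tests therefore shows the estimators are correct under the
stated model, not that real observers satisfy it — in particular, real
subjects differ in their history weights, which dilutes pooled
(cross-experiment) decoding in ways the homogeneous generator does not
reproduce.

## Trial tables and exclusion screening

Tables are validated on construction: canonical column schema, binary
coding (with the accepted string dialects low/high, unaware/aware,
left/right), one experiment label per table, unique contiguous
(block, trial) indices per subject, and `correct == (response ==
stimulus)` recomputed on load. Participant screening flags a subject when
(a) any cell of the session-level awareness × confidence 2×2 grid is
empty — such subjects cannot contribute to the full conditional design —
or (b) the aware rate falls below a floor (default 0.05). The empty-cell
count is reported rather than thresholded internally, so callers can
apply stricter rules. Screening is per session (the natural unit here)
and idempotent.

## Decoding pipeline

* **Design**: lag-k rows pair the feature triplet at t−k with the target
  at t over the subject's concatenated session; block boundaries are not
  breaks (a `within_block` switch exists for sensitivity analysis). Rows
  never span subjects.
* **Classifier**: scikit-learn `LogisticRegression` with C = 10⁹
  (penalty weight 10⁻⁹ relative to the likelihood), liblinear
  coordinate descent, tol 10⁻⁸, max 10⁴ iterations — near-ML fits whose
  coefficients are interpretable as log-odds ratios. Because the design
  rows are binary triplets, training rows are aggregated into ≤ 16
  weighted unique (pattern, label) pairs before fitting; the weighted
  objective is algebraically identical to the raw one and roughly 10×
  faster, which matters when the permutation null refits the model 10⁴
  times per subject.
* **Cross-validation**: 100 random 80/20 shuffle splits (unstratified);
  a split lacking a target class in either set is redrawn, up to 1000
  attempts. AUC is computed from the probabilistic predictions.
* **Empirical null**: feature rows and target entries permuted
  *independently*, the full cross-validation re-run per iteration
  (default 100); the null mean is the empirical chance level and centres
  on 0.5.
* **Group inference**: two-sided sign-flip permutation test on the
  subject-level (mean AUC − chance) differences with the +1-corrected
  p-value, so the smallest attainable p is 1/(1+resamples); Bonferroni
  multiplies by the number of lags, capped at 1.
* **Odds ratios**: exp of the fold-averaged coefficients per subject
  (a full-data refit is stored alongside for comparison); across-subject
  means carry percentile-bootstrap 95% CIs with 1000 resamples.

## Signal detection estimation

Type-1: d′ = z(HR) − z(FAR), c = −(z(HR)+z(FAR))/2, with left = S1 =
signal. Type-2: meta-d′ maximizes the multinomial likelihood of the
confidence counts conditional on (stimulus, response) under an
equal-variance Gaussian model whose type-1 criterion is rescaled
proportionally, c′ = c·(meta-d′/d′), with one type-2 criterion offset
per response side (offsets ≥ 0 enforce the ordering t2(S1) ≥ c′ ≥
t2(S2)). Numerical choices:

* **Padding**: 1/(2K) = 0.125 added to each of the 8 cells (K = 4
  response categories per stimulus) before any rate or likelihood is
  computed, preventing degenerate 0/1 rates; d′ and c are taken from the
  padded marginals so the type-1 and type-2 models see the same data.
* **Optimizer**: L-BFGS-B over (meta-d′, offset₁, offset₂) with
  meta-d′ ∈ [−5, 5], restarted from meta-d′ ∈ {d′, d′/2, 0}; the best of
  the three restarts is kept. An independent profile-likelihood grid
  search (0.001 steps; the two criterion offsets optimized per grid
  point, exploiting the factorization of the conditional likelihood over
  response sides) serves as the test oracle and agrees within 0.01 on
  all fixtures.
* **M-ratio**: meta-d′/d′, flagged undefined when |d′| < 0.1 to avoid
  exploding ratios in near-chance cells; undefined cells are reported,
  never imputed.

Condition grids estimate all of the above per subject in each
awareness × prospective cell and export a tidy long-format table for
downstream repeated-measures analysis (which is deliberately left to
standard statistics libraries).

## Transfer decoding

All subjects of each experiment are pooled before splitting (subject
identity is not blocked by default; a subject-blocked variant would be a
methodological comparison, not the primary analysis). Per iteration a
fresh random 80% of the pooled source design trains the model and a
fresh random 20% of the pooled target design is scored; the p-value
compares the mean AUC with a null built by independently shuffling the
target design's rows and targets and repeating the procedure. Transfer
p-values are a design choice of this package (permutation-based, like
the within-experiment nulls), since alternatives (parametric t against
0.5) make stronger assumptions on the iteration distribution.

## Pipeline sizes and reproducibility

The full pipeline (`metahistory all`) uses the 100-split / 100-permutation
settings; `--fast` runs 20/20 for quick iteration and CI-style smoke
checks. Test-suite simulations use reduced subject counts or session
lengths where the property under test does not depend on the full size
(e.g. null-calibration checks use 3 subjects at full resampling depth —
the null's centre does not depend on subject count; recovery checks use
the full 15 subjects). A single pipeline seed deterministically derives
all stage substreams (FNV-style hash of stage labels), and the manifest
records config, versions and seeds so every number in a report bundle is
reproducible.

## Known limitations

* The meta-d′ model is the equal-variance, response-specific-criterion
  convention; unequal-variance and hierarchical variants are out of
  scope.
* Exact replication of the original study's subject-level statistics
  (F values, effect sizes, AUC curves) requires the real behavioural
  data; the synthetic pipeline reproduces calibration targets and
  qualitative structure (lag decay, bidirectional lag-1 transfer), not
  subject-specific numbers.
* With homogeneous generative weights, pooled transfer decoding remains
  above chance at every lag with a nonzero weight; the empirical
  finding that transfer vanishes beyond lag 1 is reproduced under a
  lag-1-only shared-weight scenario, not under the default decaying
  profile.
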