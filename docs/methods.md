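# Methods

This note documents the modelling and numerical choices behind `optxfe`:
what each stage assumes, which parameters matter, what the synthetic data
generator does and does not emulate, and where the design was genuinely
open.

## Channel-identity transformation

The Operational Transformer converts a `len × cn` segment into five
identity sequences.  For each of the `len − 1` consecutive-sample pairs
`(A, B)` the five operator outputs (max, min, sum, absolute difference,
ratio) are ranked in descending order, so a block records *which channels
dominate* under each comparison at that instant.  The statistic is ordinal:
multiplying the whole signal by a positive constant leaves the first four
operators' identities unchanged, and the ratio operator's as well whenever
`ε` is negligible against the signal scale.  The transform makes no
stationarity or spectral assumptions; it only requires finite samples and
at least two channels.

Choices that were open and how they were fixed:

- **Block count.**  The per-pair loop runs over `i = 1..len−1`, so each
  operator emits `len − 1` blocks.  (An alternative reading with `len`
  blocks would change each transition-table total by at most `cn − 1`
  counts and no feature dimensions; the loop-bound reading is used.)
- **Tie-breaking.**  Descending sort with ties resolved toward the smaller
  channel index (stable sort on the negated values).  Any deterministic
  rule would do; this one is platform-independent and makes the
  constant-signal case reproduce the identity permutation.
- **Ratio guard.**  `out₅ = A/(B+ε)` with `ε = 1e-12` by default
  (configurable).  Because `B + ε` can still be arbitrarily close to zero
  when `B ≈ −ε`, any denominator with `|B+ε| < ε` is replaced by a
  sign-preserving `ε`.  At realistic signal scales (|B| ≫ ε) this guard
  never fires and the ratio ordering is unaffected.
- The operator bank is extensible (`OperatorBank(extra_operators=...)`);
  downstream feature indexing adapts to the bank size, but the bundled
  interpretability table assumes the five-operator layout folds onto one
  channel grid, which holds for any bank size.

## Transition-table features

Each identity sequence is summarised by first-order transition counts over
the *entire* flattened sequence, i.e. pairs spanning consecutive blocks are
counted (each operator's table then sums to `(len−1)·cn − 1`).  This is the
literal reading of the running index; a flag (`include_cross_block=False`)
provides the alternative, which changes the total to `(len−1)·(cn−1)`.

The flattening `u = (w−1)·cn + q` (row index fastest; a column-major read)
is **mandatory**, because the interpretation stage recovers the channel
pair by integer division and modulus; any other layout would silently
scramble the symbolic output.  The round-trip is tested exhaustively for
`cn ≤ 6` over all five operator blocks.

## NCA weighting and CWINCA selection

Per-feature relevance weights come from a diagonal neighborhood component
analysis: with z-scored features and weighted city-block distance
`d_w(i,j) = Σ_r w_r²|x_ir − x_jr|`, the soft-neighbour probabilities
`p_ij ∝ exp(−d_ij/σ)` define the expected leave-one-out accuracy
`(1/n)Σ_i Σ_{j:y_j=y_i} p_ij`, maximised over `w` minus a ridge penalty
`λΣw_r²`.  Numerical choices:

- full-batch gradient ascent, initial weights 1, at most 100 iterations,
  step-size halving (up to 20 halvings) with a mild growth factor on
  success; convergence when the objective gain falls below 1e-6.  The
  optimiser is deterministic — no sampling, no random init.
- `λ = 1/n` (a standard default for this estimator family).
- kernel width `σ` set to the mean pairwise distance at initialisation.
  With thousands of features the unit-weight distances are large, and a
  fixed `σ = 1` would start in a vanishing-gradient plateau; scaling by
  the observed mean keeps the soft-neighbour probabilities informative
  from the first iteration.
- the returned weight of feature r is `w_r²` (non-negative by
  construction); duplicated columns receive identical gradients and hence
  identical weights, and constant columns decay toward zero under the
  ridge term.
- the pairwise |difference| tensor (`n² × d` float32) is precomputed; a
  guard raises for problem sizes where it would exceed ~800 MB, which is
  far beyond this package's intended desk scale.

CWINCA then sorts features by descending weight, normalises to sum 1, and
takes `start_k` / `stop_k` as the smallest k whose cumulative weight
reaches 0.5 / 0.99 (defaults; both configurable).  Every top-k candidate
for `k = start_k, start_k+step, …, stop_k` (default step 1) is scored by
10-fold CV accuracy of the 1-NN/L1 classifier on the full matrix, and the
most accurate candidate is returned, ties resolved toward the smallest k
(parsimony).  The candidate evaluator is pluggable.

## Classification and validation

1-NN with city-block distance, equal weights; distance ties go to the
smallest training-row index (first-minimum rule), making predictions
deterministic.  No feature scaling is applied before the classifier — the
features are raw transition counts on a common scale; a z-scoring option
exists upstream for users who add heterogeneous features.

Two protocols: stratified segment-level k-fold (10 folds by default,
seeded shuffling; stratification is a variance-reduction choice) and LOSO,
one fold per subject.  Segment-level k-fold can place segments of the same
subject in both training and test folds, so on subject-structured data it
is the optimistic protocol and LOSO the honest generalisation estimate;
their gap is itself a tested property.

**Selection bias and the nested mode.**  The default
select-once-then-cross-validate flow reports, for the chosen k, the same
CV statistic that the selection maximised, so the headline number carries
an optimistic bias — on pure-noise data the full pipeline reports ~70%
rather than 50% at n = 48.  `fit(nested=True)` therefore re-runs the
selection inside each training fold (k-fold and LOSO alike), giving an
unbiased out-of-fold estimate; under label permutation the nested accuracy
is statistically indistinguishable from chance (measured 44–54% across
seeds at n = 48).  The chance-level tests assert on the nested estimate;
the default mode is kept for fidelity to the simpler common practice and
for the interpretability stages, which operate on the single selection.

Metric conventions: class 1 (epilepsy) is the positive class; geometric
mean is `√(sensitivity · specificity)`; a metric whose denominator is
empty is reported as NaN and flagged, never silently zeroed.

## Symbolic interpretation

Feature index → channel pair uses the inverse of the mandated flattening;
the first symbol of each pair comes from the integer-division term (the
transition's target channel `w`), the second from the modulus term (source
`q`).  The 35-entry channel→symbol table is positional, covers all 13
symbols, and is validated at load; montages with other channel counts
require an explicit table.  Duplicate channel pairs among selected features
are *not* deduplicated — `nsf` features always yield `2·nsf` symbols.

Histogram bins are the 13 symbols in a fixed alphabet order; probabilities
are counts over the total; entropy is base-2 (so the 13-symbol maximum is
`log₂13 = 3.7004` bits) and the complexity ratio is the entropy as a
percentage of that maximum.  The connectome matrix counts directed
adjacent-symbol transitions over the full string, including across feature
boundaries.  These outputs describe the selected features' regional
composition; they are not clinical connectivity or seizure-localisation
maps.

A 144-symbol reference sentence from this method's published 35-channel
epilepsy analysis ships as a plain-text fixture; its symbol count (144),
dominant symbol (TR), entropy (2.4015 bits) and complexity ratio (64.90%)
anchor regression tests and the acceptance script.

## Synthetic data

The generator emulates the *shape* of a segmented clinical recording
campaign, not seizure physiology:

- **baseline**: per-channel AR(1) noise (coefficient 0.9, innovation SD
  `noise_sd`, default 1.0) — gives EEG-like temporal correlation;
- **class signal**: class-1 segments receive Poisson(`burst_rate`,
  default 3 per segment) burst events — Hann-windowed 3 Hz oscillations
  with a second harmonic, 0.5–2 s long, amplitude `burst_amplitude`
  (default 6× the noise scale) — added to a fixed channel subset (for the
  35-channel default, the temporal-lobe positions of the bundled table).
  During a burst those channels dominate the amplitude ranking, which is
  exactly the statistic the transform measures;
- **subject structure**: each subject has per-channel gain multipliers
  `|N(1, subject_gain_sd²)|` (default SD 0.3) shared by all of the
  subject's segments, creating the subject signature that widens the
  k-fold/LOSO gap;
- **determinism**: one RNG stream per dataset; all subject gains are drawn
  before any segment noise, so growing `segments_per_subject` never
  changes earlier subjects' gains.

Defaults are 10 subjects per class × 4 segments, 35 channels, 7500 samples
(15 s at 500 Hz).  Tests use smaller montages and shorter segments (6–8
channels, 300–500 samples, 4–6 subjects per class) — chosen as the
smallest sizes at which the class signal, the subject effect and the
chance-level null are all clearly measurable.  What passing tests show: the
pipeline recovers a planted transient channel-dominance signal, behaves at
chance without one, and exhibits the expected protocol gap.  What they do
not show: performance on real EEG, robustness to artifacts, electrode
mispositioning, or inter-subject anatomical variability beyond a
multiplicative gain.

## Degenerate inputs and edge behaviour

Non-finite samples, single-class labels, all-zero weight vectors, empty
training sets, fewer than 2 subjects (LOSO) and out-of-range identities
all raise with specific messages rather than propagating NaNs.  Constant
signals produce the identity permutation in every block (tie-break
contract).  EDF export quantises to the format's 16-bit range (the only
loss, tested); EDF reading requires a single sampling rate and drops the
trailing partial window.

## Known limitations

- The NCA pairwise tensor bounds the number of segments usable in one
  selection run (≈ `n²·d` float32 entries); very large studies need
  feature pre-screening or chunked variants.
- With `step = 1` and a weakly concentrated weight profile the candidate
  range can span a large fraction of the feature count, making selection
  the dominant cost — as expected for this family of methods.
- Only the 1-NN/L1 classifier is built in; the candidate evaluator and the
  classifier hook accept any callable for bake-offs against other models.
- The 13-symbol table is montage-specific; interpretability for other
  montages depends entirely on the user-supplied channel→symbol mapping.
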