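# Methods

`eegmotif` implements a hand-modeled (non-deep) architecture for two-class
EEG epoch classification, built from five stages: a tunable Q-factor
wavelet decomposition, an ordinal ternary-motif-pattern (TMP) feature
extractor plus a statistical moment generator applied at 19 levels, a
thresholded neighborhood-component-analysis (NCA) feature selector, a
weighted k-nearest-neighbour classifier under two cross-validation
schemes, and an iterative hard majority vote across channels.  This note
records the model, its assumptions, the tunable parameters, and the
numerical and design choices that were genuinely open.

## Data model

An epoch is a channels × samples matrix (default 14 × 512, i.e. 4 s at
128 Hz) with a subject id and a class label, 1 = healthy, 2 = ADHD-like.
Epochs are stored as plain delimited text with full (`%.17g`) precision, so
write/read round-trips are bit-exact; a CSV manifest
(`record_id,subject_id,label,path`) carries the subject grouping that
leave-one-subject-out validation needs.  No preprocessing (filtering,
artifact rejection) is applied anywhere: the architecture is designed to
work on noisy signals as recorded.

## Tunable Q-factor wavelet transform

The TQWT is an iterated two-channel filter bank defined in the DFT domain.
With quality factor `Q` and redundancy `r`, the per-stage scaling factors
are `β = 2/(Q+1)` and `α = 1 − β/r`; each stage maps the current low-pass
signal of length `m` to a low-pass branch of length `2·round(α^j n/2)` and
a high-pass branch of length `2·round(β α^(j−1) n/2)` (computed from the
*original* length `n`, with deterministic half-up rounding).  The
transition between pass- and stop-band uses
`θ(ω) = ½(1+cos ω)√(2−cos ω)`, which satisfies `θ(ω)² + θ(π−ω)² = 1`, so
the bank conserves energy exactly and inverts perfectly; the test suite
checks both to 1e-8 over 100 seeded signals, and in practice both hold to
machine precision (~1e-15).

Defaults are `Q = 4`, `r = 3`, `J = 17`, giving 18 subbands (17 details +
the final scaling band) and, with the raw signal, 19 level signals per
channel.  An alternative reading of the level parameter — 18 detail bands
with the scaling band discarded — is available via
`use_scaling_band=False` with `J = 18`; both give 19 levels and 9500
features.  The level cap is `max_levels(n) = ⌊log(βn/8)/log(1/α)⌋`
(every subband keeps ≥ 8 samples); exceeding it raises.  Odd-length
signals are zero-padded by one sample (512 is even, so the default path is
unaffected).

## Ternary motif patterns

Within each stride-1 window of five samples, the ten ordered pairs
(i, j), i < j, taken in nested order (i ascending, then j), are compared
with a ternary function: 0 if less, 1 if equal, 2 if greater.  Digits 1–5
and 6–10, weighted by 3⁰..3⁴, form two base-3 codes in [0, 242] — the two
"map signals".  Their 243-bin histograms, concatenated, give 486 raw
counts per level signal.

Choices worth recording:

* Equality is exact (`τ = 0`) by default; on continuous EEG the tie digit
  is structurally present but rarely taken.  A tolerance knob widens the
  equality band to `|a−b| ≤ τ` for quantised data.
* Histograms are raw counts, not normalised — min-max scaling happens once,
  feature-wise, at the selection stage.
* Because only order relations enter, the features are exactly invariant
  under strictly increasing transforms, and negating the signal reverses
  each histogram (code `m` ↦ `242 − m`).  Both invariances are asserted in
  tests, as is exact agreement with a naive triple-loop reference.
* On continuous signals only codes whose digits are consistent with a
  strict ordering occur, so most of the 243 bins are structurally zero —
  which is precisely what the downstream threshold elimination removes.

## Statistical moments

Fourteen per level signal: max, min, mean, sample variance (divisor
`n−1`), standard deviation, median, range, RMS, energy `Σx²`, Shannon
entropy `−Σx²ln x²` (with `0·ln 0 := 0`), sure entropy
`n − #{|x| ≤ ε} + Σ min(x², ε²)`, log-energy entropy `Σ ln x²` (zero
samples contribute `ln δ²`, `δ = 1e−12`), threshold entropy `#{|x| > ε}`,
and mean absolute deviation.  The four entropies follow the common
wavelet-entropy conventions on squared coefficients; `ε = 0.2` and natural
logarithms are defaults, all configurable.  These are conventions, not
canon: the moment list names the quantities but not their formulas.

## Feature assembly

Per channel: level 0 is the raw signal, levels 1..17 the detail subbands
(highest-frequency first), level 18 the scaling band.  Each level
contributes its 486 motif counts then its 14 moments, giving
19 × 500 = 9500 features whose provenance (level, extractor, index) is
carried in the column metadata and survives CSV round-trips.

## Thresholded-NCA selection

Stage one: min-max normalise each feature to [0, 1] (constant columns map
to zero) and drop every column whose sum is not above the threshold
(default 0 — exactly the constant/never-occurring features).  Stage two
learns one nonnegative relevance weight per surviving feature by
maximising

    F(w) = (1/n) Σ_i p_i − λ Σ_r w_r²,
    p_ij ∝ exp(−Σ_r w_r² |x_ir − x_jr| / σ),

the softmax leave-one-out nearest-neighbour objective, by deterministic
full-batch gradient ascent from `w = 1` with a grow/shrink line search
(accepted objective values are non-decreasing by construction).  The top
250 features by weight are kept, ties broken toward the lower original
index.

Two numerical choices matter and were set after measuring degenerate
alternatives:

* **Regularisation.**  Default `λ = 1/n²`, the mean-form equivalent of the
  customary sum-form default `Σ_i p_i − (1/n) Σ w_r²`.  With `λ = 1/n` in
  the mean form the penalty at the all-ones start (`λ·d ≈ 5` for
  `d ≈ 1000`) dwarfs the ≤ 1 data term; every weight collapses toward zero
  and the resulting ranking is numerical noise.
* **Kernel width.**  Default `σ` = the standard deviation of the
  off-diagonal pairwise distances at the all-ones weights.  The distance
  *mean* grows like `d` while its *spread* grows like `√d`; scaling by the
  mean therefore flattens the softmax toward uniform for wide matrices
  (and a fixed `σ = 1` collapses it to one-hot), either way starving the
  gradient.  Bandwidth-from-spread keeps the softmax responsive at any
  feature count; with it, the selector recovers 20/20 planted informative
  features among 9500 on every tested seed.

For speed the pairwise per-feature absolute differences are precomputed as
a single float32 tensor when it fits in a configurable memory budget
(default 3 GB), making each iteration two BLAS contractions; otherwise
they are streamed in feature chunks (both paths are tested to agree).

**Where selection sits relative to cross-validation.**  The default,
architecture-faithful mode fits selection once on the full dataset before
cross-validation, which leaks label information into the features the CV
later sees.  The `nested_selection` mode refits normalisation and
selection inside each training fold and is the honest generalisation
estimate; it is the mode in which the permuted-label control below is
meaningful.  Measured on the default synthetic dataset: under full-dataset
selection even permuted labels score ≈ 0.9, while nested selection drops
the permuted control to chance and keeps the real labels ≈ 0.9.

## Classification and validation

Weighted kNN with `k = 10`, L1 distance, squared-inverse (`1/d²`) distance
weights.  All tie rules are pinned for determinism: equal distances rank
by lower training index; a zero-distance neighbour gives its class
infinite score (several: majority among them, ties to the smaller label);
equal class scores go to the smaller label.  Validation is either seeded
stratified ten-fold (stratified to respect the class imbalance the method
targets) or leave-one-subject-out, one fold per subject, with a hard
internal assertion that no subject ever spans train and test.  Out-of-fold
predictions are assembled in record order.

## Iterative hard majority voting

Channels are sorted by out-of-fold accuracy (ties toward the lower channel
index); for each prefix of size r = 3..C the per-record mode of the top r
prediction vectors (mode ties to the smaller label, i.e. healthy) is a new
voted vector — C − 2 of them.  The final result is the most accurate of
all C + (C − 2) candidates; accuracy ties prefer voted vectors (they pool
more channels) and then the lower index.  With 14 channels this yields 12
voted vectors and 26 candidates.  Metrics are accuracy and the geometric
mean `√(sensitivity × specificity)` with class 2 as positive.

## Synthetic data

The generator emulates exactly the structure the pipeline assumes and
nothing more: per record, unit-variance band-limited Gaussian noise in the
four classical rhythm bands (delta/theta/alpha/beta, 4th-order Butterworth,
zero-phase) scaled to baseline powers 40/25/20/10 µV², summed with white
noise (σ = 2 µV).  Class 2 multiplies theta power by 1.8 and beta power by
0.6 — a theta/beta contrast of the kind reported in the ADHD EEG
literature.  Each subject carries lognormal (σ = 0.3) multiplicative
random effects on its band powers, shared across that subject's records,
so subject-held-out validation is strictly harder than record-level
ten-fold splitting.  Channels mix a shared per-band source with
channel-specific noise (50/50 in power), so they correlate without being
copies.  The default dataset is 10 subjects per class × 10 records = 200
records.  All draws flow from one seed; identical seeds give byte-identical
record files.

What passing tests on this generator do **not** show: robustness to real
artifacts (eye blinks, muscle, drift), 1/f background structure, realistic
channel topography, or any clinical validity of the theta/beta contrast.
They show the pipeline's stages compose correctly and that a genuine
spectral class difference with subject confounding is detected, ranked,
classified and fused as designed.

## Problem sizes used in the automated checks

The conservation and oracle checks run on hundreds of short seeded
signals.  The selector-recovery check uses the full 200 × 9500 planted
design on five seeds; the end-to-end check runs all 14 channels of the
default 200-record dataset — faithful mode for both CV schemes, nested
mode for the real-vs-permuted margin.  These sizes keep a complete run on
one CPU in the tens of minutes while exercising every stage at its real
width (9500 features, 14 channels).

## Known limitations

* The NCA ascent is a local method; the line search cannot jump between
  distant basins, which is why the kernel-width choice above matters.
* With continuous inputs the motif tie digit is dead weight (121 of 243
  bins per map can only be hit through exact ties); the elimination stage
  absorbs this.
* LOSO accuracy depends on the manifest's subject mapping being truthful;
  nothing in the data can verify it.
* The EDF reader (optional, via `mne`) epochs from sample 0 with no
  overlap and no annotation handling.
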