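# Methods

This note documents the models, algorithms and design choices behind
`leafspot`: what each stage computes, which parameters matter, what the
synthetic generator does and does not emulate, and the numerical
conventions used throughout.

## Data model

A `SpectrumSet` is a matrix of intensity vectors on one strictly
increasing wavenumber axis (cm⁻¹) plus per-row metadata: spectrum id,
leaf id, treatment group (CK/ND/PD/KD), stress duration (24/72/120/168 h)
and integer grid coordinates. Grid row 0 sits at the leaf base and column
0 along the main vein; physical position is `index × spacing_cm` (1.0 cm
pitch by default, matching a dot-matrix template with 1.0 cm hole
spacing). Axes are never resampled: spectra with mismatched axes are
rejected rather than interpolated, because silent interpolation would
change peak shapes that the similarity statistic is sensitive to. Raw
files may carry a `replicate_id` column (consecutive acquisitions at one
position); the preprocessing chain averages them to one spectrum per
position.

## Preprocessing

**Baseline.** Leaf tissue under 785 nm excitation produces a broad
fluorescence background that dwarfs the Raman peaks. The estimator is an
iterative moving-average clipping smoother: starting from the raw
spectrum, each of `iterations` passes replaces the running estimate by
the pointwise minimum of itself and its centred moving average
(`window` points, reflect padding at the edges to avoid endpoint droop).
Narrow peaks are progressively shaved off while the smooth background
survives. Defaults are window 31 and 5 iterations — the settings of the
acquisition protocol this pipeline models. The corrected spectrum is
`max(raw − baseline, 0)`; clipping keeps every curve above the zero axis.

Two behaviors of this estimator family are worth knowing:

- In strongly curved background regions (here 200–700 cm⁻¹, the flank of
  the fluorescence hump) the estimate sits slightly below the true
  background — a curvature bias of roughly `f″·W²/24` per pass — so a
  smooth positive residual survives correction there. This mirrors what
  practitioners see on real leaf spectra: the low-wavenumber zone is
  never fully corrected. An optional `--range` trim is provided but off
  by default.
- Correction is therefore *not* idempotent: a second pass strips a
  substantial part of that residual again (and a little of each peak).
  What holds, and what the test suite asserts, is convergent stripping —
  successive passes remove strictly diminishing amounts, and peak apexes
  survive a second pass nearly intact. A hard "second pass removes ≤ 5%"
  bound is not attainable for this estimator at these settings on
  fluorescence-dominated input.

**Normalization.** Per-spectrum min–max scaling to [0, 1] by default
(matching the convention of plotting normalized curves per spectrum); a
unit-Euclidean-norm alternative is provided. Cosine similarity is
scale-free, so the choice does not affect similarity values; it does
affect the PLS-DA feature scale, where min–max keeps all channels in a
comparable range. A constant row (max = min) normalizes to zeros with a
logged warning rather than an error, since a dead channel row should not
abort a batch run.

## Similarity screening

Every preprocessed spectrum is compared to the channel-wise mean of all
preprocessed spectra of its leaf via the cosine of the angle between the
two vectors. The leaf mean is computed once, before any exclusion
(single-pass; no re-computation of the mean after cleansing — an
iterative variant would change thresholds mid-analysis and is
deliberately out of scope).

Two flags are derived from a similarity population:

- `is_outlier`: strictly below Q1 − 1.5·IQR (the box-plot lower whisker),
  computed on the pooled population by default — the convention for a
  single descriptive box plot of the whole campaign.
- `below_q1`: strictly below Q1. The cleansing step applies this
  per leaf, so each leaf loses its own worst quartile regardless of how
  good the leaf is overall.

Quartiles use linear interpolation of the empirical distribution (the
"type 7" convention, numpy's default); the choice is visible wherever a
quantile appears and the brute-force oracle in the test suite pins it.
Strict inequality means ties at Q1 are kept.

The value 0.991 is carried through as a *stability floor*: the similarity
level that repeat acquisitions at a fixed position stay above, so a
position scoring below it differs from its leaf consensus by more than
instrument noise. It is a reference benchmark for reporting, never a hard
filter.

## Spatial mapping and region enrichment

For each leaf, a matrix over the bounding grid holds the similarity value
where the position is below-quartile, 1.0 at other in-leaf positions and
NaN outside the leaf (missing is never conflated with 1.0). Region labels
are assigned deterministically: margin = any in-leaf cell with an
out-of-leaf 4-neighbour; vein = remaining cells in the two columns next
to the main vein; base = remaining cells in the two lowest occupied rows;
interior = the rest (precedence margin > vein > base). This is a
geometric proxy for anatomical regions that makes region claims testable
on arbitrary grids. Enrichment of a region is
`fraction of all flags landing there / fraction of all cells it offers`;
1.0 means flags are indifferent to the region.

## PLS-DA classifier

Classes are one-hot encoded and the spectra regressed onto the class
matrix by PLS (`scikit-learn`'s NIPALS implementation, no per-channel
scaling); prediction is the arg-max class score, ties broken by the fixed
class order CK < ND < PD < KD for determinism. The LV count is chosen by
stratified K-fold cross-validation (K = 5, seeded) over 1..15: the
smallest count whose mean CV macro-F1 is within τ = 0.5 points of the
grid maximum. τ operationalizes "smallest count with stable performance";
K is a conventional default. If the CV profile is still rising at the
grid edge a "no plateau" warning is raised. The train/test split
alternates spectra in collection order within each group × duration
stratum, so both halves cover all classes and acquisition drift equally.
Metrics: 4×4 confusion matrix, misdiagnoses (off-diagonal total) and
unweighted class-mean precision/recall/F1 in percent; a class never
predicted contributes precision 0 with a warning rather than NaN.
Cross-validation metrics are computed on the training half only,
consistent with a held-out test set.

## Nutrient chemistry

Pure calculators for dry-weight N/P/K content (g·kg⁻¹) from bench
readings: Kjeldahl titration for N
(`(V₂−V₀)·c·0.014 / (m·V₁/V) · 100`), molybdenum-antimony colorimetry for
P (`ρ·(V/m)·(V₂/V₁)·10⁻⁴`) and blank-corrected flame photometry for K
(same form with ρ − ρ₀). The K formula is implemented with the blank
subtracted before the volumetric factors, by parallel with the P formula.

## Synthetic generator

The generator is the package's study definition, not a test convenience:
its defaults are the conditions every multi-seed study runs under.

- **Design:** 4 groups × 4 durations × 3 leaves, half-ellipse grids on
  the vein side of the leaf (8 × 6 bounding grid, ellipse scale jittered
  per leaf), ~30 in-leaf positions per leaf, ~1400 spectra per study.
  Axis 200–3400 cm⁻¹ at 4 cm⁻¹ steps.
- **Spectrum model:** broad log-normal fluorescence hump (amplitude 3000
  counts, mode near 450 cm⁻¹, smooth enough that a 31-point window can
  track it) + 20 Gaussian peaks at the characteristic leaf-tissue
  positions 747…3191 cm⁻¹ (σ = 5 cm⁻¹ — at wider widths the 1288/1301
  pair merges into a single local maximum and ceases to be resolvable on
  this axis) + i.i.d. noise of 10 counts per acquisition, averaged over
  3 acquisitions per position.
- **Class signal:** each deficiency multiplies a small set of
  biochemically plausible peaks by 0.65–1.30; the effect ramps from 60%
  expressed at 24 h to 100% at 168 h, so early stress is hardest to
  classify, as observed in practice.
- **Position variability:** 2% multiplicative jitter on every peak
  amplitude per position, giving a continuous similarity distribution
  (normal positions ≈ 0.999).
- **Anomalies:** a position is anomalous with probability 0.50 (margin),
  0.35 (vein/base) or 0.03 (interior), scaled by 1.0 / 0.30 / 0.25 / 0.12
  at 24/72/120/168 h — frequent early, nearly gone late. An anomalous
  position has a random ~half of its peak amplitudes multiplied by
  U(0.35, 0.75) and a local baseline bump added (15% of the fluorescence
  amplitude, 60–120 cm⁻¹ wide); its class label is unchanged. This drops
  its cosine similarity to ~0.92–0.98 against ~0.999 for normal
  positions, reproducing pooled similarity statistics (min ≈ 0.92,
  sd ≈ 0.02) in the realistic range.
- **Replicate model:** repeat acquisitions at one position share the
  position's true spectrum and differ by fresh 10-count noise. Because
  the shared fluorescence background dominates the vector norm, raw
  replicate similarities sit near 0.9999 — comfortably above the 0.991
  floor. This is conservative: only shot-like noise is modeled, not the
  slow drift that makes real repeat-acquisition minima decline toward the
  floor as the count grows.

**What passing tests show — and don't.** The generator reproduces the
*structure* the screening exploits (margin-concentrated anomalies,
duration-dependent anomaly rates, separable class signatures, calibrated
instrument noise). It does not model physical Raman cross-sections,
instrument transfer functions, leaf-shape diversity beyond an ellipse, or
correlated/multiplicative noise. Results on synthetic data therefore
validate the pipeline's mechanics and its qualitative behavior, not
field-level accuracy numbers.

## Study sizes and numerical conventions

Multi-seed studies use 100 seeds (replicate stability), 20 seeds (margin
enrichment) and 10 seeds (cleansing effect); each study derives its
per-seed stream from a single base seed, so every reported number is
reproducible from one integer. Peak recovery is scored as a strict local
maximum against immediate neighbours matched within 8 cm⁻¹ (two channels,
about the modeled instrument resolution); a stricter two-channel
dominance test misreads the 1288 cm⁻¹ apex on its neighbour's shoulder.
Leaves with fewer than 4 spectra pass through cleansing untouched (a
quartile of 3 values is noise) with a warning. Degenerate inputs
(zero-norm vectors, empty sets, single-class training data) raise errors
rather than returning silent defaults.

## Known limitations

- The cleansing threshold assumes ~30 positions per leaf; on much smaller
  leaves the per-leaf quartile is unstable and pooled cleansing should be
  preferred.
- The baseline estimator's curvature bias leaves the 200–700 cm⁻¹ zone
  under-corrected (see above); analyses sensitive to that zone should
  trim it.
- Anomaly detection precision degrades gracefully as anomaly magnitude
  approaches the positional jitter; the defaults keep the two regimes
  well separated, which real data may not.
- PLS-DA is the only classifier offered, by scope; no probability
  calibration or feature selection is performed.
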