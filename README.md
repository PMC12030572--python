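# leafspot

Spectral-position screening for Raman-based early nutrient-deficiency
diagnosis in plant leaves.

## The problem

Raman spectra collected at different positions on the same leaf are not
equally trustworthy: positions near the leaf margin, the main vein and the
leaf base produce spectra that deviate from the leaf's consensus
composition, and feeding them to a diagnostic classifier degrades it —
most severely in the earliest hours of nutrient stress, exactly when a
diagnosis is most valuable. `leafspot` implements a dot-matrix screening
pipeline for this problem: score every sampled position by the cosine
similarity of its spectrum to the leaf's mean spectrum, map and flag
low-similarity positions, exclude them per leaf, and quantify what the
exclusion buys a PLS-DA nutrient-deficiency classifier.

The pipeline is exercised end to end on a synthetic leaf-scan generator
with known ground truth (group signatures, anomalous positions, noise),
because measured leaf-scan campaigns of this design are not publicly
available.

## The method

Each spectrum is a vector of intensities **A** = [A₁, A₂, …] over a common
wavenumber axis (200–3400 cm⁻¹). After baseline correction (iterative
moving-average clipping smoother, window 31 points, 5 iterations) and
per-spectrum min–max normalization, every position is scored against its
leaf's channel-wise mean spectrum **B** by

cos θ = Σᵢ AᵢBᵢ / (‖A‖‖B‖),

which is scale-free and reflects spectral shape only. Two thresholds act
on the similarity distribution: **box-plot outliers** (below Q1 − 1.5·IQR
of the pooled distribution) for reporting, and the **per-leaf lower
quartile** (Q1) for cleansing — spectra strictly below their leaf's Q1 are
excluded. The diagnostic model is PLS-DA: PLS regression of the spectra
onto a one-hot class matrix over {CK, ND, PD, KD} (control, N-, P-,
K-deficient), prediction by arg-max class score, with the number of
latent variables (LVs) chosen by stratified 5-fold cross-validation as
the smallest count within 0.5 macro-F1 points of the grid optimum.
Evaluation uses an interleaved (alternating, per group × duration)
train/test split and reports the confusion matrix, misdiagnoses (MDs) and
macro precision/recall/F1.

## Worked example

The numbered drivers under `analysis/` run the whole study and write their
tables under `results/`:

```bash
python analysis/01_simulate.py            # 4 groups x 4 durations x 3 leaves
python analysis/02_preprocess_similarity.py
python analysis/03_spatial_maps.py
python analysis/04_cleanse_and_classify.py
python analysis/05_multiseed_studies.py
```

`04_cleanse_and_classify.py` prints, for the default seed:

```
PLS-DA before vs. after cleansing (macro metrics in %):
        Group  SampleSize  LVs  MDs  CV_Macro_F1  Test_Macro_F1
         24 h         360   13   36        80.19          80.09
 24 h-cleaned         267    6   10        94.11          92.44
         72 h         358    3    9        94.43          94.81
 72 h-cleaned         265    3    0       100.00         100.00
        120 h         374    4   10        96.15          94.61
120 h-cleaned         276    3    0       100.00         100.00
        168 h         334    3    2        99.41          98.80
168 h-cleaned         248    3    0       100.00         100.00
```

Reading it: each stress duration gets a pair of rows — the classifier
trained on all positions ("raw") and on the per-leaf cleansed subset
("-cleaned"). Cleansing removes ~25% of positions per leaf, and the
held-out macro-F1 rises at every duration (here +12.3 points at 24 h,
+1.2 at 168 h) while the chosen LV count and the misdiagnosis count drop.
The gain is largest at 24 h because the generator plants anomalous
positions most densely there; `03_spatial_maps.py` shows those flagged
positions are enriched at the leaf margin (enrichment ratio ≈ 1.2) and
depleted in the blade interior (≈ 0.5).

The same pipeline is scriptable on external data through the CLI:

```bash
leafspot simulate --out-dir scan/ --seed 7
leafspot preprocess --spectra scan/spectra.csv --meta scan/meta.csv --out pre.csv
leafspot similarity --spectra pre.csv --meta pre.meta.csv --out sims.csv
leafspot cleanse --spectra pre.csv --meta pre.meta.csv --similarity sims.csv \
                 --out cleaned.csv --ledger ledger.csv
leafspot run --report report.json   # the whole chain in one command
```

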