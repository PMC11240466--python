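# Methods

## Scope and data model

The package operates on per-sample MS1 centroid clouds (`MSMap`: retention
time in seconds, m/z in Da, non-negative ion counts; default scan range m/z
500–2500, positive mode), a sample manifest mapping each sample to its
stage label (early/late), batch and train/test split, and MS2 peak lists
for fragment matching.  Raw instrument data is not required: a synthetic
generator reproduces the statistical structure the analyses assume.

## Synthetic cohorts

`generate_cohort` emulates a two-cohort staging study.  Defaults encode the
study design the pipeline targets: 20 early + 19 late subjects, ~10,000
distinct background peaks per map, 65 planted differential markers with
56/65 down-regulated in the late class, two-fold differential effect,
8 landmark time markers, two batches containing both classes, ×1.1
per-batch intensity factor, 5 s retention-time drift and 15% multiplicative
noise.  (The analysis drivers run 2,000 background peaks per map, a
desk-scale choice that leaves every per-peak statistic unchanged.)

* **Intensities** are log-normal around a per-analyte base:
  `x = base · fold · batch_shift^b · exp(ε)`, `ε ~ N(0, σ)` with
  `σ = sqrt(log(1 + CV²))`, so the per-peak coefficient of variation equals
  `noise_cv` exactly and intensities stay positive.  Planted markers have
  class-mean fold change `effect` in their assigned direction.  No peak
  model is applied: each analyte is a single centroid per sample, matching
  a workflow whose extraction already yields per-peak ion counts.
* **Retention-time drift** is a per-sample monotone piecewise-linear warp
  with Gaussian node jitter at five evenly spaced anchor times — rich
  enough to make landmark alignment non-trivial, simple enough to be
  exactly invertible, and stored in the ground truth for oracle use.
* **Reference companions.**  Real serum spectra are dense enough that a
  co-eluting, near-m/z, class-comparable peak exists beside essentially
  every marker.  At desk-scale peak counts that density is lost, so the
  generator plants the structure explicitly: three non-differential
  companion peaks within ±1.5 Da / ±10 s of each marker.
* `simulate_marker_table` draws the samples × markers table directly from
  the same intensity model (skipping the RT layer), which is what the
  calibration and panel studies need at large marker counts.

What the generator does **not** emulate: chromatographic peak shapes,
isotope envelopes, charge-state interference, missingness (every analyte is
present in every sample by default), heavy-tailed contamination, or
correlated marker panels.  Passing tests therefore demonstrate the
correctness and calibration of the algorithms under the stated noise model,
not instrument-level robustness.

## Alignment and normalization

Landmarks are matched within ±0.02 Da / ±30 s; each must match exactly one
centroid, and matches must be jointly monotone.  The fitted warp maps
observed to consensus RT piecewise-linearly through the matched pairs and
extends beyond the outermost nodes with that node's constant offset — a
deliberate deviation from an identity tail, which would break monotonicity
whenever a boundary node has nonzero offset.

Reference qualification operationalizes "consistent quantitative
comparability" as: class-mean ratio within [0.8, 1.25] **and** two-sample
t-test p ≥ 0.3, searched within ±2 Da / ±30 s of the candidate (the
candidate itself is excluded).  Among qualifiers the nearest in m/z wins,
ties broken by ΔRT.  A marker with no qualifying reference is skipped
explicitly — never normalized by 1.

Extraction windows default to ±20 s / ±0.02 Da (closed intervals).
"Variation from the mean" is implemented as ratio-to-overall-mean (unit
mean per marker); a mean-centered variant is available via `mode="centered"`.
Missing peaks yield raw 0 with a missingness flag, and flagged cells are
excluded from per-marker means and downstream t-tests.

Batch adjustment is a location/scale standardization: per marker, each
batch is rescaled to the pooled cross-batch mean and standard deviation,
then the grand mean is restored exactly.  Empirical-Bayes shrinkage is
omitted deliberately — batches are balanced by design and the marker count
is modest.  The adjustment preserves *additive* class differences; under a
strong multiplicative batch factor, class-mean ratios can shift by ~10%
(tests pin the behavior at the default ×1.1 factor, where distortion is
below 6%).

## Differential screen

The fold screen keeps markers whose class-mean ratio is ≥ 1.5 or ≤ 1/1.5
(closed boundary).  Tests are equal-variance Student's t by default (Welch
by flag), two-sided.  Zero-variance degenerate cases: equal constants give
p = 1, distinct constants p = 0.  Status is U when the late-stage mean is
larger, D otherwise; exact ties resolve to D for determinism.  No
multiple-testing correction is applied by default — a deliberately
permissive discovery screen that relies on independent confirmation — with
Benjamini–Hochberg available behind a flag.

## Panel selection

Cross-validated performance uses repeated stratified 2-fold CV (default 10
repeats; 1 repeat reproduces plain 2-fold) with out-of-fold scores pooled
across repeats; pooling stabilizes the high-variance 2-fold AUC at n ≈ 24
without changing the protocol's leakage structure.  AUC is the trapezoid
ROC area (equal to Mann–Whitney concordance; asserted against a brute-force
oracle).  Reported sensitivity/specificity sit at the Youden-optimal pooled
threshold; validation additionally reports fixed thresholds (0.7, 0.9).
The forward-selection ladder is strict (`>`): 0.65 singles, 0.70 pairs,
0.75/0.85/0.90/0.95 for sizes 3–6, and extensions must beat their parent's
AUC ("beat the better parent"); subsets are cached so each combination is
evaluated once.  Classifiers are scikit-learn implementations (random
forest default, plus SVM, kNN, Gaussian naive Bayes, logistic regression)
at library defaults with seeded RNG; comparisons share identical fold
assignments, verified by hashing.

## Grid workflow

Cells are half-open `[lo, hi)`, anchored at (0 s, scan-range minimum), so
cell identity is stable across runs; within-cell aggregation is the
intensity **sum**, making per-subject conservation exact and the
fine-grid re-parse (10 s × 0.01 Da, anchored at the coarse cell's corner)
tile each coarse cell exactly.

The decision value is `|mid(A) − mid(B)| / (halfrange(A) + halfrange(B))`
with `mid` the range midpoint.  This is the simplest statistic with the
required semantics: DV ≥ 1 **iff** the closed class ranges are disjoint or
touch at a single point.  (A mean-based numerator does not have this
property.)  Degenerate cases: two identical constant classes give DV 0;
distinct constants give a cap of 10.  The statistic is pluggable should an
overlap-fraction or standardized-difference variant be preferred.  The
randomized reference for ranking plots is the mean DV over 20 seeded
within-datapoint label permutations.

The voting classifier selects the top-N datapoints by **training-split**
DV each iteration; each selected datapoint votes for the class whose
training mean is nearer to the subject's value, weighted by its training
DV, abstaining when equidistant; vote ties predict early.  Holdouts are
stratified (20%, 50 iterations by default), and real/mock comparisons reuse
identical splits so differences reflect the labels alone.  Recomputing the
selection per iteration from training subjects only is the leakage-safe
reading of a weighted-vote design and is enforced by a canary test in which
a single held-out outlier would flip the selection if it leaked.

Cluster display uses average-linkage hierarchical clustering with
correlation distance on both axes; distances involving constant vectors are
set to zero.

## Fragment ions

b/y ladders use standard monoisotopic residue masses and the hydrogen-atom
constant (1.0078250319 Da) rather than the bare proton, which reproduces
published fragment-calculator output to < 1e-4 Da (the proton constant
deviates by ~6e-4 Da).  Composite spectra are half-open fixed-width bins
(default 0.01 Da) with summed intensity, conserving totals exactly.
Matching takes the nearest observed bin within tolerance; one bin may
account for several predicted ions, and coverage is matches / 2n.  The
isoelectric point is solved by bisection on the Henderson–Hasselbalch net
charge (EMBOSS pKa set by default); it is informational output, since the
pKa table behind any printed reference value is generally unknown.

## mzML support

mzML is written and read by a minimal serializer/parser (centroid MS1,
one spectrum per distinct RT, uncompressed little-endian 64-bit arrays).
The writer's conformance is checked in the test suite by parsing its output
with an independent mzML implementation (Bioconductor mzR via Rscript).
Compressed or 32-bit mzML input is rejected explicitly; the three-column
centroid CSV dialect is the primary interchange format.

## Problem sizes

Test and driver problem sizes are the package's own desk-scale choices:
calibration uses ≥ 1000 null markers × 20 label permutations; planted-
recovery and mock-contrast studies use 10 seeds of the 20 + 19 design with
60–150 background peaks per map (statistics per peak are unaffected by the
total count); forward selection in the acceptance study screens to the top
6 candidates by training p-value before the ladder, mirroring a screen-
then-select protocol.

## Known limitations

* The location/scale batch adjustment is not empirical-Bayes; with few
  samples per batch its variance rescaling is noisy.
* The DV formula and vote rule are principled reconstructions of a
  closed-source analysis module; alternatives fitting the same published
  semantics exist and can be swapped behind the same interface.
* `build_peak_table` uses one sample as the coordinate template rather than
  consensus clustering across samples; adequate for aligned synthetic data,
  simplistic for heavily distorted real runs.
* Charge states are carried as metadata only; no deconvolution or isotope
  handling is performed.
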