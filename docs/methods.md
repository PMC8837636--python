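# Methods

This note records the models, conventions and design choices behind
`desimilk`, in the spirit of a statistical package's methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Spectra, binning and the feature matrix

A scan is a sparse centroided peak list (strictly ascending m/z,
non-negative counts). Scans with TIC below the spectral intensity limit
(default 1×10⁶ counts) are discarded as failed acquisitions before any
averaging; a sample losing every scan is an explicit error, never a
silent drop.

Mass binning uses half-open 0.2 Da intervals over m/z 100–2000 — 9500
bins labelled by their centres at odd multiples of 0.1 (537.3 labels
[537.2, 537.4)). This is the unique 0.2 Da convention under which the
bundled marker table's representative masses land in their printed bins
(27 of 28; the 1232.7 row is an inconsistency in the source table and
is shipped as printed, flagged by `verify_marker_table`). A peak
contributes its full intensity to the single bin containing it, so
binning conserves total in-range intensity exactly. `bin_index` adds a
1e-9 guard so exact-decimal boundaries fall upward despite binary
float representation.

Scan combination is bin-then-average: each scan is binned and the bin
vectors averaged arithmetically, which is insensitive to centroid
jitter between replicate scans. The feature matrix supports one row
per sample (model fitting) or one row per spectrum (used when counting
spectrum-level correct-classification rates); row metadata carries
sample id, species, cow-milk fraction and source.

TIC normalisation (row divided by its sum; zero rows removed with a
warning) is on by default for classification pipelines and off for the
S-plot/marker pipeline — the normalisation step is an auditable switch
because raw counts keep marker covariances on an interpretable scale.
Scaling is columnwise mean-centring, Pareto ((x−mean)/√sd) or unit
variance, with the population (divide-by-N) standard deviation fixed
for bit-reproducibility; constant columns are centred only, and the
stored means/scales make the transform invertible to 1e-9.

## PCA and its cross-validated Q²

PCA is computed by SVD of the column-centred matrix with a
deterministic sign convention (largest-magnitude loading element
positive). R²X per component is the captured variance fraction.

Q² uses row-wise k-fold deletion (default 7 folds) with a
speckled-prediction twist: plain projection of complete held-out rows
onto the training loadings has PRESS ≤ SS by construction and so can
never go negative, which would make Q² useless as an overfitting
guard. Instead, within each held-out row the variables are split into
interleaved groups; each group is predicted from least-squares
component scores estimated on the complementary variables only. Held
elements never participate in their own prediction, so structureless
data yields Q² ≤ 0, noiseless low-rank data yields Q² ≈ 1, and the
procedure is deterministic given its seed.

## PCA-LDA classification

The classifier projects spectra onto enough principal components to
reach a cumulative R²X target (default 0.95, capped at 60 components —
the subspace rule of the original modelling software is undocumented,
so this package declares its own), then fits Fisher discriminant axes
(at most classes−1) by the generalised eigenproblem between/within
scatter, ridge-regularising the within matrix (ε·trace/dim) when
near-singular.

Classification assigns the nearest class centroid by Mahalanobis
distance in discriminant space using the pooled within-class
covariance; a spectrum whose nearest-centroid distance exceeds the
outlier threshold (default 5 σ) is flagged an outlier. Because it is
ambiguous whether legacy software counted outliers in the CCR
denominator, both rates are always reported. Two documented options
extend the default: `covariance="per_class"` (per-class Mahalanobis,
for heterogeneous classes where a pooled covariance is miscalibrated)
and `rule="gaussian"` (adds the log-determinant term, i.e. a
quadratic-discriminant decision at equal priors).

Bootstrap validation repeats stratified 80/20 splits (default 25) at
the *sample* level — all spectra of a sample stay on one side, which
the implementation asserts — and counts correctness at the *spectrum*
level, accumulating a confusion tally.

## OPLS-DA, S-plot and marker selection

Class labels are encoded cow = −1, everything else = +1, so cow-enriched
bins acquire negative S-plot statistics. The model removes `n_orth`
(default 1) orthogonal components — w from X'y, w_o as the part of the
loading orthogonal to w, X deflated by t_o p_o' — then fits one
predictive NIPALS PLS component on the filtered matrix. With
`n_orth = 0` this reduces exactly to textbook single-component PLS1,
which the tests verify against an independent implementation. The
folded regression vector b (ŷ = Xb + ȳ) reproduces the scores-path
prediction to 1e-8 and powers the coefficient plot.

Q²Y is 1 − PRESS/SS over stratified k-fold (default 7) held-out
predictions, recentring X and y on each training fold; the fold
structure depends only on class membership, so relabelling −1 ↔ +1
leaves R²Y and Q²Y unchanged and flips every S-plot sign, as the tests
assert. Permutation validation refits under label permutations
(identity excluded; default 100) and declares the model valid only when
every permuted Q² falls below the original; the conventional
regression intercepts of R²Y and Q² versus label correlation are
reported but do not decide the flag.

The S-plot stores p1ᵢ = cov(t, xᵢ) = t'xᵢ/(N−1) and
pcorrᵢ = p1ᵢ/(sd(t)·sd(xᵢ)) with sample (N−1) conventions;
zero-variance bins get zeros. Because the covariance carries the units
of X while the conventional influence threshold (0.05) lives on the
predictive-loading scale, `SPlotResult` also stores
`p1_model = p1/var(t)` — the loading, i.e. the covariance with t
standardised — and `select_markers` applies |p(corr)| ≥ 0.5 and
|p1| ≥ 0.05 on that model scale by default (both thresholds inclusive,
so the bundled table's p1 = 0.050 row selects). Applied to the bundled
table's own printed statistics, the thresholds reproduce all 28
markers, 23 with negative p[1].

## Lipid annotation

Formulas are parsed by a deliberately small grammar (element symbols
with optional integer counts; no parentheses or isotopes) over a fixed
monoisotopic mass table (C 12, H 1.00782503, N 14.00307401,
O 15.99491462, P 30.97376200, S 31.97207117), with Hill-order
serialisation round-tripping exactly. The only adduct model is [M+H]⁺
with the electron-corrected proton mass 1.00727646 Da: every accurate
mass in the bundled table is consistent with monoisotopic + proton to
the printed precision (two ceramide rows sit on a rounding half-edge
of the fourth decimal, within 6×10⁻⁵ Da). The marker table ships as a
checksummed CSV; peak matching returns all markers within a ppm
tolerance sorted by |error|, and fragment matching works at bin
resolution against both accurate masses and bin labels.

## Adulteration levels and the limit of detection

The four mixture series use the published v/v cow-milk fractions
(goat 0/5/10/20/50/100 %, camel 0/0.5/1/2/5/10/20/50/100 %,
oat 0/0.5/5/10/20/50/100 %, soya 0/0.1/1/2/5/10/20/50/100 %). Levels
are unordered LDA classes, as such models are usually presented; the
ordinal structure is assessed afterwards by the Spearman correlation
between per-level LD1 centroids and the cow fraction, with LD1
oriented so the pure-cow end is positive.

The detection limit uses a rule of this package's own design (the
source workflow states detection limits but not the rule that produced
them). For each nonzero level: repeated sample-level 80/20 splits; a
binary discriminant trained on pure (level 0) versus pooled {level and
higher} spectra; held-out spectra of that level counted as detected
when they fall on the adulterated side of a threshold placed midway
between the pure and level-specific training centroids. The
discriminant is a sparse diagonal LDA (nearest-shrunken-centroid
flavour): per-bin training mean differences whitened by the
*pure-class* per-bin variance (floored to guard near-constant bins),
restricted to the 100 most discriminative bins by t-statistic. Two
empirical failure modes motivate this over a dense PCA-LDA detector:
the pooled adulterated class's spread along the mixing-fraction
gradient makes a Fisher criterion suppress exactly the informative
direction, and dense components dilute the ~23 trace marker bins with
thousands of background bins, burying sub-1 % levels that a sparse
marker projection separates cleanly. The LOD is the smallest level
whose held-out detection rate reaches the criterion (default 0.8)
*while* the same boundary's false-positive rate on held-out pure
spectra stays within 1 − criterion; a boundary that flags pure milk as
adulterated cannot support a detection claim. Detection rate,
false-positive rate and spectrum counts are reported for every level
regardless of the declared LOD.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes;
its defaults are the study design: 103/27/36/34/73 pure samples of
cow/goat/camel/oat/soya from 30/2/2/4/5 sources, 6–9 replicate scans
per sample, and the four mixture series (6 samples per level — the
replication of the mixture experiments is not stated anywhere, and
fewer than ~4 leaves a single pure sample per holdout).

Species profiles are built from the bundled marker table using the
*representative* (measured) masses, so annotation's ppm matching sees
realistic offsets from theory. Cow carries the 23 cow markers
(4×10⁵ expected counts each) plus 12 private peaks; camel, oat and
soya carry their attributed table rows plus their own private peaks;
60 shared matrix peaks are common to all species. Goat is deliberately
the hard class: it shares *every* cow peak position — markers and cow
privates at 85 % of cow intensity — and its own variation hides as
15 % intensity boosts on a subset of the shared peaks, never as new
peaks. Early versions gave goat private peaks at fresh m/z values and
the classifier separated goat perfectly on presence/absence alone;
intensity-only differences reproduce the observed regime in which goat
is the only species confused with cow.

Noise laws (all invented — the source states no noise model — with
magnitudes chosen once as realistic for ambient MS): mean-corrected
lognormal per-peak scan noise (σ = 0.35); Gaussian m/z jitter
(5 ppm, well inside a 0.2 Da bin); Poisson background peaks (mean 150
per scan, exponential intensities, mean 5×10³ counts) at uniform
random m/z; a lognormal per-scan TIC factor (σ = 0.10); a 2 % rate of
failed scans at ~1 % TIC, which the intensity-limit filter removes;
and a per-source ("farm") lognormal offset on species-specific peak
intensities (σ = 0.16), drawn deterministically per (seed, source) for
pure samples and per sample for mixtures, whose base and cow milks are
paired randomly. Mixtures are linear in expectation:
E[intensity] = (1−α)·base + α·cow per peak, verified by a
Monte-Carlo test. The noise-free limit reproduces profiles exactly,
and a fixed seed reproduces a study bit-for-bit.

What the generator does *not* emulate — isotopologue envelopes,
chimeric scans, peak-shape effects, matrix suppression, correlated
drift within an acquisition day — bounds what passing tests show:
they validate the chemometric machinery under the assumed statistical
structure, not instrument physics.

## Problem sizes and calibration anchors

The raw spectra behind the original study are not publicly deposited,
so its dataset-level metrics (R²X 0.898/Q² 0.867, R²Y 0.965/Q²Y 0.964,
per-pair CCRs, 0.1–5 % detection limits) serve as qualitative
calibration anchors, not reproduction targets. Generator magnitudes
were calibrated once so that default runs land in the same regime —
camel/oat/soya perfectly separated from cow, goat the only confusable
species, sub-1 % detection for the disjoint-lipidome milks — and were
not revisited afterwards. The test suite runs the study at 12 % of the
full sample design and `scripts/acceptance.py` at 20 %, sizes chosen
to keep a full run in minutes on one CPU; at these sizes goat has only
4–5 samples, so which side of the cow–goat pair absorbs the
misclassifications varies with the seed, and the acceptance script
therefore reports pair-level confusion statistics alongside per-class
rates. Goat's detection limit is the generator's known weak spot: with
goat differing from cow only through ~15 % intensity shifts, trace
levels below ~5 % cow-in-goat are often undetectable, whereas the
marker-bearing milks reach 0.1–1 %.

## Known limitations

* Single-charge [M+H]⁺ only; no isotope patterns, no other adducts.
* The formula grammar rejects parentheses and isotope labels by design.
* The mzML reader is minimal (centroided MS1, zlib/uncompressed 32/64-bit
  float arrays) and intended for interchange, not vendor-file coverage.
* Pareto scaling and TIC normalisation are global (fitted on the whole
  matrix) before cross-validation splits, mirroring common chemometric
  practice at the cost of a small information leak across folds.
* The LOD rule's criterion rate, bin count and thresholds are exposed
  configuration, and reported limits should be read relative to that
  rule, not as instrument detection limits.
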