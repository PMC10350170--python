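# Methods

`alloatlas` re-implements, as a tested library, a spatially resolved
single-cell analysis workflow for multiplexed tissue imaging of liver
allografts: semi-supervised phenotyping of segmented cells, spatial
interaction and neighborhood-motif statistics, trajectory orientation,
normality-gated group testing, and bootstrap-stabilized L1-regularized
predictive modeling. This note records the models, their assumptions, the
parameters that matter, and the choices made where the design was open.

## Input model

The pipeline starts at the segmented-cell level: one row per cell with ROI,
patient and clinical-group identifiers (NR = no rejection, TCMR = T-cell
mediated rejection, CR = chronic rejection), centroid coordinates in µm
(ROI-local frame, origin top-left, y downward — the image convention of
segmentation masks), and mean intensity per marker of a 22-marker panel
(two nuclear intercalators; collagen, CD31 and CK7 as structural markers;
CD45/CD3/CD4/CD8/CD20/CD68/CD11b/CD138/CD15 lineage markers;
CD163/HLADR/CD16/PD1/FoxP3/Ki67/GranzymeB/CD28 functional markers). Each
patient belongs to exactly one clinical group; ROIs of one patient are
treated as i.i.d. draws (within-patient spatial heterogeneity between ROIs
is not modeled).

## Phenotyping

Raw intensities are variance-stabilized as `asinh(x / c)` with cofactor
c = 5, the standard cytometry transform for right-skewed non-negative
signal, then z-scored per channel with the sample SD (ddof = 1; the
`{1,2,3} -> {-1,0,1}` convention). Constant channels standardize to zeros
with a warning instead of aborting, so dropped markers and degenerate
synthetic channels pass through.

Gating is a declarative ordered rule list evaluated on the standardized
scale, first match wins — the deterministic analogue of manual hierarchical
gating. The default positivity threshold is z >= 0.5 for "+"/"high" and
z < 0.5 for "−"/"low"; every rule can carry its own threshold in the rules
file (one rule per line: level, parent, target, `;`-joined terms such as
`CD3>=0.5`, plus an `immune` flag on metacluster rules). The default liver
ruleset defines 10 metaclusters — hepatocytes (the fallback, assigned by
exclusion of every other lineage), cholangiocytes, endothelial cells, and
seven immune lineages — and refines the five most informative immune
compartments into 30 subclusters (CD4 T-cells: 9, CD8 T-cells: 5,
macrophages: 9, monocytes: 4, B cells: 3). Macrophages split into M1/M2 on
a CD163 branch conjunct before functional refinement; resident-memory CD4
T-cells are the CD3-low fraction of the compartment, gated with a second
CD3 threshold at z = 1.5. The three non-immune metaclusters each carry
Ki67+/HLADR+ variants, for 41 final labels (32 immune + 9 non-immune);
label accounting counts "subclusters" only under the immune subclustered
parents, matching the way the cohort study tallies its clusters.

Per-patient proportions pool a patient's cells across ROIs (the simplest
reading of patient-level composition), either over the total cell count or
over the parent metacluster's count; patients with zero parent cells yield
missing, not zero, values.

## Spatial statistics

A directed k-nearest-neighbor graph (k = 10, Euclidean distance on
centroids) is built per ROI, histoCAT-style; distance ties break on cell
id, so graphs are reproducible even with duplicated coordinates. Cells in
ROIs with fewer than two cells are skipped with a warning.

**Interaction test.** For an ordered label pair (A, B) within one clinical
group, the statistic is the across-ROI mean of the mean number of B-labeled
out-neighbors per A-labeled cell. The null shuffles labels independently
within each ROI (stratified permutation; label counts per ROI are
invariant) and recomputes the across-ROI statistic; with the finite-sample
+1 correction, `p_attraction = (1 + #{null >= obs}) / (1 + n_perm)` and
symmetrically for avoidance, so p is never exactly 0. Defaults follow the
study: 1,000 permutations, two one-sided calls at alpha = 0.01, no
multiple-testing correction across pairs (a Holm flag is available on the
group-testing engine). The counts of null draws at or above and at or
below the observed value sum to at least n_perm, so attraction and
avoidance can never both be called. On ROIs small enough (<= 8 cells in the
tests) the null can instead be enumerated exhaustively over all distinct
labelings (`exact=True`), which the test suite checks against an
independent brute-force oracle. Network export assigns each significant
pair a strength `|obs − null mean| / null sd` (0 for a degenerate null).

**Cellular neighborhoods.** Each cell's profile is the fraction of its
out-neighbors carrying each final label — fractions, not counts, so
boundary cells with degree < k stay comparable. Profiles are k-means
clustered (k-means++ init, 10 restarts, fixed seed) into 9 neighborhoods by
default; centroids are reported for annotation and empty clusters are
flagged. Recovery of planted blocks degrades near block seams, where
neighbor profiles mix; at the study's cell density (~4,800 cells per 1 mm²
ROI) planted blocks separated by total-variation distance >= 0.5 are
recovered with adjusted Rand index >= 0.9.

**Distance profiles.** Per-cell Euclidean distance to the nearest
reference-type cell (endothelial cells by default) in the same ROI, with
per-label medians; ROIs lacking the reference contribute missing values.

## Trajectory orientation and pseudotime

Per immune compartment, cells are embedded in 2-D (principal components:
deterministic and sufficient for ordering; any embedding can be
substituted), coarse-clustered with k-means (k = 2, except k = 5 for the
CD8 compartment), and the coarse cluster with the highest fraction of NR
cells becomes the root — non-rejecting tissue is taken to carry the least
differentiated state; ties break to the lowest cluster id and an absence of
NR cells is an error. Instead of iterative simultaneous principal curves,
lineages are the root-to-leaf paths of the minimum spanning tree over
coarse-cluster centroids, and pseudotime is the arc-length of a cell's
orthogonal projection onto the piecewise-linear path of its nearest
lineage (root at 0). This deliberately simpler construction preserves the
scientific content — branching order and orientation — but not the smoothed
curves of principal-curve methods; with a single coarse cluster, pseudotime
degenerates to distance from the centroid along the first principal axis.
Per-group pseudotime densities are normalized histograms; groups with fewer
than 5 cells are flagged.

## Group testing

Per feature, Shapiro-Wilk at 0.05 on every group gates the family:
parametric (one-way ANOVA overall, two-sample t pairwise) only if no group
rejects; groups with fewer than 3 values default the feature to
nonparametric (Kruskal-Wallis overall, Wilcoxon rank-sum pairwise; exact
enumeration for small tie-free samples, mid-ranks with the normal
approximation otherwise; all-tied data returns p = 1). Holm's step-down
adjustment is applied within each feature's pairwise family (3 pairs for 3
groups) — the reading most consistent with per-panel correction — and
significance is read at 0.05. Adjusting across features instead is a
one-line change on the tidy output.

## Predictive modeling

On per-patient proportion features that were significant in the pairwise
contrast of interest, the binary outcome is modeled with L1-penalized
logistic regression. The model is penalized binomial deviance — the
likelihood matching a binary outcome — although shrinkage-based selection
is sometimes written with a squared-error loss; features are standardized
inside each training set and the intercept is unpenalized. The solver is a
warm-started glmnet-style coordinate-descent path (IRLS outer loop,
soft-thresholded cyclic inner loop, numba-compiled), run over 100
log-spaced penalties from the analytic lambda_max down to lambda_max·1e-4,
with an early exit once the fit saturates; it is validated against an
independent L1 solver in the test suite.

The penalty is chosen by 5-fold stratified cross-validated deviance. Two
rules are provided: deviance-minimizing ("min", ties toward the larger
penalty) and the parsimony "1se" rule (largest penalty within one standard
error of the minimum). Prediction steps default to "min"; bootstrap
stability selection defaults to "1se", because deviance-minimizing
penalties admit dense models on null data and would let noise features
clear the frequency threshold.

Stability selection resamples patients with replacement 5,000 times
(resamples with fewer than two patients of a class are redrawn so the
iteration count stays exact), refits with an internally cross-validated
penalty, and scores each feature by the fraction of iterations with a
non-zero coefficient; features at >= 50% enter the final model. Evaluation
uses 1,000 random stratified 75/25 train/validation splits; each split
refits the selected-feature model and records sensitivity, specificity and
accuracy at probability cut-off 0.5 (the simplest documented choice) plus
AUC via the Mann-Whitney identity (ties count 1/2). The report carries
metric means ± SD, averaged coefficients, each patient's median validation
prediction, the ROC over those medians, and the Spearman correlation
between median prediction and outcome with a companion two-sided rank-sum
p.

## Synthetic cohorts

The generator produces segmented-cell tables (never pixels) with known
ground truth, emulating the cohort's structure: 3 clinical groups with
24/41/14 patients by default, ~1.2 ROIs/patient, 1 mm² ROIs with Poisson
cell counts around 4,800, and the 41 default labels with group-dependent
composition (TCMR enriches PD1+ CD4/CD8 T-cells, HLADR+ Treg,
proliferating CD8 T-cells, HLADR+ M2 macrophages and proliferating
hepatocytes while depleting resident-memory CD4 T-cells and CD16+ M2
macrophages; CR shifts toward activated CD4 pools and HLADR+ parenchymal
variants without the PD1+ expansion). Expression is log-normal per
(type, marker) — negatives impossible by construction, mimicking the
right-skew that motivates the arcsinh transform — with per-label templates
derived from the gating rules (required markers high at a raw median of
~40 counts, everything else ~0.8, CD3 three-leveled inside the T-cell
compartments) so that gating accuracy on the defaults measures the gating
engine, not template tuning. Spatially, background types follow a
homogeneous uniform scatter; types named in an attraction pair are placed
as Neyman-Scott offspring (Gaussian children, sd = 50/strength µm, around
shared uniform parents of mean size ~15), the simplest point process with
tunable cross-type aggregation; motif blocks carve vertical bands with
their own composition to plant higher-order neighborhood structure. An
optional per-patient multiplicative intensity factor (off by default)
emulates batch variation. A separate patient-level generator produces
feature matrices with informative features at a chosen standardized effect
size, and a gradient generator produces cells along a 1-D latent
differentiation axis (expression linear in the latent with Gaussian noise,
NR concentrated at low values) for trajectory validation.

What the generator does *not* emulate: segmentation errors and spillover,
marker correlation structure within a cell type, irregular tissue geometry
(blocks are bands, clusters are isotropic), or per-ROI staining drift
beyond the optional patient factor. Passing tests therefore demonstrate
the correctness and calibration of the statistics on data with the assumed
structure, not robustness to those real-data artifacts.

## Determinism and problem sizes

A single master seed drives everything through `SeedSequence` spawn keys
(per group/patient/ROI streams, per-stage streams in the pipeline), so
reruns are bit-identical and insensitive to generation order; all derived
integer seeds stay below 2^31. The test suite and the acceptance script run
at reduced but statistically adequate sizes chosen for a single-CPU
workstation: 200 permutations for calibration/power runs (50 planted
cohorts), 200 bootstrap and 200 evaluation iterations, cohorts of 6-40
patients per group and 400-4,800 cells per ROI; the library defaults remain
the study values (1,000 permutations, 5,000 bootstrap iterations, 1,000
splits).

## Known limitations

* The gating thresholds of the original study's rule table are not public;
  the default z >= 0.5 convention is a documented stand-in and real
  analyses should supply their own rules file.
* The MST-pseudotime simplification cannot reproduce principal-curve
  geometry in strongly curved embeddings, and PCA may fold manifolds that
  a nonlinear embedding would unroll.
* The interaction test reports per-pair calls without cross-pair
  correction by default, faithfully to the original alpha = 0.01 design.
* CN recovery is limited by profile mixing at block boundaries (see above).
* Exhaustive enumeration of the interaction null is capped at 5·10^5
  labelings and is only meant for tiny ROIs.
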