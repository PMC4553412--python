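# Methods

This note documents the models, defaults and design choices behind
tremornet, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic validation does and does not
establish.

## Temporal preprocessing

ROI time series are processed in a fixed order: discard the first
`n_discard` volumes (default 5, so 180 acquired volumes leave 175),
optional zero-phase Butterworth band-pass (order 4, applied
forward–backward so filter lag cannot distort correlations), then
least-squares removal of an intercept, a linear trend, and any supplied
nuisance regressors. Rank-deficient confound sets are reduced to a
full-rank subset with a warning.

One tension is worth spelling out: the conventional resting-state
band-pass (0.01–0.1 Hz) excludes most of wavelet scale 1 (0.125–0.250 Hz
at TR = 2 s) and the upper half of scale 2. Because the filter acts
identically on every node, it does not bias inter-node correlations that
are spatially planted (as in the synthetic cohort), but on real data a
scale-1 analysis under the default band-pass would correlate mostly
stop-band residue. The band-pass is therefore a config flag
(`apply_bandpass`, default on, matching common practice); scale-1
results with the filter enabled should be interpreted with caution.

## Wavelet functional networks

The MODWT is implemented as the standard pyramid with filters rescaled
by 1/√2, giving a non-decimated, shift-equivariant transform that is
exactly energy preserving under periodic boundary handling (a reflection
mode — symmetric extension to twice the length — is available when
wrap-around artefacts matter more than exact energy bookkeeping).
Scale j isolates [1/2^(j+1), 1/2^j] cycles per sample.

Defaults: `sym4`, the 8-tap least-asymmetric Daubechies filter that is
the de-facto standard in wavelet fMRI work (PyWavelets' `symN` counts
vanishing moments, so `sym4` is the 8-tap filter); J = 4 levels;
periodic boundaries; boundary-affected coefficients retained. A level is
refused when the equivalent filter support (2^J − 1)(L − 1) + 1 exceeds
the series length; with 175 timepoints and the 8-tap filter, J = 4 is
exactly the deepest admissible level.

Functional edges are Pearson correlations of same-scale detail
coefficients. Zero-variance nodes yield NaN rows/columns that
thresholding treats as never-selected.

## Morphological networks

Each node is represented by a cube of gray-matter values (default
3×3×3 voxels) centered on its centroid; the edge weight is the maximum
Pearson correlation over the cube isometry group. Defaults follow the
seed-cube lineage: 48 orientations (24 proper rotations plus
reflections; a 24-rotation mode exists). The maximum over a closed
group is symmetric in its arguments; both orientation directions are
evaluated so the symmetry is bit-exact under floating point.

Two deliberate readings of an under-specified method: (1) nodes are
centroid cubes, not whole-ROI voxel sets — the minimal construction that
maps a cube-similarity measure onto a parcellation atlas; (2) per-subject
binarization uses the shared sparsity grid rather than an ad-hoc
individual threshold, so functional and morphological networks are
compared on identical footing. Negative similarities are zeroed before
thresholding (only positive gray-matter covariance is read as
connectivity). Flat cubes (zero variance, detected exactly via
peak-to-peak) are excluded and reported; more than 50 % excluded nodes
aborts as a degenerate input. Note that the maximum over 48 correlated
orientations is positively biased: independent 3×3×3 cubes score ≈ 0.3
on average, which is why raw similarity levels should only ever be
compared within a fixed orientation policy.

## Graph metrics

Matrices are binarized by keeping the round(s·N(N−1)/2) largest weights
at each sparsity s in 0.02–0.40 (step 0.02); ties break deterministically
by (weight desc, row asc, col asc). Efficiencies follow the standard
inverse-shortest-path definitions; disconnected pairs contribute 0, and
a neighbor subgraph with fewer than two members has efficiency 0 (the
degenerate case the formulas leave open). Shortest paths are breadth-
first searches over bitset adjacency rows (64 nodes per machine word),
which makes the per-node neighbor-subgraph sweep of local efficiency
tractable at 264 nodes across the whole grid; a scipy.sparse.csgraph
path covers environments without numba. Curves are summarized by
trapezoidal AUC.

Null models are Maslov–Sneppen trial swaps (10 per edge) via igraph,
preserving the degree sequence exactly; rigid graphs (e.g., complete
graphs) return unchanged with a warning. Normalization divides observed
global/local efficiency by null-ensemble means (default 100 nulls;
validation runs use smaller ensembles on a sparsity sub-grid, see
below). Small-worldness is normalized E_loc > 1 with
|normalized E_glob − 1| ≤ tol; "approximately 1" is quantified as
tol = 0.1 since the verbal definition leaves it open. Group-level flags
use the median subject's mean normalized efficiencies over the
null-evaluated sparsities.

## Statistical inference

Group tests are Freedman–Lane permutation tests: the metric is regressed
on the covariates (intercept + age + gender), residuals are permuted,
re-attached to the covariate fit, and the group-coefficient t statistic
(via Frisch–Waugh partialling) recomputed; two-tailed p uses the add-one
estimator, making 1/(n_perm+1) the floor and p = 0 impossible. Nodal
maps apply the expected-false-positives rule p < 1/N. Partial
correlation residualizes both variables on the covariates and refers
r to a t distribution with n − k − 2 df; a variable fully explained by
the covariates gets r = 0 by convention.

## Classification

Features are AUC nodal local efficiencies. Screening (two-group
label-permutation t test, p < 0.01 uncorrected) and MLDA fitting happen
*inside* each leave-one-out fold — the unbiased ordering; the
screen-once variant, which inflates accuracy, is available behind
`select_in_fold=False` for comparison. MLDA floors the pooled
within-class covariance eigenvalues at their mean (λ* = max(λ, λ̄)),
which keeps the discriminant defined when features outnumber subjects
and reduces to classical LDA for spherical covariance. Equal class
priors are used despite the 16/20 imbalance (the threshold sits at the
midpoint of projected class means); empty screenings fall back to the
single best feature with a warning. Significance is the z score of the
observed accuracy against the accuracy distribution from repeating the
whole cross-validated procedure under label permutations (default 100).

## Regression

Clinical scores (tremor, UPDRS, duration — modeled separately) are
regressed on Pearson-screened (p < 0.01) nodal efficiencies by OLS with
intercept; predictor counts are capped at n − 2 (keeping the
smallest-p columns) and collinear sets reduced to full rank, both with
warnings. Cross-modal linkage regresses a subject-level functional
efficiency summary on morphological nodal efficiencies and vice versa.
Screening and fitting deliberately reuse the same sample — that is the
procedure being modeled — so `selection_optimism_null` reports the R²
distribution the identical procedure produces on pure noise at the same
n; any headline R² should be read against it rather than at face value.

## Synthetic cohort

The generator emulates the study design: 16 patients vs 20 controls,
264 nodes in 8 modules, 180 timepoints at TR = 2 s (175 analyzed).
Time series are zero-mean Gaussian noise colored by the symmetric square
root of a block correlation matrix — intra-module r = 0.35, inter-module
r = 0.08, values chosen so that thresholded networks are modular and
robustly small-world across the sparsity grid while leaving sampling
noise visible at 175 timepoints. An optional AR(1) knob adds temporal
autocorrelation; by default the noise is white, so every wavelet scale
inherits the full planted spatial correlation (which is what makes the
scale-resolved pipeline checkable against a single planted matrix).

The group difference is one knob: patients' intra-module coupling is
reduced by `topology_gap` (default 0.12), which lowers their local
efficiency — the direction of the motivating clinical finding. Nothing
else differs between groups by construction; the accompanying small
global-efficiency increase in patients emerges from the same knob
(weaker modularity shortens between-module paths at fixed edge count)
rather than being separately planted.

Gray-matter cubes are module archetypes plus node jitter (sd 0.10) and
subject noise (sd 0.25), clipped at zero; a configurable fraction of
nodes (default 0.01 %, the reported real-data rate — which rounds to
zero flagged nodes at N = 264) gets flat cubes to exercise the
exclusion rule.

Clinical scores are exact linear functions of *measured* AUC nodal local
efficiency on five planted nodes with mixed-sign weights
(40, −30, 35, −25, 30), plus Gaussian noise whose sd defaults to half
the signal sd (population R² = 0.8); UPDRS and duration are fixed
multiples of the same construction. Because the scores depend on
measured efficiency, the pipeline fills the clinical columns after the
metrics stage; a standalone cohort dump leaves them NaN. Age and gender
are drawn independently of group.

What passing these validations shows — and does not. The synthetic
cohort has no hemodynamics, head motion, spatial autocorrelation,
registration error, or realistic gray-matter geometry; recovery of
planted effects demonstrates that the *statistical machinery* is
correct and calibrated (type-I error ≈ 5 %, screening ≈ 1 % under the
null), not that real acquisitions carry effects of this size or purity.

## Validation problem sizes

The package's own validation runs (test suite and acceptance script)
use the full cohort design and full sparsity grid but reduced
stochastic ensembles — 8 degree-preserving nulls at every 4th sparsity,
1000 group permutations, 300 in-fold screening permutations, 100
classifier label permutations — chosen as the smallest ensembles at
which the planted effects and calibration rates are stable across
seeds. `RunConfig` defaults remain the headline settings (100 nulls at
every sparsity, 10,000 permutations).

## Known limitations

- Scale-1 functional networks under the default band-pass measure
  mostly filtered noise on real data (see above).
- The morphological centroid-cube reading is one of several plausible
  mappings of cube similarity onto an atlas; results depend on it.
- Permutation p values are add-one estimates; with reduced permutation
  counts the p floor is correspondingly coarser.
- The cross-modal and clinical R² values inherit screen-then-fit
  optimism by design; the null-cohort distribution is the corrective,
  not a removal of the bias.
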