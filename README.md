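# tremornet

Graph-theoretic analysis of **wavelet-based functional** and **gray-matter
morphological** brain networks for two-group resting-state cohorts — the kind
of study that asks whether a patient group (e.g., tremor-dominant
parkinsonism) differs from matched controls in the efficiency of its brain
network organization, whether that difference classifies individual patients,
and whether it tracks clinical severity.

The package is aimed at methods-minded neuroimaging researchers who want the
full analysis chain as tested, seedable, scriptable code, together with a
synthetic-cohort generator that plants known effects so every stage can be
validated against ground truth.

## What it computes

**Networks.** For each subject, ROI time series (after discarding initial
volumes, optional 0.01–0.1 Hz band-pass, detrending and nuisance regression)
are decomposed with the maximal-overlap discrete wavelet transform (MODWT,
least-asymmetric 8-tap filter); the functional edge between ROIs *i* and *j*
at scale *j* is the Pearson correlation of their scale-*j* detail
coefficients. At TR = 2 s the four scales isolate 0.125–0.250, 0.063–0.125,
0.031–0.063 and 0.016–0.031 Hz. The morphological edge between two ROIs is
the maximum Pearson correlation between their gray-matter seed cubes over the
48 cube isometries (negative similarities are zeroed; zero-variance regions
are excluded).

**Topology.** Each weighted matrix is binarized over the sparsity grid
0.02 ≤ s ≤ 0.40 (step 0.02). For a binary graph *G* with *N* nodes:

- global efficiency  E_glob(G) = (1/(N(N−1))) Σ_{i≠j} 1/d_ij
- local efficiency   E_loc(G)  = (1/N) Σ_i E_glob(G_i),  G_i the neighbor subgraph of i
- nodal efficiency   e_i       = (1/(N−1)) Σ_{j≠i} 1/d_ij

with d_ij the unweighted shortest-path length (disconnected pairs contribute
0). Curves are summarized by their trapezoidal AUC over the grid and
normalized against degree-preserving (Maslov–Sneppen) random networks;
small-worldness means normalized E_loc > 1 with normalized E_glob ≈ 1.

**Inference.** Group differences use covariate-adjusted (Freedman–Lane)
permutation tests (default 10,000 permutations) with the false-positive
correction p < 1/N for nodal maps; clinical association uses partial
correlation. Classification uses permutation-screened (p < 0.01) nodal
efficiencies fed to maximum-uncertainty LDA (pooled-covariance eigenvalues
floored at their mean) under leave-one-out cross-validation, with a z score
against 100 label-permutation nulls. Clinical description uses
Pearson-screened (p < 0.01) least-squares multiple regression, plus a
null-cohort R² distribution quantifying the optimism of screen-then-fit at
small n.

## Worked example

```python
import tremornet as tn

cfg = tn.RunConfig.reduced(seed=11, cohort=tn.CohortConfig(clinical_noise_sd=0.0))
res = tn.run_pipeline(cfg)

print(res.small_world[res.small_world.modality == "functional"])
gs = res.global_stats
print(gs[(gs.scale == 2)][["metric", "diff_a_minus_b", "p", "direction"]])
c = res.classifier
print(f"LOOCV accuracy {c.accuracy:.2f}, z = {c.z_score:.2f}")
```

prints (seed 11):

```
     modality  scale group  normalized_e_glob  normalized_e_loc  small_world
0  functional    2.0     A           0.969094          2.004273         True
1  functional    2.0     B           0.920823          2.688995         True
       metric  diff_a_minus_b         p  direction
   auc_e_glob        0.003735  0.000999          1
    auc_e_loc       -0.019808  0.000999         -1
LOOCV accuracy 1.00, z = 3.18
```

Reading: both groups' scale-2 functional networks are small-world (normalized
local efficiency ≈ 2 with normalized global efficiency ≈ 1); the planted
reduction of patients' intra-module coupling is detected as a local-efficiency
deficit (negative direction, permutation p ≈ 0.001) alongside a small global-
efficiency increase; and nodal local-efficiency patterns separate the groups
far above the label-permutation null.

A shell entry point wraps the same pipeline:

```bash
tremornet all --seed 11 --out runs/demo     # full run + markdown report
tremornet report runs/demo                  # regenerate the report
```

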