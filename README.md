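# hpca — multiresolution hierarchical PCA for functional connectivity

Brain activity measured with resting-state fMRI is organised as a *nested*
hierarchy: large processing systems (Visual, Somatomotor, Default Mode, …)
contain progressively smaller, more specialised subnetworks and regions.
Single-scale decompositions such as spatial ICA recover only one level of
this hierarchy at a time.  `hpca` implements a multiresolution alternative —
the **treelet transform** (hierarchical PCA) — together with the group-level
machinery needed to apply it to multi-subject voxel×time data, a parametric
filter that isolates the informative levels of the hierarchy, and a
simulator that generates fMRI-like datasets with known nested network
structure for validation.

It is aimed at methods researchers in neuroimaging who want a working,
tested reference pipeline for hierarchical functional-connectivity
decomposition, and at anyone who needs a controllable generator of
hierarchically structured multi-subject time-series data.

## The method

**Simulation.** Each subject's noise-free data follow the linear mixing
model `Z_nf = S D R`, where the columns of `S` are spatial maps of the
network components, `D` is a diagonal matrix of per-subject amplitudes
(`~ N(1, 0.3)`), and the rows of `R` are component time courses —
Bernoulli(0.2) neural event trains convolved with a double-gamma HRF,
normalised to zero mean and unit peak-to-peak range.  Magnitude (Rician)
scanner noise `sqrt(e1² + e2²)`, `e1, e2 ~ N(0, σ_n²)`, is added with
`σ_n = σ_s / CNR` and a per-subject contrast-to-noise ratio
`CNR ~ U(0.65, 2)`.  Group spatial maps form a nested block hierarchy
(depth `L`, branching `D`, equal or Dirichlet-distributed block sizes).

**Compression.** Two-stage PCA with temporal concatenation: per subject
`Y_i = Z_i F_i` (C components), then the concatenated `Y = [Y_1 … Y_M]` is
reduced to `X = Y G` (K components).  Subject-level time series of any
group-level component `h` are recovered via `h_i = h (G⁺)_i F_iᵀ`.

**Treelets.** Starting from the V voxel score vectors, the algorithm
repeatedly merges the pair of active variables with the highest signed
correlation using a local 2-variable PCA, keeping the "sum" variable for
subsequent levels.  V−1 merges yield a dendrogram plus, at every level, the
eigenvalue pair `(λ1, λ2) = (1+|r|, 1−|r|)` of the local correlation
matrix.

**Level filtering.**  Two one-sided tests per level, Bonferroni-corrected
at family-wise α = 0.001 over 2(V−1) tests:

* *Smallest Eigenvalue Test* (redundancy): reject `H0: λ2 ≥ γ` when
  `λ2 < γ − z_α λ2 √(2/(K−1))`, with `γ = 0.4`.  The maximal contiguous
  prefix of rejections defines the **base level**, whose active variables
  summarise all finer (noise-dominated) structure.
* *Correlation t-test* (unrelatedness): `√(K−2) r / √(1−r²) > t_{K−2}(α)`
  excludes levels that merge unrelated branches (e.g. the forced final
  merges of a forest-like hierarchy).

Levels above the base that pass both tests are back-reconstructed per
subject as time series and seed-correlation z-maps, optionally after
**tree-independent orthogonalization** — regressing each level's series on
every base-level basis series that is not its dendrogram descendant.

## Worked example

```python
from hpca import HierarchicalPCA, HierarchySpec, simulate_experiment

spec = HierarchySpec(n_levels=3, branching=2, n_voxels=256, seed=0)
sources, subjects = simulate_experiment(spec, n_subjects=12, n_timepoints=300, seed=0)
res = HierarchicalPCA(subjects, subject_pcs=150, group_pcs=180).fit()
print(res.summary())
```

```
Hierarchical PCA (treelets) results
========================================================
variables (voxels)        256
tree levels               255
observations K            180
subjects M                12
subject PCs C             150
gamma (SET cutoff)        0.4
alpha FWE / per test      0.001 / 1.96e-06
--------------------------------------------------------
base level (SET prefix)   248
active variables at base  8
significant levels        1
unrelated levels          6  (top: [253, 254, 255])
--------------------------------------------------------
last merges (level, r, lambda2, flag):
     253  r=-0.035  lambda2=0.965  unrelated
     254  r=-0.040  lambda2=0.960  unrelated
     255  r=-0.943  lambda2=0.057  unrelated
```

The redundancy test flags levels 1–248 as noise-level merges of voxels
inside the same block, leaving 8 active variables — exactly the 2³ = 8
deepest true blocks of the simulated hierarchy.  The top levels merge the
two top-level branches, which share no sources: their merge similarity is
near zero (and strongly negative for the forced final merge of the two
anti-balanced halves), so the correlation test excludes them.  Subject-level
maps and series for any level come from
`res.reconstruct_level(level)`; `res.level_table()` returns the tidy
per-level statistics, and `res.plot_dendrogram()` draws the hierarchy.

A command-line interface mirrors the pipeline
(`hpca simulate`, `hpca run --preset 5L2D`, `hpca filter`,
`hpca evaluate`); presets `5L2D`, `3L3D` and `3L3Ddirich` are the standard
1024-voxel, 100-subject, 300-timepoint designs.

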