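# Methods

This note records the model, the statistical procedures, the design
decisions taken where the construction was genuinely open, and what the
synthetic benchmark does and does not establish.

## Generative model of the simulator

A simulated experiment is defined by a recursive partition of `V` voxels:
the full index range is split into `D` blocks, each block split again, for
`L` levels.  One latent component is attached to every block at every
level, so there are `sum_{l=1..L} D^l` components and a voxel at full depth
loads on exactly `L` of them (one per ancestor level).  Block sizes are
either integer-even splits or, in Dirichlet mode, drawn per branch from
`Dirichlet(alpha)` with largest-remainder rounding and resampling of any
branch that would produce a block below `min_block = 2` voxels.

Per subject `i`, noise-free data are `Z_i^nf = S_i D_i R_i`:

* `S_i` — group spatial maps plus i.i.d. `N(0, 0.005^2)` voxel noise.
* `D_i` — diagonal amplitudes `~ N(1, 0.3)`, drawn per subject and
  component (component heterogeneity).
* `R_i` — per-component event trains `~ Bernoulli(0.2)` per TR, convolved
  with a double-gamma HRF (peak 6 s, undershoot 16 s, ratio 1/6, sampled at
  the TR), normalised to zero mean and unit peak-to-peak range.  Time
  courses are regenerated for every subject: group structure is spatial,
  dynamics are individual.  An all-zero event train (probability
  `0.8^N`, negligible at N=300 but possible at toy sizes) is resampled
  once and then raises an explicit error rather than dividing by zero.

Scanner noise is Rician: `Z = Z^nf + sqrt(e1^2 + e2^2)` with
`e1, e2 ~ N(0, sigma_n^2)` i.i.d. per voxel and time point.  The noise
scale is set per subject: `sigma_s` is the temporal SD of the noise-free
data averaged over voxels (a single per-subject scalar; a per-voxel
alternative would couple noise level to block size, which we deliberately
avoid), `CNR ~ U(0.65, 2)` and `sigma_n = sigma_s / CNR`.

### Group spatial maps: unit-energy, zero-mean block contrasts

Each component's map is the indicator of its block scaled to unit L2 norm
(`1/sqrt(B)` inside a block of `B` voxels), then centred to zero spatial
mean and renormalised.  Two consequences drive the whole downstream
benchmark, and both are deliberate:

1. **Per-voxel amplitude grows as blocks shrink.**  Every component
   carries the same total energy, so small (specialised) networks are the
   strongest per voxel — the group correlation matrix shows its strongest
   blocks at the finest scale, decreasing with block size, as in real
   functional connectivity.  Quantitatively, two sibling deepest blocks in
   the five-level binary design then correlate at `r ~ 0.48` (four shared
   ancestors of increasing dilution vs one private component), safely on
   the "distinct" side of the redundancy-test boundary (`r ~ 0.71` at
   gamma = 0.4, K = 300), while voxels inside one block correlate at
   `r > 0.95`, safely on the "redundant" side.  A flat weight-1
   construction instead makes sibling blocks share 4/5 of their variance
   (`r = 0.8`), which lands *inside* the rejection region and merges the
   two finest scales — the filter could then never stop at the
   deepest-level basis.
2. **Zero-mean maps make the top of the hierarchy a contrast.**  The
   top-level branches are anti-balanced (one branch's positive support is
   the others' negative tail), so the final forced merges of the hierarchy
   have strongly negative similarity (about −0.95 binary, −0.5 then −0.9
   ternary) and are cleanly excluded by the one-sided correlation test,
   and the sum variable of such a merge is a near-degenerate residual
   whose forced seed maps are weak.

On the same grounds the map-noise parameter `0.005` is interpreted as a
standard deviation.  Read as a variance, per-voxel map noise (0.005 × ~40–60
components) would exceed the shared signal variance of a voxel (~0.01–0.06
under unit-energy maps) and erase within-block redundancy altogether; the
SD reading leaves within-block correlations at ~0.97, which is what a
"small amount of added noise" on a subject's map should do.

## Compression and back-projection

Subject stage: rows (voxels) centred over time, thin LAPACK SVD, top
`C` right singular vectors kept (`Y_i = Z_i F_i`); deterministic, no
randomised solver, and every basis column's sign is fixed so its
largest-magnitude loading is positive (bit-reproducible runs).  Group
stage: identical contract applied to the concatenation `Y = [Y_1 … Y_M]`,
keeping `K` components (`X = Y G`).  Defaults `C = 295`, `K = 300` for
300-timepoint data; `K` is a free knob.  Requesting more components than
`min(rows, cols)` raises a rank error; exactly-zero trailing singular
directions (one is always induced by centering) are kept deterministically
and carry zero scores, so lossless round trips remain exact.

Back-projection of a group-level score vector `h` into subject `i` is
`h_i = h (G^+)_i F_i^T`, where `(G^+)_i` is the subject-`i` block of the
generalized inverse of the *full* group basis.  Because `G` has
orthonormal columns this block is simply `G_i^T`.  The distinction
matters: pseudo-inverting the isolated `C x K` subject block instead
inverts the small singular values of one subject's share of the shared
basis and returns noise (best-match accuracy against ground-truth series
drops from ~0.6–0.85 to chance, ~0.1, at 25 subjects).  The two coincide
only in the single-subject lossless case.

## Treelet construction

Variables are the rows of `X`, standardised.  At each level the active
pair with maximal signed Pearson correlation is merged (ties break to the
lexicographically smallest id pair); the local PCA operates on the
correlation scale, so the eigenvalue pair is `(1+|r|, 1−|r|)` and lives on
a fixed [0, 2] scale on which the `gamma = 0.4` cutoff is meaningful.  The
continuing "sum" variable is the normalised positive combination
`(x~_i + x~_j)/sqrt(2(1+r))`, re-standardised before re-entering the
active set; the "difference" variable is the complementary combination.
For every positively correlated merge — i.e. every merge the
max-similarity rule actually selects — the sum *is* the leading principal
component.  We prefer the sum convention over "always the leading
eigenvector" because the leading eigenvector flips discontinuously at
`r = 0` (and at `r < 0` would silently turn a merge into a contrast),
whereas the sum is continuous in `r` and becomes degenerate exactly when
the merged pair is perfectly anti-correlated — which the implementation
records and excludes from further merging rather than propagating a
zero-variance variable.  The similarity matrix is maintained
incrementally (only the new variable's row/column is recomputed), which an
oracle test verifies against full recomputation.

## Level filtering

Both tests use `K` (the compressed, concatenated time dimension) as the
sample size, and a per-test level `alpha = alpha_FWE / (2 (V−1))`
(Bonferroni over two tests at each of `V−1` levels; 0.001 family-wise maps
to 4.9e-7 per test at V = 1024).

* SET: `H0: lambda2 >= gamma` rejected when
  `lambda2 < gamma − z_alpha · lambda2 · sqrt(2/(K−1))` — the classical
  first-order asymptotic for an eigenvalue estimate with
  `Var(lambda_hat) ≈ 2 lambda^2/(K−1)`.  `lambda2 = 0` maps to p = 0;
  p-values below 1e-300 are floored at 0 and flagged.
* Correlation test: upper-tail t with `K−2` df on
  `sqrt(K−2) r / sqrt(1−r^2)`; `r = ±1` map to p = 0/1.

The **base level** is the end of the maximal contiguous prefix of SET
rejections; isolated rejections further up are reported (flag
`redundant_isolated`) but do not move the base.  *Significant* levels are
those above the base that are SET-accepted and correlation-significant;
the rest are *unrelated*.  With `gamma = 0.4` the boundary sits at
`lambda2 ≈ 0.286` (`r ≈ 0.714`) for K = 300 — comfortably between the
within-block (~0.97) and between-block (~0.3–0.5) correlation regimes of
the simulated designs.

## Back-reconstruction and orthogonalization

A level's subject time series is its (optionally orthogonalized) sum
variable pushed through the compression inverses; its subject map is the
Pearson correlation of that series with every *raw* voxel time series
(correlating against compressed series would be cheaper but conflates the
map with the compression), z-scored across voxels with the population SD;
the group map is the mean of subject maps, excluding (with a warning) any
subject whose reconstructed series is constant.

Tree-independent orthogonalization regresses the level's compressed score
vector on every base-level basis variable whose leaf set is disjoint from
the level's subtree, by ordinary least squares; an empty independent set
(the root) leaves the series unchanged.  Orthogonalization sharpens
spatial contrasts between sibling branches but strips the shared ancestor
variance that true *time courses* contain, so the accuracy benchmark uses
orthogonalized series for maps-oriented questions and raw series for
time-series accuracy; both are always available.

## Accuracy benchmark and the ICA baseline

For every ground-truth component, per subject and per domain (spatial /
temporal), the estimate with the highest absolute correlation is its
best match; matching is deliberately not injective, so a method that only
captures one scale shows up as one estimate serving many true components
(a multimodal accuracy distribution).  The hPCA estimate set is the
base-level basis plus the significant levels.  The baseline is
single-scale spatial FastICA at the true model order, run on its *own*
two-stage reduction whose group stage keeps exactly as many components as
the ICA model order — the configuration a practitioner would use —
with multi-restart centrotype stabilisation (the run with the best mean
matched agreement with all other runs is kept).  Methods are compared by
paired t-tests over (subject, component) pairs.

Under the simulated designs the baseline recovers the deepest level with
near-perfect spatial accuracy (|r| > 0.9) and degrades sharply for every
coarser scale, while the treelet pipeline reconstructs all scales at
usable accuracy and tracks true time courses slightly better on average;
the temporal margin is small (~0.01 in mean |r| at 25 subjects) because
both methods' reconstructed series are block aggregates that inherit
ancestor variance.

## Problem sizes and numerical choices

The full study conditions are 1024 voxels, 100 subjects, 300 timepoints,
TR 2 s; the acceptance script runs them as such (about a minute per design
on one CPU).  The test suite fits the same designs once per session at 25
subjects (equal-block designs) and 50 subjects (Dirichlet).  The Dirichlet
design needs the larger group because the scanner-noise fraction that
survives compression scales as `K/(C·M)` and its largest deepest blocks
(up to ~500 voxels, with per-voxel signal an order of magnitude weaker
than in small blocks) sit closest to the redundancy boundary: at M=25 a
single marginal voxel merge inside a 161-voxel block (r = 0.706 vs
boundary 0.714) can end the prefix early, while at M≥50 the behaviour
matches the 100-subject design.

Other numerical conventions: correlations are clipped to [−1, 1] before
eigenvalue formulas; degenerate (zero-variance) inputs raise named errors
rather than NaNs; dendrogram export heights are `1 − r` (monotonised for
plotting); all randomness flows through `numpy.random.Generator` seeds and
per-subject child generators, making every run replayable bit-for-bit from
its configuration.

## What the synthetic benchmark does not show

The simulator emulates the hierarchical block structure, BOLD-like
autocorrelated dynamics, subject amplitude/CNR heterogeneity and Rician
magnitude noise — not spatial smoothness, head motion, physiological
confounds, slice timing, or spatially varying noise.  Passing tests
establish that the pipeline recovers *this* family of nested-block
hierarchies; real fMRI hierarchies are less cleanly nested, their
components overlap gradually rather than block-wise, and the
unit-energy/zero-mean map convention is an idealisation of how network
strength scales with network size.  Real-data use enters through
`load_nifti_masked` (4-D NIfTI plus gray-matter mask, x-fastest voxel
order, exact re-embedding of result maps), with preprocessing assumed done
upstream.
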