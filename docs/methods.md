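# Methods

This note documents the modelling choices, conventions and limitations of
the morphnet pipeline in the order the method runs.

## Network construction

**Sampling.** Each region's raw material is the set of GM volume values of
its voxels (at least 2 per region, positive spread required). The package
consumes either NIfTI map/atlas pairs or per-region TSV samples.

**Density estimation.** Gaussian-kernel KDE with Scott's rule
`h = σ̂ · n^(−1/5)`, where `σ̂` is the ddof-1 sample standard deviation.
The bandwidth is stored in every `PDFEstimate` for auditability. Scott's
rule is the stated selector; diffusion-based bandwidths (Botev) are a
common alternative in this literature but are deliberately not implemented
— one selector, recorded in outputs, keeps results comparable.

**Evaluation grid.** The two PDFs of a pair are evaluated on a *shared*
grid of 256 equally spaced points spanning the union of both samples'
ranges padded by 3 bandwidths on each side. Per-pair shared grids (rather
than one global grid, or per-region grids) guarantee the divergence is
well-defined without extrapolation; the discretisation-stability test
(doubling to 512 points moves no entry by more than 1e-3) shows 256 points
suffice on smooth data.

**Similarity.** `KLS = exp(−D_sym)` with
`D_sym = KL(p‖q) + KL(q‖p)` computed by discrete summation after flooring
both discretised densities at 1e-10 and renormalising to unit sum. The
flooring keeps `D_sym` finite and deterministic when supports barely
overlap; because the sum-renormalisation absorbs any scalar factor, the
trapezoid normalisation of the PDF estimates cancels exactly, which is why
the batch network builder and the per-pair operations agree to machine
precision. The exponential form is the standard map satisfying the stated
contract: range [0, 1], 1 iff the distributions coincide, symmetric.

**Diagonal.** Stored as 1 but excluded from thresholding, features and
graph metrics; self-similarity carries no information.

## Graph metrics

**Thresholding.** At sparsity `S`, exactly `⌊S·R(R−1)/2⌋` strongest edges
are retained with their weights. Ties (measure-zero on real-valued KLS)
break by ascending (i, j) lexicographic order so results are reproducible.
The grid endpoints 0.10 and 0.34 are treated as inclusive (25 thresholds
at step 0.01): the strict inequalities in the source description are read
as typographical, which matches the standard practice of an inclusive grid
with the stated interval; both endpoints are configurable.

**Conventions.** All metrics use edge distance `d = 1/w`:

* `Cp`: mean Onnela weighted clustering, weights rescaled by the graph
  maximum; nodes of degree < 2 contribute 0.
* `Eglob`: mean of `1/d_ij` over distinct pairs; unreachable pairs
  contribute 0, so disconnected graphs are handled without special cases.
* `Lp = 1/Eglob` (harmonic-mean path length) — finite under
  disconnection, exact (`Lp = 1`) on complete unit-weight graphs.
* `Eloc`: mean over nodes of the global efficiency of the neighbour-induced
  weighted subgraph.
* Nodal degree is the binary incident-edge count by default (summed weight
  available via `degree_mode="weight"`); nodal efficiency is the mean
  inverse distance to all other nodes; betweenness is unnormalised Freeman
  betweenness on the same distances.

These weighted variants are not uniquely pinned down by toolbox-based
descriptions in the literature; each is fixed here, property-tested against
independent brute-force oracles on small graphs, and switchable where a
defensible alternative exists.

**Null networks.** γ, λ, σ are normalised against 100 degree-preserving
rewired graphs per threshold (Maslov–Sneppen double-edge swaps, 10·|E|
attempted swaps, implemented through igraph's C rewiring with a locally
seeded RNG), with the original weight multiset randomly reassigned to the
rewired edges. 100 nulls is the common toolbox default; it bounds the
Monte-Carlo error of the null means to a few percent.

**AUC.** Trapezoidal integration over the grid — exact on linear curves,
and equal to 0.24·c for a constant c on the default grid.

## Group statistics

Permutation tests reallocate subjects between groups 10,000 times; the
p-value uses the +1-corrected estimator and is two-tailed by default
(configurable): observed differences go in both directions across metrics,
and the two-tailed test is the conservative symmetric choice even though
the original description reads one-tailed. Nodal measures are corrected
per-measure by Benjamini–Hochberg FDR. Quantiles in the outlier screen use
linear interpolation (type 7), and the `±3·IQR` fences drop only strictly
outside values. Partial correlation residualises both variables on
`[1, covariates]` by least squares; the t-based two-tailed p-value uses
`n − 2 − k` degrees of freedom. The clinical-correlation helper applies
the IQR screen jointly to the metric AUC and the clinical variable before
correlating, mirroring the reported exclusion procedure.

## Network-based statistic

Edgewise pooled-variance t statistics on the node subset that was
FDR-significant in at least one nodal measure; edges with `|t| ≥ 2.9`
(two-tailed by default, configurable) are kept and maximal connected
components extracted. Component size is the *edge count* (the conventional
extent statistic; node counts are reported alongside). Significance comes
from the permutation distribution of the maximum component size, which
controls the family-wise error over components. Edgewise tests are
unadjusted for covariates (the original procedure does not state any
adjustment); the observed FWER calibration on exchangeable synthetic data
is part of the acceptance suite.

## Classification

Features are the row-major upper-triangle KLS entries (R(R−1)/2 values;
the redundant lower triangle and constant diagonal are dropped — the
vectorisation is information-preserving and invertible). Inside each outer
training fold: per-feature z-standardisation (statistics from training
rows only), inner stratified k-fold grid search over
`C ∈ {1e-3 … 1e4}` by balanced accuracy, refit on the full outer-training
set, prediction on the held-out fold. Classes are inverse-frequency
weighted because the target design is imbalanced (115 vs 87). Reported
balanced accuracy, sensitivity and specificity are means over outer folds;
significance reruns the entire nested procedure on permuted labels.
Region ranking sums each region's incident mean-|weight| edge scores
(a degree-style projection; per-region mean is available), and the top 20
are reported.

## Synthetic cohorts

The generator emulates the statistical features the method depends on, not
MRI physics:

* **Spatial structure.** Region base means follow a smooth two-frequency
  gradient over homologous region pairs (amplitudes 0.05 and 0.025 around
  a 0.5 mean level) plus independent per-region offsets (sd 0.03). Nearby
  and homologous regions therefore have similar PDFs, the analogue of the
  spatial autocorrelation and bilateral symmetry of VBM maps.
* **Shared background.** Every region's distribution is a mixture: 40%
  region-specific Gaussian (scale drawn once per cohort from U(0.08,
  0.14)) and 60% a common N(0.5, 0.15) background, reflecting that all GM
  regions share the global GM intensity distribution. The background both
  keeps similarities off the degenerate extremes and supplies the
  long-range "shortcut" edges real morphological networks show; without
  it, thresholded graphs are too lattice-like (λ ≈ 1.4 instead of the
  realistic ≈ 1.1).
* **Subject variability.** Per-subject, per-region mean jitter (sd 0.035)
  and region sample sizes drawn uniformly from 200–800 voxels, matching
  the wide size range of AAL regions.
* **Planted effects.** Group B shifts the entire value distribution of
  each effect node by `effect_size · σ_r · m_k`, with cyclic multipliers
  `m_k` of varying sign and magnitude, so that edges *within* the effect
  set carry group differences too (equal shifts would cancel pairwise).
  A multiplicative scale effect is optionally available. Expected
  downstream |t| on effect-incident edges is monotone in the effect size
  (tested).
* **Covariates.** Age ≈ 23 ± 8, education ≈ 12 ± 3, M:F ≈ 4:1, onset
  ≈ 13 ± 3 with duration = age − onset, drawn independently of group.

What passing tests on these cohorts show: the pipeline's machinery —
similarity construction, metric conventions, calibration of every
permutation procedure, effect recovery and classification — behaves
correctly under a generative model with realistic similarity structure.
What they do not show: that real GM maps satisfy the Gaussian-mixture
assumption (real within-region distributions are only approximately
unimodal), nor anything about preprocessing choices upstream of the
regional samples.

## Numerical choices and degenerate inputs

Density floor 1e-10 before logarithms; matrices symmetric to 1e-9
(revalidated on file read at 1e-8 after 10-significant-digit TSV
round-trip); σ = γ/λ by construction to 1e-9; zero-variance samples,
regions with < 2 voxels, empty thresholded graphs, rank-deficient
covariates and constant pooled permutation data all raise typed errors (or
a degeneracy warning where the contract specifies a defined result, e.g.
p = 1 for constant pooled values, t = 0 with a flag for zero-variance
edges). One global seed expands into per-stage seeds via
`SeedSequence(seed, stage_index)`; every stochastic routine takes an
explicit seed and is bit-reproducible.

## Problem sizes in the shipped checks

The test suite runs cohorts of 3–80 subjects with 8–90 regions, 1,000
replicate null datasets for permutation calibration, a 40+40 cohort with
1,000 NBS permutations for recovery, and a 20-subject end-to-end
determinism run; the acceptance script uses a 20-subject, 90-region cohort
with the full 25-threshold grid and 100 nulls per graph. These sizes were
chosen so each check isolates one property at the smallest scale that
makes the property visible.

## Known limitations

* The KLS depends on the discretisation and flooring conventions; other
  implementations may differ in the third decimal for near-disjoint
  supports.
* The weighted-metric conventions (Onnela Cp, harmonic Lp) are one
  defensible choice among several; comparisons across toolboxes should fix
  the conventions first.
* Classifier permutation significance reruns the full nested CV per
  permutation and is therefore expensive at the default 1,000
  permutations; the pipeline exposes `run_svm_permutation` to switch it
  on where the budget allows.
* The generator plants location (optionally scale) effects only; it does
  not model covariate–network coupling, site effects, or non-Gaussian
  within-region structure.
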