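# Methods

## Genotype model and standardization

The pipeline operates on an n × L matrix C of reference-allele counts
c_il ∈ {0, 1, 2} with an explicit missing mask. Standardization is the
smartpca convention: estimate p̂_l as the mean of non-missing genotypes at
locus l divided by 2, then set non-missing entries to
(c_il − 2p̂_l) / sqrt(2 p̂_l (1 − p̂_l)). Missing entries become zero (the
column mean), and monomorphic columns (p̂ ∈ {0, 1}, where the denominator is
undefined) are zeroed wholly. Because every standardized column sums to
zero, the all-ones vector is in the null space of Yᵀ and Y Yᵀ has rank at
most n − 1; exactly n − 1 components are therefore retained.

The denominator uses 2p̂(1 − p̂) — the binomial variance of a diploid count.
A per-locus-constant rescaling (e.g. dropping the factor 2) would change
all columns by the same factor and leave PC subspaces, variance proportions
and every downstream statistic unchanged; the choice is a display
convention, not a modeling one. Allele frequencies are plain means; no
bias-adjusted estimator is applied.

## PCA conventions

PCA eigendecomposes the n × n matrix Y Yᵀ (no further centering — the mean
removal is inside the standardization). Scores are eigenvalue-scaled,
score_k = sqrt(λ_k) · u_k, so the variance of score column k is exactly
λ_k / n and the relative spread of PC1 vs PC2 is visible in the map. This
is deliberately *not* the equal-variance eigenvector convention; the two
differ by per-axis rescaling, which changes Procrustes similarity scores.
Variance explained is λ_k / Σ_{j≤n−1} λ_j. Eigenvalues below zero by more
than 1e-8·λ₁ raise an error; smaller negatives (round-off) are clipped to
zero. PC signs are unconstrained — the Procrustes step absorbs reflections —
and exact eigenvalue ties make the ordering of the tied pair
solver-dependent, so tests avoid constructing ties.

## Quality control

Two ordered steps, matching standard practice for merged SNP panels:

1. **Missing-data filter.** Individuals with *strictly more* than 5% missing
   genotypes (over the loci of the current matrix) are removed; exactly 5%
   is retained. The threshold is configurable (`max_missing`).
2. **Iterative PC-outlier removal.** Standardize → PCA → flag any individual
   whose score on at least one of the top min(10, n−1) PCs lies more than
   10 sample SDs from that PC's mean → remove flagged → repeat until a pass
   flags nobody. The SD is the plain sample SD of the current pass's
   scores, recomputed each pass (no robust estimator). The flag decision is
   invariant to per-PC linear scaling, so applying it to eigenvalue-scaled
   scores or raw eigenvectors is equivalent.

A structural note: the z-score of a single point among n is bounded by
(n − 1)/√n, so a 10-SD rule can only ever fire for n ≳ 102. This matters
for test design (plants use n = 200) and for users with small samples, who
should lower `sd_threshold`. Removal is pure row deletion; retained
genotypes are never altered, and running the two-step QC twice is
idempotent.

## Geographic coordinates

Southern latitudes and western longitudes are negative. Regional analyses
use unprojected (longitude, latitude) as an isotropic plane (1° of latitude
counted equal to 1° of longitude), which distorts at high latitudes — an
accepted simplification for subcontinental maps. Worldwide analyses first
shift longitudes below a threshold (default −40°) east by +360°, so the
Americas plot beyond Eurasia rather than wrapping across the Atlantic, then
apply the Gall–Peters equal-area projection with standard parallel 45°
(x = R·λ·cos45°, y = R·sinφ/cos45°, R = 1). Both the threshold and the
parallel are configurable; R is irrelevant because the Procrustes statistic
is invariant to global rescaling of either map.

## Procrustes superposition and t0

The geographic configuration X is fixed; the PC1–PC2 configuration Y is
transformed. Over translation, positive scale, rotation, and optionally
reflection, the minimized sum of squared distances, scaled by the centered
target dispersion tr(X_cᵀX_c), gives D ∈ [0, 1] and t0 = sqrt(1 − D). The
closed form: with A = Y_cᵀX_c = UΣVᵀ, the optimal orthogonal map is
Q = UVᵀ and t0 = (σ₁ + σ₂)/sqrt(tr(X_cᵀX_c)·tr(Y_cᵀY_c)). When reflection
is disallowed and det(UVᵀ) < 0, the best proper rotation negates the
smaller singular value: Q = U·diag(1, −1)·Vᵀ and t0 uses σ₁ − σ₂.
Reflection is allowed by default; the restricted family is a flag.

The rotation angle is reported in degrees counterclockwise, in (−180, 180]
with the ±180 tie resolved to +180. When the optimal map is improper it is
factored as (reflection across the first axis) ∘ (rotation) and the angle
of the rotation factor is reported, with the `reflection_used` flag set —
the angle alone does not describe an improper map. Only the first two PCs
enter the fit; higher-dimensional Procrustes is out of scope. Degenerate
inputs (fewer than 3 points, or zero dispersion in either configuration,
e.g. all individuals from one population) raise errors.

## Permutation test

Each permutation reassigns the multiset of population locations to
populations uniformly at random, all individuals of a population moving
together; t0 is recomputed with the same settings (including reflection
allowance). PCA is not recomputed — the genetic map is fixed under the
null. p̂ = M/N with M the count of t0^π ≥ t0 (a 1e-12 tolerance guards the
degenerate equality case); M = 0 is displayed as "< 1/N" rather than with a
pseudocount, matching the convention of reporting p < 10⁻⁵ at N = 100,000.
Permutations are drawn independently (collisions allowed) since in real use
N is far below the number of distinct assignments; an exhaustive mode
enumerates all K! assignments for K ≤ 8 populations, where M/N is exact.
Note the sampled M/N estimator is mildly anti-conservative compared to
(M+1)/(N+1); its type-I error at the 0.05 level is (⌊0.05·N⌋+1)/(N+1) under
a continuous null, which the acceptance checks measure empirically.

## Leave-one-out and marker curves

Leave-one-out drops one population at a time from the post-QC matrix,
reruns standardization and PCA (the outlier search is *not* repeated), and
reports t0′ (new map vs geography) and t_PCA (new map vs the original
PC1–PC2 coordinates on the shared individuals, aligned by individual ID).
Both are ordinary two-configuration Procrustes similarities. Marker curves
subsample loci uniformly without replacement; the selection depends only on
(seed, L_sub), so datasets sharing locus IDs analyze identical marker sets
and their curves are comparable.

## Weir–Cockerham FST

Per locus, population sample sizes n_i (non-missing individuals), allele
frequencies p_i and observed heterozygote frequencies h_i (genotypic — no
Hardy–Weinberg assumption) yield the three 1984 variance components a
(among populations), b (among individuals within populations) and c
(within individuals), via n̄, n_c, p̄, s², h̄. The multi-locus estimate is
the ratio of sums θ = Σa / Σ(a+b+c), never a mean of per-locus ratios (the
two demonstrably differ). Loci that are monomorphic overall, observed in
fewer than two populations, or with n̄ ≤ 1 are dropped from both sums and
counted in `loci_used`. Negative θ (possible when true differentiation is
~0) is reported as computed, not clipped.

## Synthetic data generator

`simulate_lattice_dataset` emulates isolation by distance: populations at
known planar coordinates; per locus an ancestral frequency drawn uniformly
(default 0.1–0.9); population logit-frequency deviations drawn from a
zero-mean Gaussian process with covariance σ²·exp(−d/ρ) over planar
distance d in degrees; genotypes Binomial(2, p); optional uniform
missingness and planted outlier individuals (frequencies mixed toward an
independent uniform vector). Frequencies are clipped to [0.001, 0.999];
monomorphic columns can still arise by sampling and are handled by the
standardization. Defaults (σ = 1.0, ρ = 30°, 10 individuals/population,
10° grid spacing) give strong structure — FST near 8–9% with PC maps that
visibly reconstruct the grid; σ ≈ 0.1 gives weak, Europe-like
differentiation (θ of a few per mil), and σ = 0 gives an exchangeable null.
The logit-Gaussian construction was chosen over stepping-stone or
coalescent simulation because the pipeline needs only the statistical
signature of isolation by distance (distance-decaying frequency
correlation) with explicit covariance control, not demographic realism: no
linkage disequilibrium, admixture events, or mutation model. Passing tests
on these data therefore demonstrate correctness of the statistical
machinery, not robustness to LD pruning, platform merging, or relatedness —
features real merged SNP panels have and this generator does not emulate.

`simulate_balding_nichols` draws population frequencies from
Beta(p(1−F)/F, (1−p)(1−F)/F), giving Var = F·p(1−p): known-truth substrate
for FST recovery and for the two-population limit in which PC1's variance
share approaches FST.

## Problem sizes and numerical choices

Validation runs use deliberately modest sizes chosen to leave the
statistics unambiguous: QC plants at n = 200, L = 1500–4000 (comfortably
above the (n−1)/√n ≈ 14 z-score ceiling); structure recovery on a 4×4
lattice with n = 160, L = 2000 and N = 999 permutations; FST recovery at
r = 10, n = 30, L = 5000 (sampling SE of θ well under 0.005); marker curves
up to L = 20,000; permutation calibration over 500 null datasets at
N = 199. The two-stage QC cascade uses shifts of 0.45 and 0.22: the first
plant dominates PC1 and inflates its SD enough to mask the second
(z ≈ 7 < 10) until the first is removed (then z ≈ 12 > 10).

Other numerical conventions: exceedance and equality comparisons use
absolute tolerances of 1e-9–1e-12 as noted above; the Gaussian-process
Cholesky adds a 1e-10 jitter; eigen-solver sign indeterminacy is accepted
everywhere (tests compare up to sign, Procrustes absorbs it).

## Known limitations

- Only PC1–PC2 enter the similarity score; structure on deeper PCs is
  invisible to t0.
- The permutation null fixes the PC map, so it tests the arrangement of
  locations, not re-estimation uncertainty in PCA.
- Unprojected regional coordinates distort east–west distances at high
  latitude.
- The 10-SD outlier rule is ineffective below n ≈ 102 (see above).
- The VCF reader handles diploid biallelic GT fields only; triallelic
  records are an error rather than being silently dropped.
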