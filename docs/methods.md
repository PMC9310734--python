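# Methods

This note records the models, numerical choices and limitations behind
`landpop`, in the spirit of the methods documentation of estimator-heavy
scientific packages.

## Genotype-likelihood inference

All genetic estimators operate on the three genotype likelihoods
GL(g), g ∈ {0,1,2} copies of the derived (or minor) allele, per individual
and biallelic site, stored in beagle-normalized space (maximum of the
three values is 1; three equal values mean missing data). Log space is
used internally where products over individuals occur.

**Allele-frequency likelihoods.** For a site with N diploids the
likelihood of a total derived count d is a sum over genotype
configurations weighted by the hypergeometric factor
C(2,g₁)…C(2,g_N)/C(2N,d), evaluated by convolution over individuals in
O(N²) per site (vectorized across sites). The normalization makes L(d) an
exact indicator for fully certain genotypes and exactly flat for an
all-missing site — two limits the tests assert.

**SFS EM.** The spectrum is the maximizer of Σ_s log Σ_d φ(d) L_s(d) by
EM (E-step: posterior class membership; M-step: mean posterior).
Defaults: tolerance 1e-8 on the maximum class-proportion change, 500
iterations. The log-likelihood trace is recorded and any decrease beyond
1e-9 raises an internal error rather than returning a corrupt result.
Folding sums classes d and 2N−d after estimation; θπ applies the weights
i(n−i) to folded classes unchanged, since i(n−i) = (n−i)i makes the
folded and unfolded sums identical. θπ is reported per variable site
(total divided by the number of sites in the spectrum); because the
synthetic data contain only variable sites, these values are on the order
of 0.1–0.5, not the genome-wide 10⁻³ scale seen when monomorphic sites
are included in the denominator.

**Inbreeding EM.** The genotype prior for individual i at site s is
(q²+Fpq, 2pq(1−F), p²+Fpq). The EM treats the autozygosity indicator z as
a latent variable: with probability F one allele is drawn and doubled,
otherwise Hardy–Weinberg. F_i updates as the mean posterior of z;
p_s updates from posterior allele counts in which autozygous genotypes
contribute one independent allele. This is a complete-data EM, so the
likelihood is provably non-decreasing (asserted at 1e-9 relative). Two
stages mirror common practice for this estimator: a short run (100
iterations, loose tolerance) from near-neutral starting values
(F = 0.01), then a deep run capped at 1,500 iterations. F = 0 is not used
as a start because it is a fixed point of the EM.

**FST.** Hudson/Bhatia ratio-of-sums over joint-SFS classes: numerator
(p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1), denominator
p₁(1−p₂) + p₂(1−p₁), with n the haplotype count. Hudson is the default
for its behaviour under unequal sample sizes; a Reynolds-style ANOVA
estimator is available by flag. Under the Balding–Nichols model the
estimator recovers the generating parameter (the numerator's expectation
is 2Fp(1−p) and the denominator's 2p(1−p)); the acceptance suite checks
±0.02 recovery at F ∈ {0.05, 0.1, 0.3} with 20+20 diploids and 50,000
sites. Negative matrix entries are clamped to 0 (raw values are returned
alongside) because downstream normalization x/(1−x) requires [0,1).

**Joint SFS EM.** The E-step factorizes: with per-population class
likelihood matrices A (sites × K₁) and B (sites × K₂) and prior Φ, the
accumulated posterior is Φ ∘ ((A/Z)ᵀB) with per-site normalizer
Z = diag(A Φ Bᵀ); each iteration is two matrix products, which keeps
50,000-site × 41×41-class problems at well under a second per iteration.

**Genetic distances** use the dosage kernel |g−h|/2 on genotype
posteriors (flat prior unless site frequencies are supplied); a 0/1
mismatch kernel is available by flag. The PCA covariance standardizes
expected dosages by 2p̂(1−p̂) and drops sites with p̂ outside (0.01, 0.99).

## Synthetic data

The generator defines the study conditions for every test:

- **Landscape**: 1/f^roughness spectral noise rescaled to [0, 4000] m
  (roughness 1.2 default; 0 gives a flat landscape). Temperature-like
  layers decrease with elevation at 6.5 °C/km plus small seeded noise;
  precipitation-like layers follow a spatial gradient. Past epochs
  (mid-Holocene, LGM) apply additive shifts (−1, −4 °C) to
  temperature-like and multiplicative factors (0.95, 0.75) to
  precipitation-like layers — monotone, recorded transformations rather
  than a climate model.
- **Localities**: 5–6 per run, one pair closer than 12 km, all other
  pairs beyond 20 km, with ~6–13 individuals scattered within 1 km of
  each centroid; the centroid is defined as the mean of member
  coordinates. Placement margins of 2.5× the scatter radius keep the
  individual jitter from flipping a pair across a distance threshold.
- **Genotypes**: Balding–Nichols population frequencies
  Beta(p(1−F)/F, (1−p)(1−F)/F) around ancestral p ~ U(0.05, 0.95)
  (F = 0 uses p directly), per-individual inbreeding via
  P(het) = 2pq(1−f), Poisson read depth (default mean 8, configurable;
  error rate 0.01), binomial read sampling, and exact binomial
  read-sampling likelihoods. Zero-depth entries carry three equal
  likelihoods rather than being dropped.
- **Spatial coupling**: for end-to-end runs, population frequencies come
  from a logit-scale Gaussian field over localities with covariance
  σ² exp(−d/λ) on the *terrain least-cost distance* d, so expected
  pairwise FST grows with accumulated terrain resistance by
  construction. σ = 1.2 and λ = half the median pairwise least-cost
  distance give pairwise FST in roughly the 0.05–0.3 band at the default
  sizes.

What the generator does **not** emulate: linkage disequilibrium (sites
are independent), coalescent genealogies and recombination, read-level
artefacts (mapping bias, base-quality miscalibration), and real climate
surfaces. Passing tests therefore demonstrate estimator correctness under
the stated generative models, not robustness to those real-data
complications.

## Niche model and resistance

The suitability model is an L1-penalized logistic presence/background
classifier on standardized linear and quadratic terms of the four
bioclimatic layers — the penalized-GLM formulation of maximum-entropy
modelling. Ten replicate 80/20 presence splits are fitted (iteration cap
500) and the suitability raster is the mean replicate probability; the
output is the classifier probability, chosen because downstream stages
only require a [0,1] suitability. Background points (default 10,000) come
from non-presence, non-nodata cells.

Evaluation: AUC as the Mann–Whitney rank statistic (ties count half), TSS
maximized over score thresholds, and a fixed 2×2 spatial-block fourfold
cross-validation (points on an internal boundary belong to the south/west
block). MESS uses strictly-below percentages with the standard piecewise
form; habitat stability is the cellwise mean suitability over the three
epochs.

Resistance surfaces: TRI is the Riley sum-of-squared-differences form
over the 8-neighbourhood (mean-absolute variant by flag); the tier scheme
assigns costs 1/2/4/8/16 by linear-interpolation empirical quantiles of
occurrence TRI with boundary ties resolving to the cheaper tier; masking
removes cells outside the 0.4°-buffered occurrence convex hull or outside
the occupied elevation band ±100 m (the lower bound is dropped for
stability surfaces, since glacial elevation zones shifted downward). The
±100 m reading of the elevation margin is one of two grammatically
possible interpretations; the alternative (a 100 m-above-sea-level floor)
is not implemented as default but the margin is a parameter.

The movement graph uses 8 queen plus 8 knight moves; edge weight is the
haversine length between cell centers (R = 6371 km) times the arithmetic
mean of the two cell resistances, floored at ε = 1e-6 so zero-cost
terrain yields positive weights. The arithmetic resistance mean is an
accumulated-cost integral and is the default; a harmonic
(conductance-averaging) variant is a flag, matching transition tools that
average conductance — the two differ on heterogeneous edges. Least-cost
distances are Dijkstra shortest paths (scipy csgraph) between locality
centroids snapped to the nearest passable cell within 2 cell diagonals.

## Matrix statistics

Mantel tests correlate lower triangles (Pearson r), permuting rows and
columns of one matrix jointly; the default tail is one-sided for positive
association (the standard isolation-by-distance direction), two-sided by
flag. Matrices can be standardized by their off-diagonal mean, which
leaves r unchanged. MMRR z-scores the unfolded vectors, solves OLS, and
permutes the response, recomputing t and F statistics; coefficients are
also reported back on the raw distance scale. All permutation p-values
use the (1 + exceedances)/(1 + permutations) convention and seeded
generators. Defaults: 10,000 permutations (Mantel, MMRR), 500 (GDM),
α = 0.05.

GDM: response dissimilarities in [0,1) (FST is used directly as the
response; normalized FST is reserved for Mantel/MMRR), link
μ = 1 − exp(−η), η = β₀ + Σ_k Σ_j β_kj I_j(d_k) with all β ≥ 0. The three
order-2 I-splines per predictor are suffix sums of degree-2 B-splines on
knots at the 0/50/100 percentiles of the observed distances. Fitting is
IRLS with a non-negative least-squares inner solve on the binomial
deviance, with step-halving if a step would increase deviance; percent
deviance explained is measured against the intercept-only null. Predictor
importance is the mean drop in deviance explained when that predictor's
matrix is row/column-permuted; backward elimination removes the least
contributing predictor until all retained predictors are significant or
one remains, recording the per-round table.

With 5–6 localities there are only 10–15 distance pairs, so GDM fits up
to 16 parameters on 10–15 observations; the non-negativity constraints
make this well-posed (most coefficients pin at zero), but permutation
p-values at this size are coarse — the same caveat applies to any
analysis at the typical sampling scale of landscape-genetic studies.

## Problem sizes

Test and demonstration sizes were chosen to exercise every code path at
desk scale: pipeline runs use 32×32–48×48 rasters, 5 localities × 6–10
diploids, 1,500–5,000 variable sites; estimator-recovery checks use
20–40 diploids and 20,000–50,000 sites, matching the order of magnitude
of variant counts in RADseq datasets. Permutation counts are reduced in
fast tests (199–999) and kept at full defaults (10,000/500) in the
pipeline configuration.

## Known limitations

- The beagle reader loads the full likelihood array into memory
  (~25 MB per 10⁵ sites × 10² individuals); no streaming mode.
- Unfolded analyses assume the ancestral allele is correctly assigned;
  the folded path avoids this but discards polarization information.
- The niche-model surrogate omits hinge/threshold/product features, so
  sharply thresholded niches are fitted by quadratic approximation.
- Rasters are WGS84 lon/lat grids only (Esri ASCII interchange);
  projected coordinate systems are out of scope.
- Negative FST clamping introduces a small upward bias in downstream
  matrices when true differentiation is ~0.
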