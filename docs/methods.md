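# Methods

`samplescape` evaluates how the choice of sampling scheme — individuals
versus populations versus "everyone you managed to catch" — changes
model selection in landscape genetics.  This note documents the models,
the numerical choices, and what the synthetic experiments do and do not
show.

## Sampling schemes

Three designs over a set of sampled sites:

* **ISS** (individual sampling scheme): draw *n* individuals per site
  without replacement, typically *n* = 1–11, with many bootstrap
  replicates per *n*.  Sites holding fewer than *n* individuals
  contribute everyone they have (mirroring the proportion-available
  logic; the alternative of dropping such sites would silently change
  the site set across replicates).
* **PSS** (population sampling scheme): every individual, but only at
  sites with at least `min_pop_size` individuals (default 11).  One
  deterministic realization.
* **PASS** (proportion-available sampling scheme): every individual at
  every site regardless of count.  One deterministic realization.

## Genetic distances

The response is the allele-sharing distance `1 − Dps`, where for two
diploid multilocus genotypes

    Dps = Σ_l Σ_a min(c1_la, c2_la) / (2 L_obs),

`c` being per-individual allele counts (0/1/2) and `L_obs` the number of
loci called in both individuals (pairwise deletion).  Bray–Curtis
dissimilarity on the concatenated allele-count vectors equals `1 − Dps`
algebraically whenever each co-called locus contributes two gene copies
per individual, i.e. always under pairwise deletion; the package asserts
this identity rather than treating the two as separate estimators.
Orientation: larger values mean more dissimilar genotypes, so positive
resistance coefficients mean impeded gene flow.  Flipping the
orientation changes only the sign of fixed effects, never the
information-criterion ranking.

Population-level matrices are means of the interindividual distances
over all cross-site pairs (single-individual sites are allowed; the mean
then runs over 1×n pairs).  Also provided: Nei's Da on allele-frequency
profiles and the Weir–Cockerham (1984) θ estimator for FST, computed as
the ratio of summed among-population variance components over summed
totals across loci and alleles.  Negative θ estimates are retained
as-is; truncating them would bias index correlations.

The whole-matrix allele-sharing computation uses an indicator-matrix
identity: with per-allele count indicators U1 = [c ≥ 1] and
U2 = [c ≥ 2], shared copies between all pairs are `U1·U1ᵀ + U2·U2ᵀ`,
turning the O(n²L) loop into two matrix products.

## Population summaries

Per population: unbiased expected heterozygosity
`uHe = (2n/(2n−1))(1 − Σp²)` averaged over loci; total and rarefied
allelic richness by hypergeometric rarefaction
`Σ_a [1 − C(N−N_a, g)/C(N, g)]` (the default rarefaction base g is twice
the smallest population's diploid sample size — with the default
threshold of 11 that is 22 gene copies); mean private alleles per locus;
monomorphic-locus counts.

Hardy–Weinberg equilibrium is tested by a Monte Carlo exact test: gene
copies are shuffled into diploid genotypes conditional on allele counts,
and the Levene conditional probability of the genotype array is the
statistic (small = extreme).  Linkage disequilibrium between locus pairs
uses the G statistic on the two-locus genotype table with one locus
permuted across individuals.  Both report the add-one estimator
`(1 + #extreme)/(n_perm + 1)`; monomorphic cases are "not testable" and
are excluded from the Bonferroni denominator, which therefore counts
only performed tests.  The LD test is a permutation approximation to
likelihood-based LD testing on unphased genotypes; it does not attempt
EM haplotype-frequency estimation.  Exact-test p-values are discrete:
with small samples or few permutations they are conservative
(stair-stepped), which the null-calibration tests account for by using
moderate sample sizes.

## Circuit-theory resistance

Each hypothesis is a single resistance raster: binary land cover
(resistance 2 inside the focal class, 1 elsewhere), a raw continuous
surface min-shifted to be strictly positive (no rescaling), or the
all-ones layer representing pure isolation by distance.  Raster cells
are graph nodes; neighbor conductance is `2/(r_a + r_b)` (average
resistance), scaled by 1/√2 for diagonal neighbors; connectivity
defaults to 8 (4 available for hand-solvable circuits).  Effective
resistance `R(s,t) = (e_s − e_t)ᵀ L⁺ (e_s − e_t)` is computed by
grounding one focal node, factorizing the reduced Laplacian once
(sparse LU), and solving one indicator system per remaining node, so a
40-site landscape costs one factorization plus 39 triangular solves.
Resistance is computed once on all sites; smaller analyses take
submatrices.  Effective resistance is a metric and obeys Rayleigh
monotonicity (raising any cell's resistance cannot lower any pairwise
value); both properties are property-tested.

Collinearity among candidate predictors is screened by iterative VIF on
the lower-triangle vectors (the quantities that actually enter the
models), dropping the worst predictor until all VIF < 4.  The screen is
advisory — it logs removals but does not silently delete candidate
models, since single-variable hypotheses remain interpretable even when
their predictors are mutually correlated.

## MLPE mixed models

Pairwise observations are not independent: two pairs sharing an
endpoint population are correlated.  The maximum-likelihood
population-effects model adds a random effect per endpoint:

    y_ij = x_ijᵀβ + u_i + u_j + e_ij,   u ~ N(0, σu²), e ~ N(0, σe²)

so V = σe²(I + φ ZZᵀ) with φ = σu²/σe² and Z the pair×site incidence
(two unit entries per row).  β is profiled out by GLS and σe² has a
closed form given φ, leaving a 1-D profile (restricted) likelihood in φ.
The eigendecomposition of ZZᵀ — fixed for a given site set — makes each
profile evaluation O(n·p); it is computed once and cached.  φ ≥ 0 is
found by bounded scalar search over log(φ + 1e-8) on three overlapping
brackets (φ up to ~10³) with an explicit check of the φ = 0 boundary.

Predictors are z-standardized before fitting (numerical stability;
IC ranking is unaffected).  Model size is counted as
k = 1 intercept + #slopes + 2 variance components, so a single-predictor
model has k = 4 and the four-predictor model k = 7.  Information
criteria use the number of pairwise rows as the effective sample size —
a debatable convention this class of analysis inherits (pairs are
positively correlated, so n_pairs overstates information); it is
documented and configurable rather than silently corrected.
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) and BIC = −2ℓ + k·ln n, with
Akaike-type weights exp(−Δ/2) normalized over the candidate set.  Both
ML and REML are exposed; comparing fixed-effect structures by IC is only
strictly valid under ML, and REML tables are produced for comparison
with the common field practice of using them anyway.  Ties in Δ within
1e-9 break by smaller k, then model name.

## Bootstrap experiment and convergence

For each per-site sample size n and replicate r (seed = base_seed + r),
an ISS dataset is drawn, the response rebuilt, every candidate fit, and
a model flagged "competitive" when ΔIC < 2.  Summaries report
competitive counts out of R replicates and mean IC weight ± SE.  A model
is "supported" when its mean weight strictly exceeds 0.1 or its count
reaches 30 of 100 (both thresholds configurable).  Convergence takes the
deterministic PSS (or PASS) top-model set as reference and reports, per
n, the fraction of replicates whose competitive set intersects the
reference (an exact top-model-match mode is also provided, since
"agreement" admits both readings); the convergence point is the smallest
n whose fraction strictly exceeds 0.9.

## Synthetic data generator

The generator emulates the structure of a pond-breeding amphibian
microsatellite study: a 60×60 classed landscape (cover fractions
forest_ld 0.30, shrub 0.20, ag 0.15, grass 0.10, rest background,
realized by quantile-cutting a smoothed Gaussian field, so fractions are
met exactly up to ties), an independent positive "slope" field, 40 sites
placed with minimum separation 5 cells, and per-site sample sizes
totalling 334 individuals of which 18 sites have ≥ 11 (five exactly 11).
Eight loci start with 10 equifrequent alleles.

Demography is a frequency-level stepping-stone Wright–Fisher process:
migration `m_ij = m0·exp(−R_ij/ρ)` (row-normalized with self-retention
kept ≥ 0.5) mixes deme allele frequencies deterministically, then
multinomial drift resamples 2Ne gene copies per deme per locus, for T
generations.  Defaults m0 = 0.02, ρ = 0.3×median effective resistance,
Ne = 50, T = 200 put pairwise Nm in the 0.1–1 range across the
resistance spectrum, giving equilibrium-scale FST around 0.1 and a clear
isolation-by-resistance gradient through the causal cover class
(low-density forest) — the strong-structure regime reported for this
kind of pond system.  Stepwise mutation is available (off by default; at
T = 200 generations mutation is negligible at microsatellite rates).
All randomness flows from one master seed through named substreams
(landscape, placement, genotypes), so every artifact replays
byte-identically.

What the generator does *not* emulate: overlapping generations and
stage structure, sibship clusters within ponds (the field protocol
removes siblings before analysis), genotyping error and allelic
dropout, null alleles, and temporal landscape change.  Passing the
end-to-end tests therefore shows that the pipeline recovers a known
causal surface from drift-migration structure of realistic magnitude —
not that any particular field inference is correct.

## Numerical choices and degenerate inputs

* Linear solves: sparse LU on the grounded Laplacian; dense
  pseudoinverse oracles use `hermitian=True` (the general SVD path is
  visibly less accurate on grid Laplacians).
* Half-missing genotype calls are rejected at validation; GenePop
  half-missing fields (e.g. `000120`) are read as wholly missing.
* A locus with no observed copies in a group yields an empty frequency
  vector, excluded from means.
* Constant responses fit with zero slopes and a σe² floor at the
  boundary; rank-deficient designs raise; non-converged fits are
  excluded from rankings and logged.
* Monomorphic loci are "not testable" for HWE/LD and excluded from the
  Bonferroni m.
* FST of two samples with no shared polymorphic locus is NaN and is
  dropped from index correlations.

## Scale of the shipped experiments

The test suite and the acceptance script run the full experiment at the
default study size (40 sites, 334 individuals, 8 loci) with 100
bootstrap replicates per sample size on a 60×60 landscape — a size
chosen so a complete run takes a couple of minutes on one core while
leaving every qualitative contrast (scheme differences, convergence in
n, ML/REML divergence) clearly resolvable.
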