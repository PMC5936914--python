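# Methods

This note documents the models implemented in `canidmacro`, their
assumptions, the defaults that matter, and what the synthetic-data
generator does and does not emulate.

## Trait-evolution models

All six models are Gaussian: tip values are multivariate normal with
mean and covariance determined by the shared path-length matrix `C`
(`C[i,j]` = root-to-MRCA distance; diagonal = root-to-tip times `T_i`)
and, for some models, the tip depths or the lineages-through-time
curve. Trees may be non-ultrametric: extinct tips simply have smaller
depths, and all formulas below are exact in that case.

| model | mean_i | cov_ij | parameters |
|-------|--------|--------|------------|
| BM    | z0 | σ²·C_ij | z0, σ² |
| OU    | z0 | σ²/(2α)·e^(−α(T_i+T_j−2C_ij))·(1−e^(−2α·C_ij)) | z0, σ², α ≥ 0 |
| ACDC  | z0 | σ²·(e^(r·C_ij)−1)/r | z0, σ², r |
| Trend | z0 | σ²·(C_ij + b·C_ij²/2) | z0, σ², b |
| Drift | z0 + μ·T_i | σ²·C_ij | z0, σ², μ |
| Div   | z0 | ∫₀^C_ij (σ₀² + ψ·n(t)) dt | z0, σ₀², ψ |

ACDC, Trend and Div are time-inhomogeneous Brownian models whose
instantaneous rate depends only on time since the root, so their
covariance is an elementwise monotone transform of `C`; Trend requires
1 + b·t ≥ 0 and Div requires σ₀² + ψ·n(t) ≥ 0 over the tree's span.
`n(t)` is the lineage count of the *reconstructed* tree being fitted
(internal nodes increment it, extinct tips decrement it at their tip
age): past diversity is only observable through the sampled tree. The
OU model uses the single-stationary-peak convention with the root fixed
at the optimum (mean ≡ z0 ≡ θ); on non-ultrametric trees the exact
exponential covariance is used, never a branch-stretch approximation.
Every model contains BM as a boundary case (α, r, b, μ, ψ → 0), which
the fitter exploits (below) and the tests assert.

### Fitting

For each model, the location parameters (z0; z0 and μ for Drift) and
the scale (σ² or σ₀²) are profiled analytically by GLS through a
Cholesky factorization, leaving at most **one** shape parameter. That
parameter is maximized by a coarse grid scan — which always includes the
BM boundary value 0, so `loglik(model) ≥ loglik(BM)` holds by
construction — followed by bounded Brent refinement between the best
grid point's neighbours. Shape bounds are scaled to the tree: α ∈
[0, 50/T], |r| ≤ 10/T, b ∈ (−1/T, 10/T], ψ/σ₀² ∈ (−1/n_max, 50/n_max],
with T the maximum tip depth. This profile-plus-1-D design replaces a
multi-start quasi-Newton search over three parameters: it is faster,
cannot converge to a local optimum in the profiled directions, and makes
the BM-nesting invariant exact rather than approximate.

Parameter counts for AICc are k = 2 for BM and k = 3 for the others
(location, scale, one shape/direction term);
AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) and Akaike weights are
w_i ∝ exp(−Δ_i/2). Over a posterior sample of trees, each tree is
pruned to the species shared with the trait (trees missing more than
half are skipped with a warning), per-tree weights are computed, and the
per-model **median weight across trees** is reported.

## Phylogenetic signal and PGLS

Pagel's λ scales the off-diagonal covariance: V(λ) = λC off-diagonal,
diagonal T_i. λ̂ maximizes the profiled likelihood over [0, 1] (grid +
bounded refinement); the p-value is a likelihood-ratio test against
λ = 0 on χ²(1). By default the boundary 50:50 mixture correction is not
applied (a flag enables it), mirroring common implementations.

Blomberg's K is the observed mean-square ratio of the GLS-centred trait
over its Brownian expectation:
K = [(x−â1)ᵀ(x−â1) / (x−â1)ᵀC⁻¹(x−â1)] ÷ [(tr C − n/1ᵀC⁻¹1)/(n−1)],
with significance from tip-label permutation,
p = (1 + #{K_perm ≥ K_obs})/(1 + n_perm); the default n_perm = 999 puts
the attainable floor at p = 0.001. The implementation agrees with R's
phytools to six decimals on shared inputs. Two calibration facts worth
knowing: the *mean* of K under BM is ≈ 1, but its distribution is
right-skewed, so the *median* on ~128-tip birth–death trees is ≈ 0.92
and rises toward 1 with tree size; and under directional change (Drift)
K typically exceeds 1.

**PGLS** uses the Pagel-λ transform of the phylogenetic *correlation*
matrix (unit diagonal, off-diagonals λ·C_ij/√(T_i·T_j)), exactly as R's
`nlme::gls` with a `corPagel` structure. This matters on
non-ultrametric trees: scaling the correlation matrix makes λ = 0
reduce *exactly* to ordinary least squares, whereas scaling the
covariance would leave depth-proportional residual variances (weighted
LS). The covariance-scale transform remains available for the signal-λ
estimator, where it is the conventional definition. λ is estimated by
profile ML when requested, or fixed at 1 (Brownian residuals) or 0
(OLS); the three modes are compared by AICc with k counting
coefficients + σ² (+ λ when estimated). Coefficient t-tests use the
unbiased residual variance with n − p − 1 degrees of freedom.

## Sampling-adjusted durations

Each species' occurrence ages are modelled as a homogeneous Poisson
process at rate q (occurrences/Myr) on its unknown lifespan (TE, TS):
per-species likelihood q^k·exp(−q(TS−TE)) with TS ≥ oldest and TE ≤
youngest occurrence age. Across species, lifespans follow a
constant-rate birth–death prior, logL = S·log λ_bd + E·log μ_bd −
(λ_bd+μ_bd)·Σ(TS_i−TE_i) for S species and E extinct species. Priors:
TS_i and TE_i uniform on windows extending the observed range by a
configurable pad (default 15 Myr, truncated at 0); q, λ_bd, μ_bd vague
Gamma(1.01, rate 0.01).

The sampler is Metropolis-within-Gibbs. Given the rates, the posterior
factorizes over species, so all TS_i (and all TE_i) are updated in one
vectorized sliding-window Metropolis step (proposal SD 0.5 Myr,
acceptance log-probability −(q+λ_bd+μ_bd)·Δduration). The three rates
have conjugate gamma full conditionals and are drawn by Gibbs:
q | · ~ Gamma(a+Σk_i, b+Σd_i), λ_bd | · ~ Gamma(a+S, b+Σd_i),
μ_bd | · ~ Gamma(a+E, b+Σd_i). Extant species have TE pinned at 0.
Occurrence interval dates enter as midpoints by default; an optional
mode treats the ages as latent, redrawing them uniformly within their
dating intervals each iteration subject to TE ≤ age ≤ TS (the HPP
likelihood depends on ages only through these order constraints).

Desk-scale default chain: 5×10⁵ iterations, 10% burn-in, thinning 100;
the classic long setting (10⁷ iterations, 2×10⁵ burn-in) is available
through the same settings object. Reported per species: FAD, LAD,
posterior medians of TS and TE, duration = median(TS) − median(TE)
(stored as a nonnegative Myr value), the posterior mean of q, and an
autocorrelation-based effective sample size for q. With one species, a
fixed q and the birth–death prior disabled, the posterior is a product
of truncated exponentials, which the tests integrate numerically as an
oracle; with simulated data the 95% credible intervals for TS cover the
truth at the nominal rate and the q posterior concentrates on the
generating value.

## Occupancy

Occurrences are assigned to half-degree cells by floor(coordinate/0.5)
(half-open cells, boundaries belong to the upper cell) and to time
slices by the midpoint of their dating interval (a slice covers
(young, old]; the oldest boundary and age 0 are included). Occupancy of
species s in slice t is |cells of s in t| / |cells of any included
species in t|, undefined when the denominator is empty; maximum locality
coverage is the maximum over slices, ties resolved toward the older
slice. The shipped 18-slice table subdividing the North American
land-mammal ages over 40–0 Ma is approximate and user-replaceable via
CSV. Species occurring at a single locality ("singletons") and extant
species are excluded before occupancy and duration estimation.

## Carnivory index

The three dietary ratios differ in spread by an order of magnitude, so
the PCA uses the correlation matrix: each ratio is standardized by its
extant-training mean and SD (ddof = 1, as in `prcomp(scale.=TRUE)`),
the correlation matrix is eigendecomposed, and the PC1 sign is fixed so
RBL loads positively (carnivory increases to the right; PC2
approximates durophagy). Diet-category labels are never used in the
fit. Fossils are projected through the extant standardization and
loadings; their PC1 scores are re-centred by subtracting the fossil
median (stored on the model so later projections remain comparable),
making the post-recentring median exactly 0. Species missing any ratio
are excluded from projection and reported. The PCA is deliberately
standard, not phylogenetic; the known artefact — traits evolved under
multivariate BM can masquerade as early/late bursts after standard PCA —
is a documented caveat of the design, not something this package
attempts to correct.

Mass regression coefficients are configuration with a documented,
non-normative default (a = −2.27, b = 2.97 on mm → kg log10 scales, in
the style of published canid m1 allometries). Dentary imputation is a
per-subfamily OLS fit of log10(dentary) on log10(m1) (allometric
convention; ≥ 3 complete training species per subfamily, no pooling),
and imputed values are flagged.

## Specialization and duration regressions

The carnivory axis is split at its median; species exactly at the
median go to the "less carnivorous" side (a deterministic tie rule).
Specialization is |carnivory − median| within each side. Configured
outlier species stay in the dataset but never enter a fit. Per side,
duration ~ specialization is fitted by OLS when the ML λ of the PGLS
fit is below a threshold (default 0.1) and by PGLS otherwise.

Quantile regression minimizes the pinball loss Σρ_τ(y−a−bx),
ρ_τ(u) = u(τ − 1{u<0}), solved exactly as a linear program (HiGHS), so
the fit attains an LP vertex — a line through two data points — which
the tests verify by brute-force enumeration. Standard errors are the
SD of the estimates over xy-pair bootstrap resamples (default 10,000;
configurable), with two-sided p-values from a normal reference on
t = estimate/SE and percentile intervals also reported.

The nested duration models are five OLS fits: each of mass, carnivory
and coverage alone (k = 2 mean parameters), mass × carnivory full
factorial (k = 4), and mass × carnivory × coverage full factorial
(k = 8). AICc counts mean parameters only, excluding the residual
variance — this convention reproduces the published AICc column of the
corresponding analysis from its log-likelihoods to ~0.1, whereas
counting the variance misses by > 2 — and the weights-from-AICc path is
treated as normative.

## Synthetic data

The generator defines the study conditions; its defaults are fixed, not
tuned. Trees come from a forward constant-rate birth–death simulation
started at the root split and conditioned on total tip count (extinct +
extant), default n = 60 with birth 0.25 and death 0.18 per lineage-Myr —
giving canid-like clades a few tens of Myr deep with a substantial
extinct fraction. The present falls at a random instant while the clade
has n tips; by memorylessness the elapsed time since the last event is a
full Exp(n·(b+d)) draw. Clade extinction before reaching n triggers a
retry (cap 1,000); exhausting retries signals infeasible rates. An
age-stopping mode exists for calibration against the closed-form
birth–death expectation E[N(t)] = 2e^((b−d)t). Species are tips under
the budding convention: TS is the age at which the terminal branch
began, TE the tip's age (0 if extant).

Traits are drawn from the exact MVN law of the requested model (same
code path as the likelihoods, Cholesky of the model covariance).
Fossil records use the same homogeneous-Poisson preservation the
estimator assumes (default q = 1.5/Myr), uniform occurrence ages on
[TE, TS], a per-species 2-D Gaussian geographic kernel (SD 1.5°) inside
a North-America-like extent, localities binned at 0.1°, and dating
intervals of ± half the enclosing time slice (land-mammal-age-style
binning; configurable). A `true_age_ma` column carries the synthetic
ground truth and is not part of the standard occurrence schema. The
extant morphoset places 45 species (12 hypo-, 15 meso-, 15
hypercarnivores, 3 hyaenid-like bone-crackers) at diet-category
centroids chosen so the hyaenid-like centroid has the highest RBL and
JD/DL and the lowest RUGA, plus Gaussian noise; raw characters are
reconstructed consistently with the ratios. A "posterior sample" of
trees is emulated by multiplying every edge of the base tree by
independent lognormal(0, 0.1) factors — same topology and tips,
perturbed divergence times.

What the generator does **not** emulate: spatially explicit dispersal
or climate-driven preservation, non-Poisson (e.g. hump-shaped)
preservation, taxonomic error, database duplication, or correlated
measurement error in morphometrics. Passing tests therefore show the
estimators are correct under their own assumptions and calibrated under
the stated generating processes — not that real occurrence databases
satisfy those assumptions.

## Problem sizes and numerical choices

The packaged end-to-end study uses 60 species, 50 posterior trees,
2×10⁵ MCMC iterations and 500 bootstrap replicates — sizes chosen so a
full run completes in about a minute on one CPU while every stage
remains statistically meaningful; all of them scale up by configuration.
Monte-Carlo calibration suites use 100–1,000 replicates as appropriate
to the quantity. Cholesky factorizations are used everywhere a dense
inverse would be tempting; singular model covariances (e.g.
zero-length cherries) raise an error naming the exchangeable duplicate
tips. Optimizer tolerances: 1e-10 (scaled) on the 1-D shape searches.
Summary tables report medians and R-style median absolute deviations
(scale constant 1.4826). A master seed spawns per-stage child seeds
(NumPy `SeedSequence`), and reruns of the pipeline with the same
configuration are byte-identical.

## Known limitations

- One global preservation rate q is shared across species by default
  (a per-species q is a flag, at an identifiability cost at desk scale);
  no rate-shift or time-varying preservation variants.
- The Div model's lineage count ignores unsampled diversity.
- λ̂ is constrained to [0, 1]; values slightly above 1 that some
  implementations allow are truncated.
- Quantile-regression bootstrap resamples with degenerate predictors are
  dropped (NaN) rather than re-drawn; at the default replicate counts
  this is negligible.
- The carnivory index inherits every caveat of standard PCA on
  phylogenetically structured data (see above).
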