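# Methods

This note records the statistical model, the conventions and defaults the
package commits to, and what the synthetic-data tests do and do not
establish.

## Outcome construction (ACSC classification)

A hospital discharge counts as an avoidable hospitalisation (AH) when its
ICD-10 *main diagnosis* matches the built-in catalogue of ambulatory-care-
sensitive conditions, each labelled acute or chronic. Pattern semantics are
prefix-based at the catalogue's own level of detail:

* a 3-character category (`J45`) covers all its subcodes;
* a dotted subcode (`I24.0`) covers itself and deeper extensions;
* a range (`E10.0–10.8`) expands over the single-decimal subcodes it names,
  inclusively — so `E10.9` is *not* an ACSC.

Codes are normalised (upper case, dot inserted after the category when
missing) before matching; an unparseable code is classified `none` with a
warning, never an exception, because one malformed record should not abort
an administrative batch. The acute and chronic code sets are verified
disjoint by exhaustive expansion at load time. Deliberate non-corrections:
the catalogue lists hypoglycaemia (`E16.2`) under diabetes and is kept
verbatim; no same-day-admission filter is applied (the data source does not
mark them); secondary diagnoses and age/sex exclusion rules used by other
ACSC catalogues are out of scope.

The dependent variable is the share of AH in all general hospitalisations
per district-year, computed on a balanced district × year grid with
zero-filling, and carries an explicit `outcome_scale` flag ("proportion" or
"percent") that all effect translation must consult (preventing silent
100× errors).

## Spatial weights

Three constructions, all returned row-standardized so that `W x` is a
neighbour average and the largest real eigenvalue of W is 1:

* **queen contiguity** — neighbours share at least one boundary point;
* **k nearest neighbours** (default k = 5) — Euclidean centroid distances,
  ties broken by district id order; generally asymmetric;
* **distance decay** (default cut-off 50 km) — `w_ij = d_ij^(-a)` within the
  cut-off, default exponent a = 1 (inverse distance). The exact decay form
  and whether the non-contiguity matrices were row-standardized are not
  pinned down by any source available to us, so both are explicit,
  overridable parameters; row-standardizing all three keeps ρ on a common
  scale across specifications.

Islands (districts with no neighbour) are kept as zero rows with a
prominent warning rather than dropped: dropping would silently change N
between model specifications. Distances must be projected kilometres;
coordinates that look like lon/lat degrees are rejected unless the caller
asserts a projection, because a kilometre cut-off is meaningless in
degrees. W is held fixed over time.

## Moran's I

`I = (N/S0) Σ_ij w_ij z_i z_j / Σ_i z_i²` with z the deviations from the
mean; islands are excluded from the statistic (with a warning) since zero
rows contribute nothing to S0 but inflate N. Default inference is a seeded
permutation test with 999 shuffles, reported directionally (toward the
observed side of E[I] = −1/(N−1)); the classical normality and
randomization variance formulas are available as alternatives. For panels
the statistic is computed per year, or pooled as the across-year average of
yearly statistics.

## Panel preparation

Regional fixed effects are removed by district-demeaning every variable
(the within transformation), which also annihilates anything
time-invariant; year dummies for all but the first year are appended
*after* demeaning. District means are stored so the transformation
round-trips. Lags (e.g. the previous year's unemployment rates, used to
blunt reverse causality) shift within district and drop the first years for
all districts, preserving balance. Missing values are rejected, not
imputed: the intended inputs are complete administrative counts.
Standard deviations for per-SD effect translation are computed on the raw
pooled panel (not the within-transformed one); this is a documented choice,
switchable by passing different columns.

## Spatial error likelihood

With B(ρ) = I − ρW, the concentrated log-likelihood over ρ is

    ll(ρ) = −(n/2)[log(2π σ̂²(ρ)) + 1] + c·log J(ρ)

where β̂(ρ) is OLS on the spatially filtered data (B y_t, B X_t per year),
σ̂²(ρ) the mean squared filtered residual, n the Gaussian kernel dimension
and c the number of periods carrying the Jacobian J.

**Year dummies and the unit eigenvalue.** A row-standardized W satisfies
W·1 = 1. Year dummies (together with the intercept the fitter adds
alongside them) absorb each year's cross-district mean — exactly the
1-eigenvector component, which is the most spatially amplified direction of
u. The likelihood of the remaining data is exact, not approximate, with

    n = (N−1)·T,      log J(ρ) = log|B(ρ)| − log(1−ρ),

because the filtered residual of the projected data satisfies
J B(ρ₀) u_t = J ε_t exactly (J the centering projector; B maps span{1} to
itself, so the quotient determinant is |B|/(1−ρ)). Omitting this adjustment
biases ρ̂ downward by O(1/N) *independently of T*: simulations at N = 16,
T = 4 show a bias of about −0.18 without it and about −0.015 with it. The
adjustment is applied automatically whenever year dummies are in the design
and W has unit row sums (islands disable it, with a warning). The intercept
is added because T−1 reference-coded dummies alone leave the reference
year's filtered mean unabsorbed, which overcorrects (≈ +0.08 bias).

**Degrees-of-freedom flag.** An optional Lee–Yu-style correction replaces T
by the T−1 effective periods that district-demeaning leaves. It provably
does not move the ρ argmax (kernel and Jacobian scale by the same factor)
— it only rescales σ̂² and the likelihood level — and is off by default.

**Search and uncertainty.** ρ is searched on (1/μ_min, 1), μ_min the
smallest real eigenvalue of W, by a 25-point grid warm start and bounded
scalar minimisation (xatol 1e-8); log|B| comes from the one-off
eigendecomposition of W, so a likelihood evaluation is O(N·K²). Var(β̂) =
σ̂²(X̃'X̃)⁻¹ (β is asymptotically orthogonal to (ρ, σ²) in the SEM); se(ρ)
comes from the numerical curvature of the profile likelihood. Estimates at
the boundary of the interval trigger a warning. BIC = −2·ll + k·log(N·T)
with k counting all regression coefficients plus ρ and σ².

**SDEM.** Spatially lagged copies `W_x` of the designated Durbin columns
(default in the pipeline: the BMS-selected substantive covariates; year
dummies are never lagged since their lag is themselves) are appended and
the SEM machinery reused; the θ coefficients are those on the lagged
columns, and `lr_test` compares 2Δll to χ²(number of θ). An all-zero
Durbin column is tolerated (it cannot affect the fit) rather than treated
as collinear.

## Bayesian model sampling

Candidates are screened on the demeaned panel with year dummies. The fixed
block (dummies plus any always-include regressors) is projected out of the
outcome and the candidates by QR; each model M over the candidates gets the
Zellner-g-prior marginal likelihood

    log m(M) = −(k_M/2) log(1+g) − ((n−q)/2) log( y'y − g/(1+g)·y'P_M y )

on the residualized data (q = rank of the fixed block). Defaults are the
conventional ones for this methodology, whose original settings are
unreported: unit-information g = n, uniform model prior (a binomial prior
with tunable inclusion probability is available), exact enumeration up to
2^20 models, otherwise an MC3 Metropolis chain with add/drop/swap moves
(swap proposed with probability 0.25) and cached marginal likelihoods.
PIPs are posterior-mass-weighted inclusion frequencies — exact under
enumeration, chain frequencies under MC3. Selection uses the median
probability model (PIP ≥ 0.5), overridable. A rank-deficient candidate
block gets zero mass and a warning instead of aborting the run.

## Effect reporting

`pp_change = β × sd`, rescaled to percentage points through the outcome
scale flag (which is mandatory), and `pct_of_mean = pp_change /
mean_share_pct × 100` with the pooled mean share. Entries with p ≥ 0.05
render as `n.s.`; stars follow the two-sided normal convention *** p < 0.01,
** p < 0.05. CSV exports use 17-significant-digit formatting and re-import
with round-trip float parsing, so rendered tables recover the fit exactly.

## Synthetic data: the stated world

The generator emulates the motivating design — 117 districts × 6 years
(2008–2013), an outcome share around 0.11 — with a known DGP:

    y_it = 0.11 + α_i + τ_t + x_it'β + u_it,   u_t = (I−ρW)⁻¹ ε_t

* geometry: a 13 × 9 lattice of 20 km square cells by default (queen
  contiguity on a lattice is analytically checkable; 20 km cells make the
  50 km cut-off non-degenerate); `random_points` scatters centroids on a
  300 × 300 km square; the lattice rule picks the divisor pair of N closest
  to square, so primes degenerate to a chain;
* disturbances: ρ = 0.4, σ_ε = 0.02 on the share scale, dense solve of
  (I−ρW) (exact; fine for N up to a few thousand);
* fixed effects: α_i ~ N(0, 0.02²), τ_t ~ N(0, 0.005²);
* covariates: eight standard-normal candidates with uniform
  cross-correlation 0.3, β = 0.01 on x1 and x3 and zero elsewhere (i.e.
  active standardized effects of 0.5 σ_ε), mirroring a screening problem
  with correlated but mostly irrelevant candidates;
* discharges: Poisson general counts (mean 2000), ACSC counts rounded from
  the target share, split acute/chronic with probability 0.41 (matching the
  relative size of acute vs chronic shares), scattered over a fixed set of
  catalogue codes plus non-ACSC fillers, with exact truth counts retained;
* seeds: one integer seed drives everything through named SeedSequence
  spawns; the default 20080101 encodes the panel's first year. Identical
  seeds give byte-identical files.

What the generator does **not** emulate: real district shapes or adjacency
irregularities, calibrated covariate magnitudes or trends, over-dispersed
or autocorrelated counts, and any nonlinearity in the outcome. A green
test therefore establishes correctness of the estimators and plumbing
under the stated DGP, not the substantive findings obtainable from the
restricted administrative data (whose headline estimates are deliberately
not reproduced anywhere in this package). The outcome is Gaussian on the
share scale and can stray outside [0,1] in extreme draws; `clip_share=True`
clips it and keeps the latent value in a separate column for recovery
tests.

## Known limitations

* SAR/SDM models with a spatially lagged outcome (λ ≠ 0) are out of scope;
  only SEM and SDEM are estimated.
* Standard errors for ρ use the profile-likelihood curvature; no clustered
  or heteroskedasticity-robust variants.
* The unit-eigenvalue adjustment requires unit row sums; panels whose W has
  islands fall back to the naive Jacobian and inherit its small-N bias.
* Unbalanced panels, random effects, and time-varying W are unsupported by
  design.
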