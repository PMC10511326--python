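# Methods

This note documents the models implemented in `landsea`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate about real monitoring data.

## Driver layers

All drivers live on a 100-m alongshore cell lattice (cells 0-indexed,
distances in metres, years calendar years, windows endpoint-inclusive).
One percentile convention — linear interpolation between order statistics,
the numpy/R type-7 default — is used package-wide (wave-power tails, cover
categories, scenario levers).

**Fish biomass.** W = a·TLᵇ grams per fish, summed as count × W over the
survey area and converted to kg ha⁻¹. The belt-transect area defaults to
125 m² (25 m × 5 m width); width is configurable since survey programmes
differ. Life-history groups poorly captured by visual survey (cryptic,
nocturnal, pelagic schooling taxa) carry an `excluded` flag and are
dropped before summation. Guilds: scraper, grazer, browser,
other-herbivore, other; "herbivore" pools the first four.

**Dispersal kernel.** Offshore/alongshore spreading of land-based loads
uses w(d) = exp(−d²/2σ²). "Approaching zero at 2 km" is operationalized as
σ = 2000/3 m, giving w(2 km) = e^(−4.5) ≈ 0.011; σ is a parameter.
Wastewater effluent and nitrogen flow to the nearest shoreline cell
(sources beyond the one-year groundwater travel time are excluded), then
disperse under the kernel and are divided by cell area. Golf-course
nitrogen is area × 585 kg ha⁻¹ yr⁻¹ × 32% leaching, attenuated by a
Gaussian inland-distance decay with its own scale (default 2 km) — the
inland decay's form is a package choice; only "reduction with distance
inland" is externally constrained.

**Sediment.** Yearly loads modulate a long-term mean by a discharge
ratings curve, load_t ∝ (Q_t/Q̄)^β, rescaled to preserve the long-term
mean. β defaults to 1.5, the middle of the range typical of published
sediment ratings curves; reef-level summaries use the mean of the top-k
annual events (k = 5 pre-disturbance, 3 afterwards).

**Heat stress.** Summer SST statistics are computed over a 90-day window
centred on the maximum of the 7-day moving mean (earliest day on ties;
truncation at series bounds is recorded). DHW follows the Coral Reef
Watch v3.1 convention: hotspot = SST − MMM, accumulation of hotspots
≥ 1 °C over a trailing 84-day window, ÷ 7 for °C-weeks, annual maximum
reported; MMM is an input, not estimated.

**Wave power.** "Mean of the top 97.5%" is ambiguous; the implementation
takes the mean of daily maxima **at or above the year's 97.5th
percentile** (the upper-tail reading). The alternative (largest 97.5% of
values ≈ trimming the lowest 2.5%) would give values close to the plain
annual mean; the tail reading is the one that yields an exposure metric.

**Gear restrictions.** Rank 1 = full no-take … 6 = open access.
Prohibition combinations without a listed category (e.g. a lone spear ban)
map to the least restrictive listed category they satisfy; asserting open
access together with any prohibition is an error.

## Stage 1 — trajectory contrast

Classification uses Δcover over the pre-disturbance window with a ±3
percentage-point cutoff (the observed between-survey range of mean cover
motivates the default; it is a parameter). Outliers are screened per
factor at median ± 2 sample SD before the drop-one jackknife; the
jackknife statistic is the mean/min/max of all pairwise differences
between the two groups' drop-one means. Because the mean of drop-one
means equals the sample mean identically, the central value equals the
plain group-mean difference — the min/max bars carry the sensitivity
information.

PERMANOVA is one-factor on Euclidean distances of z-scored factors
("normalized" is read as z-scoring; no formula is externally fixed).
p-values use unrestricted permutations with the +1 convention
(p = (#{F* ≥ F} + 1)/(n_perm + 1)); when n! ≤ 20,000 the permutation
distribution is enumerated exactly and the identity permutation supplies
the +1. Zero within-group variance makes pseudo-F unbounded; the result is
flagged degenerate rather than silently infinite. The implementation is
cross-checked against scikit-bio's PERMANOVA (statistic agreement to
1e-10) and against the univariate ANOVA F identity.

CAP is classical principal coordinates (for Euclidean distances this is
PCA) followed by linear discriminant analysis on the first m axes, with m
chosen to maximize leave-one-out allocation success (smallest m on ties).
Note that LOO success is *pessimistically* biased under the null — leaving
out a member of group A tilts the training set toward B — so random labels
produce below-50% success on average; the property test asserts
"no better than chance" rather than ≈ 50%.

## Stage 2 — heatwave additive models

Response: Δ = (A_a − A_b)/A_b × 100; reefs with zero pre-event cover are
excluded and logged. Predictor preparation: a-priori exclusions (human
population, browser biomass) → outlier screen at median ± 2 SD with the
25% retention rule (a flagged value within 25% of the most extreme
unflagged value is kept) → named square-root / fourth-root transforms →
z-standardization → correlation pruning (|r| > 0.7 drops one of each pair,
honouring a hypothesis-driven keep list; a conflict between two
keep-preferred predictors is an error at the library level, while the
pipeline releases the lower-priority preference and logs it). Every
removal and transform is recorded.

Coast sections come from average-linkage hierarchical clustering of
alongshore positions; the group count is chosen at the maximum curvature
(discrete second difference) of intragroup variance versus group count,
restricted to granularities whose mean section span is within 1.5× the
10-km target, earliest inflection on ties. Tight, widely separated
clusters therefore win over the target span.

The model per candidate subset is
y = α + Σⱼ fⱼ(zⱼ) + b_section + ε with each fⱼ a cubic regression spline
in the knot-value parameterization (4 knots evenly spaced over the
observed range; penalty = integrated squared second derivative, which has
an exact banded closed form), a sum-to-zero constraint absorbed by QR
reparameterization, and the section random intercept represented as a
ridge-penalized dummy block (the exact mixed-model identity). All
smoothing/variance parameters maximize the exact Gaussian restricted
likelihood; the optimizer is L-BFGS-B on log-λ with bounds e^(−12)…e^(18).
After constraint absorption each smooth's penalty null space is the linear
trend, so an infinitely penalized smooth degrades gracefully to a straight
line rather than to zero.

Effective degrees of freedom are tr{(XᵀX + S)⁻¹XᵀX}; AICc uses
k = edf + 1 (the +1 for the residual variance; smoothing parameters are
not counted, a deliberate simplification documented here because the
reference criterion is silent). AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with ℓ
the Gaussian log-likelihood at the penalized estimates. Candidates with
n − k − 1 ≤ 0 or singular fits are skipped and logged, never silently
dropped.

Model averaging over the ΔAICc ≤ 2 set uses **Akaike-weighted prediction
averaging** (renormalized weights), with unweighted averaging available:
averaging in prediction space is the standard multimodel-inference reading
of "averaging the coefficients" and is well-defined when smooths differ
across models. The pointwise variance combines within-model variance and
between-model spread, w·(se² + (μ_m − μ̄)²); intervals default to 80%.

## Stage 3 — proportional-odds persistence

Internal category order is low < moderate < high with
logit P(y ≤ j) = C_j − η, η = Σ B_k z_k — the latent-variable
parameterization, so a positive B means the predictor favours better reef
outcomes. The equivalent high-first indexing (j = 1 meaning high, with
C*_j + η) is implemented behind a flag and verified to give identical
probabilities; one internal convention avoids sign confusion.

The MLE maximizes the cumulative-logit likelihood with analytic gradients
under the ordered-intercept reparameterization C₂ = C₁ + e^γ (BFGS,
gradient tolerance 1e-5); the covariance is the inverse observed
information evaluated numerically on the natural (C, B) scale. The fit
agrees with an independent implementation (statsmodels `OrderedModel`) to
~1e-5 in log-likelihood and coefficients, and beats a dense grid-search
oracle on small fixtures. Complete separation surfaces as a convergence
error, not a silent huge coefficient.

Brant's test fits the J−1 cumulative binary logits, assembles the
between-model covariance from the fitted probabilities (the Σ̂_jl =
(XᵀW_jj X)⁻¹ XᵀW_jl X (XᵀW_ll X)⁻¹ blocks with W_jl = diag(π_l − π_j π_l)),
and reports per-predictor and omnibus Wald statistics against chi-squared;
an intercept-only model yields an explicit "not applicable" row.
Separation in a sub-model raises an error (the pipeline logs and skips the
diagnostic). The likelihood-ratio test requires nested term sets on the
same data. McFadden's pseudo-R² is 1 − ℓ_full/ℓ_null.

The dredge caps candidates at four predictors (lower replication than the
heatwave stage), k = (J−1) + |subset| exact parameters in AICc, and
records McFadden pseudo-R² per candidate. The scenario engine maps raw
lever values through the recorded transform (square root where applied)
and standardization statistics to z-scores, holds non-lever predictors at
their sample mean (z = 0), and returns the three category probabilities
and fold changes between scenarios.

## Synthetic generator

The generator is the package's ground-truth instrument, not a model of any
real coastline. Structure: reefs occupy distinct cells of a 100-m lattice
(default 2,000 cells ≈ 200 km, 80 reefs, 2003–2019); land-based loads are
log-normal (right-skewed, a robust qualitative feature of pollution-load
distributions); rainfall is daily gamma with a winter-wet seasonal cycle
per 1-km watershed; SST is a sinusoid peaking in late summer plus AR(1)
noise (φ = 0.8, σ = 0.15 °C) plus a boxcar anomaly of 2.2 °C over the
heatwave year's warm season, with MMM taken from the noise-free
climatology; daily maximum wave power is log-normal with a seasonal
modulation and a per-reef exposure multiplier. Heat stress is deliberately
*regional* — every reef sees the same heatwave — mirroring the situation
where divergent outcomes cannot be explained by heat exposure itself.
Guild compositions vary independently between reefs so guild biomasses are
not collinear by construction.

Outcomes: pre-disturbance cover slopes are a linear combination of
injected effects on the standardized drivers plus Gaussian noise (covers
clipped to [0, 100] with every clip logged); the heatwave response is a
linear combination of injected effects minus a 15-point baseline loss; the
post-disturbance category is a latent-logistic draw from the generating
proportional-odds model (defaults B = +1.5 scraper, −1.5 wastewater,
C = logit(0.25), logit(0.75)). Those ordinal defaults were chosen from the
closed form so that combined-lever management scenarios (levers at the
92nd/36th and 95th/36th percentiles) imply a three-to-four-fold gain in
P(high) over single-lever scenarios — the qualitative regime the scenario
engine is meant to operate in.

One integer seed feeds a named-stream `SeedSequence` hierarchy (layout,
fish, sources, rain, sst, wave, pop, reg, phyto; outcome streams spawn
from seed + 1), so individual tables are reproducible bit-for-bit.

**What passing tests show — and don't.** Recovery of injected effects
shows the inference machinery is correct under its own assumptions
(linear/smooth effects on standardized drivers, logistic latent ordinal
noise, exchangeable sections). It does not validate the assumptions
against real reef data: real driver distributions, spatial
autocorrelation beyond a section intercept, observation error in cover
estimates, and survey-frequency imbalance are all outside what the
generator emulates.

## Validation experiments

`landsea.validation` packages the ground-truth experiments used by both
the acceptance tests and `scripts/acceptance.py`. Problem sizes are the
study's own scales: ordinal recovery at n = 55 reefs × 100 replicates
(coefficient recovery reported as the bias of the mean estimate across
replicates — the per-replicate mean absolute error, also reported, is
~0.3–0.36 at these conditions, i.e. at the information limit of the MLE
itself); importance recovery at n = 80 × 100 replicates; scenario
self-consistency averaged over ten n = 500 coastlines to separate engine
error from single-dataset sampling noise; PERMANOVA calibration over
1,000 null datasets of 12 observations with 199 permutations each.

## Known limitations

- No spatial autocorrelation structure beyond the section random
  intercept, and no interaction terms, in the heatwave stage.
- One grouping factor only in PERMANOVA; no nested or multi-factor
  designs.
- No partial-proportional-odds fallback when Brant's test rejects; the
  test reports, the modeller decides.
- The additive-model AICc counts smoothing parameters as free only
  through their effect on edf.
- Driver routing is nearest-shoreline-point only; no hydrological
  networks, no wave or groundwater simulation.
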