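# Methods notes

This document records the models, the defaults and the judgement calls in
`rhizoclim`, in the order the pipeline runs them.

## Study design being emulated

A factorial climate grid: three mean growing-season temperature levels
(6.5, 8.5, 10.5 °C) crossed with four annual precipitation levels (600,
1200, 2000, 2700 mm) gives 12 grassland locations; 8 host plants are sampled
per location (96 samples), each yielding a rhizosphere and a root ASV count
table with mixed prokaryote (16S) and fungal (ITS) markers. Temperature and
precipitation are *design* variables: constant within a location, varying
only across the 12 locations. Every mixed model below therefore uses a
location random intercept, and location-level fixed effects carry roughly
11 denominator degrees of freedom, not 95.

## Synthetic data generator

The generator is first-class, tested code; it defines the conditions under
which every downstream claim is verified.

**Covariates.** A declared ground-truth DAG of standardized linear-Gaussian
structural equations, evaluated in topological order:

    z_child = Σ β·z_parent + b_location + ε

with `b ~ N(0, sd_b)`, `ε ~ N(0, sd_e)`. The coefficient signs encode the
study system: temperature advances and precipitation delays the start of the
growing season (coded as days since the first soil-temperature exceedance of
2.5 °C, so the temperature coefficient is positive), an earlier season
lowers soil pH, shrub cover and plant diversity; temperature raises forb
cover which raises NO3; warm vegetation winters raise bryophyte and lower
litter cover; shrub cover damps the circadian soil-moisture cycle. Default
magnitudes are 0.40–0.60. Residual variances are solved from the recursively
built covariance matrix so every node has *unit population variance* — the
declared βs are then exactly the standardized effects the SEM engine should
recover. The location intercept takes 25% of each residual SD. Physical
scales (days, °C, %, mg kg⁻¹, pH) are affine maps of the latents; affine
maps are invisible to the SEM because it re-standardizes. `festuca_cover` is
generated as pure noise (unaffected by climate).

**Sensor series.** Per location: daily soil temperature in the sampling year
as a sinusoid whose first strict exceedance of 2.5 °C lands on the location's
season-start target; daily canopy temperature equal to the winter target
within January–March; hourly soil moisture for two sensors with a diel
sine whose amplitude is `cv·m·√2` (so the 24 hour-of-day means reproduce the
circadian CV exactly in expectation) plus small Gaussian noise. The default
span is six years (2015–2020) — a desk-scale choice; the field deployment it
mimics is longer. Optional failure windows delete whole months to exercise
the sensor-failure exclusion rule.

**Counts.** Per compartment, each cluster has a latent
`L_c = Σ θ·z_covariate + noise`; an ASV's log abundance is its base level +
its cluster latent + a per-location offset + per-sample overdispersion, and
counts are multinomial draws at log-normal depth (deeper for rhizosphere
than root, mirroring the real compartments' sequencing-depth asymmetry).
Specialist ASVs get location offsets `N(0, 2.0)` centred multiplicatively
(`u −= ln mean(exp u)`) so they concentrate reads across locations without
being more abundant overall — without centring, the abundance-weighted
community CWM reference collapses onto the specialist level and the IQR
labelling rule degenerates. Rhizosphere cluster latents are driven mostly by
season start and soil pH (both *joint* mediators), with one temperature-only
(forb cover) and one precipitation-only (soil moisture) cluster; this is the
mechanism behind the joint-pathway dominance the acceptance suite asserts.
The two compartments use disjoint synthetic ASV id spaces, so the
taxa-overlap summaries are structurally zero on synthetic data (real data
share taxa between compartments).

**What the generator does not emulate:** taxonomy strings, phylogenetic
structure, shared taxa between compartments, non-Gaussian covariate
distributions, mechanistic snow physics, or temporal autocorrelation in the
counts. Passing tests demonstrate the statistical machinery recovers planted
structure under these idealised conditions; they do not certify performance
on field data.

## Filtering

Blank-listed ASVs are removed first, then ASVs with fewer than 100 total
reads, then samples with fewer than 1000 reads — one fixed pass, no
iteration. Manual outlier exclusion is an explicit sample list, never
inferred. The network pre-filter additionally requires presence
(count > 0) in at least 6 samples.

## Community analyses

clr uses pseudocount 1 (common practice and what the downstream network
estimator expects). Shannon entropy is natural-log, averaged over 1000
rarefactions to the smallest retained sample total. PERMANOVA follows the
McArdle–Anderson trace decomposition of Gower-centred squared distances with
*sequential* (Type-I) sums of squares in the order temperature,
precipitation, interaction, on per-location clr centroids (Euclidean on clr
= Aitchison distance; the pairing of clr with PCA implies this geometry, but
it is a choice — Bray-Curtis is not offered). Permutation p-values include
the observed statistic in the null set; numerical cancellation in the
residual SS is clipped at zero so perfect-fit configurations yield the
minimal attainable p rather than NaN.

## Specialisation index

`SI_i = σ_i/μ_i − K/N_i` on rarefied reads; σ uses the sample SD (ddof = 1,
exposed as a parameter — the index's source does not pin the estimator).
ASVs that lose all reads to rarefaction are excluded, not scored zero.
Rarefaction and SI are computed per marker (16S and ITS have very different
depths); cluster CWMs weight the concatenated per-marker rarefied counts,
which slightly over-weights the deeper marker — a documented compromise
since clusters mix markers. Quartiles for the IQR labelling rule use linear
interpolation (exposed as a parameter). The community-wide reference is the
mean over samples of the all-ASV CWM (the per-ASV unweighted mean is the
obvious alternative; the per-sample reading was chosen and the weighting is
visible in the code).

## Mixed-model engine

All regressions are one-random-intercept Gaussian models fitted by REML in
`rhizoclim.lmm`: the likelihood is profiled to a one-dimensional search over
the variance ratio λ = σ²_b/σ²_e using block-wise Woodbury inverses, which
makes a fit ~100× faster than a general mixed-model optimizer — necessary
because the d-separation machinery and the simulation-based tests perform
~10⁵ fits. Agreement with statsmodels' MixedLM (parameters, variance
components, standard errors) is enforced in the test suite. Fixed-effect
p-values are t-tests with containment degrees of freedom: a term constant
within every location is tested against `g − 1 − q_between` df, a
within-varying term against `n − g − q_within` df. This mirrors nested-design
conventions and is what keeps Fisher's C calibrated (z-tests would
accumulate anticonservativeness over ~75 claims). A REML estimate on the
λ = 0 boundary is flagged as a singular random effect; the fit is then
numerically the fixed-effects-only model.

## Networks

Neighbourhood selection runs every node's lasso along one log-spaced
45-point penalty path (from the smallest penalty giving an empty graph, down
by a factor 100), OR-symmetrised. The coordinate-descent path solver is a
numba kernel over the per-subsample Gram matrix (all nodes share it);
agreement with scikit-learn's `lasso_path` is enforced in tests. StARS draws
300 subsamples of 80% of the samples without replacement (the classical
10√n rule exceeds n here), computes edge-wise instability 2θ(1−θ), averages
over all possible edges, monotonizes from the sparse end, and selects the
*densest* penalty whose monotonized instability stays ≤ 0.05 — the selection
rule of the published procedure (picking the sparsest qualifying penalty
would degenerately return the empty graph). Edge signs: mean of the two
directed coefficients at the selected penalty on the full data; pairs with
non-zero opposite-sign coefficients are dropped with a warning — the
estimator itself does not define signs, so this is an interpretation and is
flagged here.

Spin-glass clustering minimises the signed Hamiltonian with γ⁺ = γ⁻ = 1 and
configuration-model nulls per sign layer, by simulated annealing: geometric
cooling 0.99 from T = 1 to 0.01, 25 node-sweeps per temperature, best of 10
restarts. Single-spin moves use O(deg) updates via cluster strength sums; an
explicit xorshift RNG inside the numba kernel makes results bit-for-bit
reproducible for a seed. On 8-node graphs the annealer provably reaches the
exhaustive-enumeration minimum (tested over all 4140 partitions). Cluster
ids are canonical: sorted by descending size.

The cluster-density test rewires edges degree-preservingly (signs travel
with edges) and compares the within-cluster edge share; p includes the
observed network. Cluster–cluster correlations are random-intercept
regressions on transformed (normality ladder, below) standardized
abundances, Bonferroni-corrected by the number of successfully fitted pairs.
Cluster–climate models approximate the beta GLMM by a random-intercept
linear model on logit-clamped abundances (clamp 1e-6) — exact
beta-likelihood fitting is out of scope; the approximation preserves sign
and significance behaviour at this scale and is the documented engine.

## Seasonal covariates

Season start: first calendar day whose *daily mean* soil temperature
strictly exceeds 2.5 °C (instantaneous exceedance is the undocumented
alternative), counted to the sampling date. Winter vegetation temperature:
plain observation mean within January–March across admitted years. Mean soil
moisture: daily means → year means → sensor means, in that order (differs
from the pooled mean under unbalanced coverage; the pooled alternative is
exposed). Circadian CV: population SD over the 24 hour-of-day means divided
by their mean (the 24 bins are the entire population of interest). A year is
excluded per (location, sensor, variable) when more than 5 calendar months
have no observations; a month with any observation counts as present.

## Piecewise SEM

The base model declares the hypothesised climate topology with
`temperature ~~ precipitation` as a design-fixed exogenous pair (exempted
from d-separation claims — their pairing is set by the factorial layout, not
testable). Claims: one per non-adjacent, non-exempt pair, conditioning on the
union of both variables' parents, regressing the later variable in
(lexicographic) topological order — except that when the designated response
is constant within locations and the other variable is not, the direction is
swapped: a location random intercept absorbs a design-constant response
completely and the test would be vacuous (conditional independence is
symmetric, so the swap changes nothing asymptotically). Claim regressions
carry the same random-intercept structure as structural equations, and
transformed responses stay transformed in their claims.

AICc counts *every* estimated parameter: one slope per edge, plus intercept
and two variance components per equation. During backward elimination a node
that loses its last parent keeps an intercept-only equation so each removal
changes K by exactly one and AICc comparisons stay like-for-like (removing
whole equations mid-loop rewards model collapse through vanished claims);
nodes with neither parents nor children are pruned only when the final model
is assembled. Candidate edges are scanned in decreasing p-value order
(declaration order breaks ties) and the first removal that lowers AICc is
kept; the loop stops when none does. With K ≈ 50 and n = 96 the marginal
AICc penalty is ≈ 9.6, i.e. an edge survives when its d-sep claim would have
p below ≈ 0.008 — the practical retention/removal boundary of this design.

Appended microbial responses are transformed by the first rung of
identity → ln(x + ε) → √x whose LMM residuals pass Shapiro–Wilk at α = 0.05
(ε = half the smallest positive value); elimination then touches only the
response's edges, and the engine asserts bitwise equality of upstream
coefficients before returning. Candidate parents are restricted to nodes
reachable from temperature or precipitation (climate-unrelated pathways are
excluded by design).

## Attribution

Composite effect = product of standardized coefficients along a path over
edges with p < 0.05. Joint = the path's first mediator has both climate
drivers among its ancestors in the final model; direct edges carry their
source's label. The response's marginal R² budget is allocated across
categories proportionally to summed |composite effect| (signed sums are also
reported; sign handling in the scaling is under-determined and the
proportional-absolute rule is one consistent reading, labelled as such);
random = conditional − marginal R²; unexplained = 1 − conditional R². When a
response's final equation retains only non-significant edges (p between the
AICc boundary ≈ 0.008 and 0.05), no significant pathway exists while
marginal R² > 0; the pipeline then reports zero for every climate category
and folds that variation into the unexplained share so the shares still sum
to one. Aggregation across a compartment's clusters weights by relative read
mass, renormalized.

## Problem sizes and determinism

Defaults: 96 samples; 50 rhizosphere ASVs in 5 planted clusters and 40 root
ASVs in 4; StARS with 45 penalties × 300 replications; spin-glass with 10
restarts; 1000 Shannon rarefactions; 999 PERMANOVA permutations; 199
density-test rewirings. An end-to-end run takes ~1–2 minutes on one CPU and
is bit-for-bit reproducible for a fixed seed (every stage derives its
sub-seed from the master seed via SHA-256). The simulation-based tests use
200–500 replicates per claim.

## Known limitations

- The root compartment's shallower depth and smaller clusters fragment its
  inferred partition (adjusted Rand ≈ 0.5–0.6 vs ≈ 0.8 in the rhizosphere);
  the planted direct climate effects on root clusters are correspondingly
  hard to detect at 12 locations.
- StARS at subsample ratio 0.8 under-estimates instability (subsamples share
  most of their data), so selected graphs are denser than the true graph;
  edge precision ≈ 0.6 at n = 96, p = 60 is the realistic operating point.
- The beta GLMM is approximated on the logit scale; estimates are not
  beta-likelihood estimates.
- Only one random-intercept grouping (location) is supported; no crossed or
  nested random effects.
- Sensor synthesis reproduces location *means*; within-location microsite
  variation in the seasonal covariates exists only in the covariate table,
  not in the series.
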