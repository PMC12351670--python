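# rhizoclim

Tools for tracing how temperature and precipitation shape the rhizosphere
and root microbiome of a perennial grass growing across a factorial climate
grid (3 summer-temperature levels × 4 annual-precipitation levels, 12
grassland locations, 8 plants each). The central question is *via which
pathways* climate acts: directly, through the start of the growing season
(snowmelt timing), through plant community composition, or through soil
chemistry — and how much of the variation in microbial community structure
each pathway explains.

The package is organised as an analysis pipeline over five statistical
components:

1. **Compositional community analysis.** Counts are centred-log-ratio (clr)
   transformed, `clr(x)_i = ln(x_i + 1) − mean_j ln(x_j + 1)`; PERMANOVA with
   sequential sums of squares tests temperature, precipitation and their
   interaction on per-location Aitchison centroids; Shannon diversity is
   averaged over repeated rarefactions.
2. **Habitat specialisation.** For each ASV, on reads rarefied to a common
   depth, `SI_i = σ_i/μ_i − K/N_i`: the coefficient of variation across
   samples minus a correction for under-sampling of rare ASVs (`K` habitat
   classes = 12 locations, `N_i` total rarefied reads). Community-weighted
   mean (CWM) SI summarises samples; network clusters are labelled
   specialist/generalist/unspecified by comparing their per-sample CWM
   distribution (IQR rule) with the community-wide mean.
3. **Signed co-occurrence networks.** Neighbourhood selection — an
   L1-penalised regression of every ASV's clr profile on all others along a
   45-step penalty path — with the penalty chosen by StARS (edge-selection
   instability `mean 2θ(1−θ)` over 300 without-replacement subsamples,
   threshold 0.05). Edge signs come from the mean of the two directed lasso
   coefficients. Clusters minimise the signed spin-glass Hamiltonian
   `H = −Σ[w⁺ − γ⁺p⁺]δ(c_i,c_j) + Σ[w⁻ − γ⁻p⁻]δ(c_i,c_j)` by simulated
   annealing (positive edges attract, negative edges repel; no preset
   cluster number).
4. **Piecewise structural equation models.** Each structural equation is a
   random-intercept (location) linear model on standardised variables;
   global fit uses Shipley's d-separation basis set and Fisher's
   C = −2 Σ ln p ~ χ²(2k); models are reduced by backward elimination under
   AICc = C + 2Kn/(n−K−1) and accepted when p_C > 0.05. Microbial responses
   are appended downstream of the accepted base model without touching
   upstream estimates.
5. **Pathway attribution.** Every significant climate→cluster path gets a
   composite effect (product of standardised coefficients along the path);
   paths are temperature-only, precipitation-only or *joint* (first mediator
   has both climate drivers as ancestors); a cluster's marginal R² is split
   across categories in proportion to |composite effect|, the
   conditional−marginal gap is the within-location "random" share, and
   aggregation weights clusters by relative read mass.

A synthetic-data generator emulates the whole study from a declared
ground-truth path diagram (linear-Gaussian structural equations on the
factorial grid, sensor time series consistent with each location's season
start and moisture regime, and Dirichlet-multinomial-like ASV counts with
planted clusters and habitat specialists), so every stage can be tested
against known truth without any downloads.

## Worked example

```sh
rhizoclim demo --seed 1 --out demo_run
```

runs simulate → filter → community → seasonal → specialisation → networks →
clusters → SEM → attribution → report (about 1–2 minutes) and prints:

```
## Base path model
- Fisher's C = 145.67 on 150 df, p = 0.585 (accepted)
- AICc = 368.21, K = 51, n = 96

## Rhizosphere network
- 6 clusters; labels: c1=specialist, c2=generalist, c3=generalist, ...

## Attribution (cluster-size weighted)
- rhizosphere: temperature_only=0.000, precipitation_only=0.000, joint=0.254,
  random=0.299, unexplained=0.448
- root: temperature_only=0.050, precipitation_only=0.000, joint=0.013,
  random=0.638, unexplained=0.299
```

Reading this: the hypothesised base path model is consistent with the
simulated data (the d-separation test does not reject it, p = 0.585); the
rhizosphere co-occurrence network splits into six clusters; and of the
variation in rhizosphere cluster abundances, 25% is explained by pathways
driven **jointly** by temperature and precipitation (mostly via the start of
the growing season and its effect on soil pH), 30% by within-location
structure absorbed by the random effect, and the rest is unexplained — the
joint-pathway dominance the generator plants by routing climate effects
through season start.

The numbered scripts under `analysis/` run the same stages individually with
narrated output, e.g.

```sh
python analysis/01_simulate.py --seed 1 --out results/run
python analysis/06_sem.py      --seed 1 --out results/run
```

Individual stages are also exposed on the CLI
(`rhizoclim run network --out demo_run --seed 1`) and as plain functions
(`rhizoclim.stars_select`, `rhizoclim.spinglass_cluster`,
`rhizoclim.SemEngine`, ...).

## Layout

```
src/rhizoclim/     io_tables, community, specialisation, network, seasonal,
                   sem, attribution, synth, lmm, pipeline, cli
analysis/          numbered narrative drivers over the pipeline stages
tests/             unit, property and acceptance suites
docs/methods.md    model and implementation notes
```
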