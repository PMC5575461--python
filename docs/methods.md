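# Methods

This note documents the models implemented in `andesdiv`, the numerical
choices behind them, what the synthetic-data generators emulate, and the
design decisions taken where several defensible options existed.

## Chronograms

All analyses operate on rooted, strictly binary, ultrametric chronograms
with node ages in Myr measured backwards from the present (tips at 0,
root at the crown age T). Time is counted backwards because
palaeo-elevation curves and divergence-time literature are written in Ma
before present. Newick input must carry branch lengths; trees whose
root-to-tip path spread exceeds `1e-4 * T` are rejected rather than
silently stretched (dated trees are ultrametric by construction, so a
larger spread indicates a data problem), and polytomies are rejected
because every likelihood below assumes binary nodes.

## Palaeo-elevation curve

The elevation history E(t) is a cubic smoothing spline through (age,
elevation) samples, clamped at 0 m and extended as a constant beyond the
oldest sample. The smoothing penalty defaults to generalized
cross-validation and can be set to 0 for exact interpolation. The
synthetic uplift generator is a logistic curve

    E(t) = E_floor + (E_max - E_floor) / (1 + exp(-k (t_mid - t))),

defaulting to a Northern-Andes-like history: plateau E_max = 4000 m at
the present, inflection t_mid = 6 Ma, steepness k = 1 /Ma, floor 0 m.

## Environment-dependent birth-death model

Rates follow the exponential dependence

    lambda(t) = lambda0 exp(alpha x(t)),   mu(t) = mu0 exp(beta x(t)),

where the covariate x is elevation in km ("env" form, so alpha is per
km), time in Myr ("time" form, the time-exponential cross-check
variant), or absent ("constant"). The exponential law is the canonical
form of the environmental-dependence framework and keeps rates positive;
alpha = beta = 0 recovers the constant-rate birth-death exactly.

The reconstructed-tree likelihood integrates the extinction probability
E(t) (tip condition 1 - f, with f the known uniform sampling fraction)
and the accumulated per-lineage log-decay Phi(t) as one augmented ODE.
Each branch contributes -(Phi(parent) - Phi(child)); each internal node
except the root contributes log lambda(t_node); each tip contributes
log f. Crown-survival conditioning (default, toggleable) divides the
root-factor-carrying likelihood by lambda(T) (1 - E(T))^2, which for the
root-factor-free form used internally amounts to subtracting
2 log(1 - E(T)). Constant combinatorial factors are omitted throughout;
they cancel in every AIC comparison on a fixed tree. The closed-form
constant-rate likelihood (logistic solution of the extinction ODE) uses
the same conventions and is kept free of any shared numerical code so it
can serve as an independent cross-check; the two agree to ~1e-13 on
simulated trees of 10-200 tips.

Numerics: the E/Phi system is integrated by classical RK4 on a uniform
2000-step grid with rates evaluated at half-steps, and evaluated between
grid nodes by cubic Hermite interpolation using the analytic slope. This
is deterministic, fast (~0.3 ms per likelihood), and accurate far below
the 0.01-AIC scale that model ranking needs.

Fitting maximizes over log(lambda0), log(mu0) (bounds 1e-6..100) and
unconstrained alpha/beta with multi-start bounded L-BFGS-B (default 3
starts; the recovery study below uses 6 because the flat
lambda0-mu0 ridge described there stalls the optimizer from poor
starts). Wald 95% intervals come from the central finite-difference
observed information in the optimization coordinates. AICc uses the tip
count as the sample size.

## Two-region GeoSSE

States are A (the focal montane region), B (everywhere else), and AB
(widespread). The seven rates are within-region speciation sA/sB,
between-region speciation sAB of widespread lineages, extirpation xA/xB
(death for single-region lineages, contraction AB -> B or A), and range
expansion dA/dB. The likelihood integrates the three coupled extinction
equations and three clade equations along branches, combines daughters
at nodes with the state-dependent speciation kernel (the AB row
averages both daughter orderings), and handles the root by
likelihood-proportional weighting by default ("equal" and fixed weights
are available) - the de-facto convention of the standard
state-dependent-diversification software. Survival conditioning divides
by the root-weighted lambda_s (1 - E_s(T))^2 with lambda_AB = sA + sB +
sAB. State-specific tip sampling fractions enter the tip conditions.

Numerics: extinction probabilities on a 1500-step RK4 grid (cubic
Hermite between nodes, clamped to [0, 1]); clade probabilities per
branch with RK4 at step T/400 in a compiled postorder sweep with
per-node rescaling. The implementation is self-converged to ~1e-14
under grid refinement and agrees with an independently coded fixed-step
Euler integrator (dt = 1e-4) to under 1e-4 on random 5-tip trees; that
residual is the Euler oracle's own first-order truncation (it halves
when dt is halved), so the oracle-test parameter draws are kept at
crown ages 0.7-1.2 Myr and rates below 0.25/Myr where the oracle's
error budget is a few 1e-5.

Constrained fits tie rates by equality (e.g. sA=sB); tied groups share
one free log-rate. The asymmetry statistic is dAIC = AIC(constrained) -
AIC(free), and its null distribution is built by refitting both models
to uniformly reshuffled tip states (warm-started from the observed
optima to keep many permutations tractable), with the add-one p-value
(1 + #{null >= observed}) / (n + 1). Because a "difference in
diversification between regions" can mean either the dispersal contrast
or the net-diversification contrast, the MCMC reports both dA - dB and
(sA - xA) - (sB - xB) alongside sA - sB. MCMC uses an adaptive joint
Gaussian random walk in log-rate space with independent exponential
priors of mean 2 ln(n)/T (a net-diversification scale), overridable; a
prior-only mode exists for prior-recovery checks.

## Speciation-rate mapping

Per-species tip speciation rates (typically exported from an upstream
rate-shift analysis) are joined to occurrence records, the records are
thinned to exactly one per 0.5-degree grid cell (half-open cells
anchored at integer degrees; the seed decides which record survives,
never how many) to blunt collection-density bias, and the thinned rated
points are interpolated by inverse distance weighting onto a grid
masked to the clade's distribution polygon. Defaults: power p = 2 and
k = 12 neighbours (the documented defaults of the GIS tool that
popularized the method), great-circle (haversine) distances because the
domain spans tens of degrees of latitude, a mask defaulting to the
convex hull of the points buffered by one cell (no curated distribution
polygon is assumed to exist), and thinning applied before rate
attachment since the bias being corrected concerns record density, not
rates. A cell centre closer than 1e-6 km to a point takes that point's
rate exactly. Rasters are written as ESRI ASCII grids or CSV (both
round-trip bit-exactly); regional summaries bootstrap over points, not
cells.

## Elevation traits

Species elevations are summarized as the mean (plus min/max/count) of
their records; species whose records all lack elevations are excluded
and reported. The montane/lowland split uses the 1100 m sub-Andean
forest limit with montane = mean strictly above 1100 m; the boundary
point itself is classified lowland because the ecoregion definition's
two strict inequalities leave it undefined, so the convention is
documented rather than implied. Richness profiles count species per
half-open elevation bin (default 250 m) and always conserve the species
total.

Ancestral elevations assume Brownian motion. sigma^2 is the REML
(independent-contrasts) estimator; node expectations and variances come
from the standard two-pass pruning recursion (uppass of subtree
conditional moments, downpass folding in the rest of the tree), which
equals GLS with a flat root prior - verified against a dense
graph-Laplacian GLS solver. Zero-length branch pairs make the system
singular and raise an error. Estimates are convex combinations of tip
values and shift-equivariant; the package emits the (node age, estimate,
variance) table a traitgram would be drawn from rather than a figure.

## Synthetic data generators

The generators are first-class, tested code and define the study
conditions for every validation:

- **Birth-death trees**: forward Gillespie from two crown lineages with
  thinning against a dense-grid rate bound (rates are evaluated on a
  4096-point grid); extinct and unsampled lineages pruned; each extant
  tip kept independently with probability f. Trees are resampled until
  both crown lineages retain a sampled descendant, so the reconstructed
  crown age equals the nominal crown age and matches the conditioned
  likelihood.
- **GeoSSE trees**: exact Gillespie over the seven event types with the
  same event semantics the likelihood assumes (notably xA on AB =
  contraction to B). Stopping at a tip count uses GSA-style sampling - a
  time drawn uniformly (length-weighted) from the epochs during which
  exactly n lineages were extant - avoiding first-passage bias.
- **Occurrences**: per-species centroids uniform in rectangular region
  boxes (an Andes-like box for A, an adjacent lowland box for B;
  widespread species get a centroid in each), Gaussian scatter (0.5
  degrees), record counts Poisson with mean 20 (min 1), elevations from
  per-region truncated normals (A: 2000 +/- 600 m, B: 300 +/- 250 m).
  Rectangles rather than real topography: the analyses consume only
  point patterns, so realistic coastlines would add nothing testable.
- **Range reshuffling**: a uniform permutation of the state column,
  exactly preserving the state multiset.

What the generators do *not* emulate: spatially autocorrelated sampling
effort, georeferencing error, taxonomic misidentification, non-uniform
(genus-stratified) sampling fractions, and rate heterogeneity beyond
the fitted forms. Passing validations therefore demonstrate internal
correctness and statistical behaviour under the assumed models, not
robustness to the full messiness of herbarium data.

## Validation studies and problem sizes

The studies in `andesdiv.studies` are run by `scripts/acceptance.py`
at the following sizes (the test suite runs the same studies, some at
reduced replicate counts, noted in parentheses):

- Constant-rate limit: 100 simulated trees, 10-200 tips.
- GeoSSE Euler-oracle agreement: 20 random 5-tip trees.
- Env-BD recovery: 200 replicates (tests: 80) simulated with
  lambda0 = 0.2/Myr, alpha = 0.5/km, mu0 = 0.05/Myr on the default
  uplift curve, crown age 9 Myr, uniform sampling fraction set so the
  expected sampled tip count is 100 (f ~ 0.02) - mirroring the heavy
  undersampling of real mega-diverse epiphyte clades.
- GeoSSE type-I calibration: symmetric generator sA = sB = 0.2,
  xA = xB = dA = dB = 0.05, sAB = 0.1, root AB; 25 replicates of
  100-tip trees with 19 permutations each (tests: 12 replicates of
  70-tip trees). With 19 permutations the test rejects exactly when the
  observed dAIC exceeds every null value, giving a 5% level by
  construction under exchangeability.
- GeoSSE power: sA = 0.3 vs sB = 0.15 at 150 tips; 100 replicates
  (tests: 40).
- Rate-map contrast: 50 seeded datasets with Andes-box rates double
  lowland-box rates.
- BM root coverage: 200 BM simulations (sigma^2 = 100 m^2/Myr, root
  1000 m) on random 100-tip chronograms.

## Known limitations

- **The base rate lambda0 is weakly identified at ~100 tips under the
  recovery study's conditions.** With speciation reaching
  ~1.5/Myr at the present-day 4000 m plateau, a ~100-tip tree forces a
  ~2% sampling fraction at any plausible crown age, and extinction then
  trades off almost perfectly against sampling: the likelihood has a
  flat (lambda0, mu0) ridge (freeing mu0 gains only ~0.05 log-units
  over fixing it at truth). The ML lambda0 consequently has a 10-90%
  range spanning more than a decade and a median bias of roughly
  +20-40%. This is a property of the information content, not the
  optimizer (high-precision polishing changes nothing) or the
  implementation (bias is -1% with mu0 known, -9% at 400 tips, and the
  constant-rate analogue at f = 0.1 is unbiased to -2%). alpha, by
  contrast, is recovered with <15% median bias and ~90% CI coverage,
  and the environment model beats the constant model by AIC in
  essentially every replicate.
- Permutation refits reuse the observed optima as warm starts; with a
  single restart per refit, occasional convergence to a local optimum
  adds noise to individual null draws but not systematic bias (the same
  procedure is applied to every permutation).
- The GeoSSE family here is strictly two-region, without hidden states;
  the mapping stage offers IDW only (no kriging); discrete-character
  ancestral estimation is out of scope.
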