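# Methods

This note documents the models, estimators, numerical choices and known
limitations of `phyloflora`, in the order the pipeline applies them.

## Phylogeny handling

Trees are rooted, with finite non-negative branch lengths and unique tip
labels; Newick I/O and birth–death simulation are delegated to dendropy and
wrapped in an immutable `Phylogeny` with cached array views (edge-by-tip
incidence, root-path depths, patristic distance matrix). Patristic
distances come from the shared-path identity
d(i,j) = depth(i) + depth(j) − 2·shared(i,j), with shared root-path lengths
obtained as a single weighted incidence product.

**Megatree grafting.** New species are attached at the most basal node of
their genus — the MRCA of congeneric tips, or the parent of the single tip
for a monotypic genus — with pendant branch length equal to that node's
age, so an ultrametric backbone stays ultrametric (checked to a relative
tolerance of 1e-6 of tree depth). Genera absent from the backbone are
reported as skipped, never errors; polytomies are left unresolved. When no
explicit tip→genus mapping is supplied, the genus is the first whitespace-
or underscore-delimited token of the tip label. This deliberately simple
placement preserves metric values well; reproducing any particular
tree-building package's internal node tables is out of scope.

## Metrics

- **Faith's PD** is root-inclusive: it sums the union of root-to-tip paths,
  so a single-species region has PD equal to that species' root distance.
  This keeps PD defined for richness-1 regions; the convention is stated
  here because alternatives (MRCA-rooted PD) exist.
- **Area correction** divides PD by log₁₀(area km²). Areas ≤ 1 km² are
  rejected (non-positive divisor); areas in (1, 10] km² warn.
- **MPD** is the unweighted mean over unordered pairs.
- **RPD** divides the PD *fraction* on the observed tree by the PD fraction
  on a unit-branch-length tree of identical topology (each tree first
  normalized by its own total length). RPD is therefore invariant to
  uniform rescaling of the branch lengths and equals 1 for the full tip
  set.
- **SES** uses the uniform tip-shuffle null: tip sets of the observed size
  drawn without replacement from the pool of all tree tips. Two modes are
  provided: exhaustive enumeration of all C(pool, k) subsets (population
  sd, ddof 0) when that count is below a configurable cap, and seeded
  Monte Carlo (default 999 draws, sample sd, ddof 1). The two agree in
  expectation; the suite checks them against each other and checks the
  exact identity E[MPD] = pool mean pairwise distance. A null whose spread
  is zero up to floating-point noise (relative 1e-12) — the whole pool, or
  a star tree — yields an SES reported as missing with a reason, not an
  exception. Per-region null seeds are derived from the master seed by a
  CRC of (seed, region, metric), so batch tables and standalone calls
  reproduce each other exactly.

Species absent from the tree are dropped with a logged count; regions left
empty are excluded with a warning. The species pool defaults to all tips of
the supplied tree; restricting it (e.g. per continent) is a caller choice.

## SAR error model

The model is y = Xβ + u, u = λWu + ε, ε ~ iid N(0, σ²). W is
row-standardized; by default k = 8 nearest neighbours by great-circle
distance between region centroids, with distance ties broken by position in
the region-id order. The log-likelihood is profiled over λ:
β and σ² have closed forms from OLS on the filtered data (I − λW)y,
(I − λW)X, and the Jacobian log|det(I − λW)| is evaluated from the (possibly
complex) eigenvalues of W, computed once per weights matrix and cached.
λ is searched by bounded scalar minimization (tolerance 1e-8) on the open
interval between reciprocal extreme real eigenvalues, shrunk by 1e-6. An
all-zero W short-circuits to OLS with λ = 0. The reported pseudo-R² is
1 − RSS(Xβ̂)/TSS — trend predictions only, which is the definition used in
all output tables. Standardized coefficients z-score both variables with
the n−1 sample sd before fitting.

Calibration is established by simulation: median estimates over 50
parameter-recovery runs (n = 400, λ = 0.6, innovation sd 0.5 — chosen so a
50-run median resolves a few-percent relative error) fall within 5% of the
true coefficients and 0.1 of λ, and the slope z-test rejects at 3–7% under
the null. The profile optimum is verified against a 2,001-point λ grid.

## Variation partitioning

Fractions are inclusion–exclusion combinations of adjusted R²
(1 − (1 − R²)(n − 1)/(n − p − 1)) from OLS fits of the response on each
union of predictor groups — OLS, not SAR pseudo-R², because the adjustment
formula presumes the OLS coefficient of determination; an alternative R²
function can be injected for sensitivity analyses and is clearly
non-default. All group members always enter together. Because each
component model is penalized for its own predictor count, fractions can be
negative; they are reported as computed. The identities (fractions sum to
the full-model adjusted R²; identical groups collapse to pure overlap) are
exact and tested to 1e-10 against an independent statsmodels oracle.

Variable groups: C = {T_mean, T_min, T_seas, P_mean, P_min, P_seas},
H = {T_anom, T_vel, P_anom, P_vel}, V = {E_sd, T_sd, P_sd}; subgroups
T/P (temperature- vs precipitation-related) and E = {T_min, P_min} vs
S = {T_seas, P_seas}. Six designs run per scope and metric: C|H, C|V, H|V,
C|H|V, T|P, E|S.

## Pipeline

Scopes are the global region set plus one scope per continent label taken
from the region table (labels are input data, never inferred from
coordinates); scopes below 17 regions (configurable) are skipped with a
warning. Weights are rebuilt inside each scope, so continental models have
no cross-continent neighbours. Missing metric values are deleted pairwise
per (metric, scope), and weights are rebuilt on the surviving regions.
Summaries average |standardized coefficients| across the five metrics per
variable and scope, coefficients across continents, and partition fractions
across metrics (per scope) and across continents (per metric), always
excluding missing cells and reporting the contributing count. A `run-all`
invocation writes every table with a fixed column order and a manifest
carrying the configuration and its hash; outputs are byte-reproducible
given the same config and seed.

## Synthetic worlds

The generator emulates the statistical structure of a global flora/climate
dataset at desk scale. Defaults define the study conditions used throughout
the test suite.

- **Tree**: birth–death (0.4/0.1 per lineage per Myr) conditioned on 500
  extant tips; depth is then ~20 Myr.
- **Niche evolution**: Brownian motion per axis (temperature °C,
  precipitation mm) run on an early-burst rescaled tree: branch lengths are
  multiplied by a rate decaying as e^(−0.25 t) with age t from the root.
  Plain BM produces trait similarity proportional to relatedness but not
  *clade-structured* tolerances: in a sizeable fraction of plain-BM worlds
  two deep lineages independently drift cold, and cold floras are then
  convergent mixtures rather than clustered clades. The early-burst
  transform concentrates divergence on deep branches, which is the
  standard generating model for phylogenetic niche conservatism — major
  tolerances diverge among deep clades and are retained within them.
  Setting `conservatism_rate = 0` recovers homogeneous BM; `evolve_bm`
  itself is always plain BM (tip-state variance σ²·depth, covariance
  σ²·shared path, both verified by simulation). Root states sit at the
  warm, moist end of the gradient (26 °C, 1800 mm) with initial rates 5
  °C²/Myr and 5·10⁴ mm²/Myr.
- **Regions**: a 12×12 lon/lat grid (lat −55…70), log-uniform areas in
  [10³, 10⁶] km², six contiguous continent blocks.
- **Environment**: latent fields x = (I − ρW)⁻¹ε (rook weights, ρ = 0.8)
  mapped affinely to units; T_mean carries a −0.35 °C/degree-latitude
  gradient; T_min is T_mean minus a latitude-growing offset; P_mean is
  log-normal; P_min ≤ P_mean/12 by construction. Anomalies are present
  minus past with a shift surface dominated by its own spatial structure
  (mildly latitude-weighted); velocities divide the temporal rate
  (anomaly over 21,000 yr) by the local spatial gradient from neighbouring
  regions, floored at 1e-6 units/km to avoid unbounded values on flat
  surfaces. Heterogeneity columns are sds over 25 sub-cells whose spread
  follows relief surfaces independent of the climate means — a deliberate
  simplification that keeps the V group from proxying the C group.
- **Assemblages**: species occur where every niche optimum is within the
  axis tolerance (10 °C, 1600 mm) of the regional mean. The filter is hard
  and deterministic; empty regions are allowed.

What these worlds do **not** contain: dispersal limitation, abundance,
speciation–environment feedback, realistic paleoclimate, taxonomic error.
Passing tests therefore demonstrate that the estimators and the pipeline
recover known generative structure, not that real floras behave this way.

A note on the generative signature experiment: with conserved warm niches
and a latitudinal gradient, the standardized SAR coefficient of MPD_ses on
T_min is positive in roughly nine out of ten seeded worlds (and the pure-C
partition fraction dominates essentially always). The residual failures are
worlds in which convergent cold tolerance arises in two deep clades despite
the early-burst model; this is an irreducible property of Brownian-type
trait evolution, discussed above, and the success proportion should be read
with that in mind.

## Problem sizes

Test and acceptance runs use 50–500-tip trees, 64–256-region grids,
99–999-draw nulls, 50-simulation recovery studies, 500-replicate
calibration studies and 50-world generative experiments — sizes chosen so
the full suite completes in minutes on a single CPU while every statistical
check retains adequate power; each experiment's n is recorded in its
output.
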