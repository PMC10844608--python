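# phyloflora

Phylogenetic structure of regional floras and its environmental drivers.

Large-scale floras are not random draws from the species pool: lineages tend
to retain their ancestral climatic tolerances (phylogenetic niche
conservatism), so assemblages in climates far from a clade's ancestral niche
are built from the few clades that crossed the ecophysiological barrier and
are therefore phylogenetically clustered. `phyloflora` provides the complete
analysis chain used to test this at the regional scale — for ecologists and
biogeographers working with regional species checklists, a dated phylogeny,
and per-region environmental summaries — together with a fully seeded
synthetic-world generator so every step can be validated end to end without
any proprietary data.

## What it computes

**Five phylogenetic metrics per region** (richness *n*, tree with branch
lengths in Myr):

- **PD** — Faith's phylogenetic diversity, the summed branch length of the
  union of root-to-tip paths spanning the assemblage, divided by
  log₁₀(area in km²) to correct for sampling area;
- **MPD** — mean patristic distance over all unordered species pairs,
  sensitive to deep tree structure;
- **RPD** — relative phylogenetic diversity,
  (PD/L) ÷ (PD₁/L₁) where PD₁, L₁ are computed on a comparison tree of
  identical topology with all branch lengths set to one; RPD > 1 marks an
  excess of long branches;
- **PD_ses, MPD_ses** — standardized effect sizes
  (obs − mean₀)/sd₀ under a null drawing equal-sized tip sets uniformly from
  the pool of all tree tips (Monte Carlo, or exhaustive enumeration on small
  pools). Positive = overdispersion, negative = clustering.

**Spatial regression.** Each metric is regressed on each of 13 environmental
variables (6 current-climate, 4 historical-climate, 3 heterogeneity) with a
maximum-likelihood simultaneous autoregressive (SAR) error model
y = Xβ + u, u = λWu + ε, where W is a row-standardized k-nearest-neighbour
great-circle weights matrix. Variables are z-scored first, so the slope is a
standardized coefficient. λ is profiled with an eigenvalue-based
log-determinant.

**Variation partitioning.** Explained variation is decomposed among variable
groups by inclusion–exclusion on adjusted R²
(1 − (1 − R²)(n − 1)/(n − p − 1)): three pairwise designs (C|H, C|V, H|V),
the full three-set design, and two current-climate subgroup designs
(temperature T vs precipitation P, extremes E vs seasonality S). Fractions
may legitimately be negative and are reported as computed. Analyses run
globally and per continent, and summaries average |coefficients| across
metrics and fractions across metrics or continents.

**Synthetic worlds.** A seeded generator produces a birth–death phylogeny,
niche optima evolving by Brownian motion on an (optionally) early-burst
rescaled tree — the generating model for clade-structured niche
conservatism — spatially autocorrelated climate surfaces on a lon/lat grid
with a latitudinal temperature gradient, glacial–present anomaly and
velocity layers, sub-cell heterogeneity, and assemblages built by
environmental filtering of niche optima.

## Worked example

```python
from phyloflora import (SyntheticConfig, generate_world,
                        NullSpec, compute_metric_table)
from phyloflora.pipeline import make_scopes, run_coefficients

cfg = SyntheticConfig(seed=42, n_tips=120, grid_shape=(10, 10))
world = generate_world(cfg)
metrics = compute_metric_table(world.tree, world.assemblages, world.regions,
                               NullSpec(n_randomizations=999, seed=42))
print(metrics.head(4).round(3))
```

```
region_id  richness  PD_raw     PD    MPD   RPD  PD_ses  MPD_ses
    r0003        17  74.864 14.237 16.337 1.273  -3.304   -3.625
    r0004        26  93.702 30.093 16.137 1.195  -4.505   -5.246
    r0005        64 163.510 30.139 16.738 1.035  -6.172   -9.027
    r0006         8  43.331 10.172 13.810 1.141  -2.700   -4.630
```

Every region is phylogenetically clustered (negative SES: assemblages are
filtered subsets of the pool), more strongly so at higher richness-corrected
depth. Regressing the deep-structure metric on minimum temperature recovers
the niche-conservatism signature — clustering intensifies toward the cold:

```python
scopes = make_scopes(world.regions, min_n=17)
coef = run_coefficients(metrics, world.env, world.regions, scopes)
print(coef.query("metric == 'MPD_ses' and variable == 'T_min' "
                 "and scope == 'global'").round(3))
```

```
 metric variable  scope  std_coef  lambda  pseudo_r2   n
MPD_ses    T_min global     0.347  -0.333       0.09  78
```

The positive standardized coefficient (+0.35) says MPD_ses increases with
minimum temperature: cold-region floras are drawn from fewer, more closely
related clades. Temperature variables dominate the global summary
(mean |coefficient| across the five metrics: T_min 0.460, T_mean 0.450,
T_seas 0.425).

A complete run — simulation, metrics, coefficients, partitions, summaries,
manifest — is one command:

```
phyloflora run-all --seed 42 --out runs/demo
```

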