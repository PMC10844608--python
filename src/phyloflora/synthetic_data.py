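"""Seeded synthetic worlds: phylogeny, niches, climate surfaces, assemblages.

The generator emulates the statistical structure of a global regional-flora
dataset: a dated birth-death phylogeny, species niche optima evolving by
Brownian motion (hence phylogenetically conserved), a lon/lat grid of
regions with spatially autocorrelated current-climate surfaces and a
latitudinal temperature gradient, glacial-to-present anomaly and velocity
surfaces, within-region heterogeneity from sub-cell values, and incidence
produced by environmental filtering of niche optima.  All randomness flows
from a single master seed, so every output is bit-reproducible.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.model import birthdeath
from scipy.special import expit

from phyloflora.phylo_core import Phylogeny
from phyloflora.spatial_stats import SpatialWeights, great_circle_km, _row_standardize

__all__ = [
    "SyntheticConfig",
    "World",
    "simulate_tree",
    "evolve_bm",
    "make_grid_regions",
    "grid_rook_weights",
    "generate_environment",
    "assemble",
    "generate_world",
    "write_world",
]

#: duration, in years, separating the past climate epoch from the present
#: (Last Glacial Maximum to present).
EPOCH_YEARS = 21_000.0

#: floor for the spatial climate gradient (units per km) in the velocity
#: denominator, preventing unbounded velocities on flat surfaces.
GRADIENT_FLOOR = 1e-6

CONTINENT_NAMES = ["NW", "NC", "NE", "SW", "SC", "SE"]


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic world.

    Rates are per lineage per Myr; niche axes are temperature (°C, matched
    against ``T_mean``) and precipitation (mm, matched against ``P_mean``).
    ``rho`` is the autoregressive parameter of the latent climate surfaces,
    ``epoch_shift`` the mean present-minus-past change used for anomalies,
    and ``tolerance`` the half-width of the environmental filter per axis.
    """

    n_tips: int = 500
    birth: float = 0.4
    death: float = 0.1
    # rates for the early-burst trait model below; tip-state sd works out
    # to a few °C / a few hundred mm on the default tree
    bm_sigma2: dict = field(default_factory=lambda: {
        "temperature": 5.0,         # °C² per Myr (initial rate)
        "precipitation": 50_000.0,  # mm² per Myr (initial rate)
    })
    # the ancestral niche sits at the warm, moist end of the gradient
    root_state: dict = field(default_factory=lambda: {
        "temperature": 26.0,
        "precipitation": 1800.0,
    })
    #: exponential decay rate (1/Myr) of the trait-evolution rate through
    #: time; > 0 concentrates niche divergence on deep branches so major
    #: climatic tolerances are clade-structured (phylogenetic niche
    #: conservatism); 0 recovers homogeneous Brownian motion
    conservatism_rate: float = 0.25
    grid_shape: tuple = (12, 12)
    n_subcells: int = 25
    rho: float = 0.8
    epoch_shift: dict = field(default_factory=lambda: {
        "temperature": 5.5,        # °C of warming since the past epoch
        "precipitation": 300.0,    # mm of moistening since the past epoch
    })
    tolerance: dict = field(default_factory=lambda: {
        "temperature": 10.0,
        "precipitation": 1600.0,
    })
    seed: int = 0

    def __post_init__(self):
        if self.birth < 0 or self.death < 0:
            raise ValueError("rates must be non-negative")
        if self.death >= self.birth:
            raise ValueError("death rate must be below birth rate")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must lie in (-1, 1)")
        if any(t <= 0 for t in self.tolerance.values()):
            raise ValueError("tolerances must be positive")


@dataclass
class World:
    config: SyntheticConfig
    tree: Phylogeny
    niches: dict            # axis -> {tip label -> optimum}
    regions: pd.DataFrame   # region_id, row, col, lon, lat, area_km2, continent
    env: pd.DataFrame       # region_id + 13 environment columns
    subcells: dict          # surface name -> (n_regions, n_subcells) array
    assemblages: pd.DataFrame  # long format: region_id, species
    manifest: dict


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


def simulate_tree(n_tips: int, birth: float, death: float, seed: int) -> Phylogeny:
    """Ultrametric birth-death tree conditioned on ``n_tips`` extant tips."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if death >= birth:
        raise ValueError("death rate must be below birth rate")
    tree = birthdeath.birth_death_tree(
        birth_rate=birth,
        death_rate=death,
        num_extant_tips=n_tips,
        rng=random.Random(seed),
        repeat_until_success=True,
    )
    width = max(4, len(str(n_tips)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i:0{width}d}"
    return Phylogeny(tree)


def evolve_bm(tree: Phylogeny, sigma2: float, root_state: float, seed: int) -> dict:
    """Brownian-motion trait evolution along the tree; returns tip states.

    Increments on each branch are Normal(0, sigma2 × branch length), so the
    expected covariance of two tip states is sigma2 times their shared
    root-path length.  ``sigma2 = 0`` returns the root state everywhere.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    rng = np.random.default_rng(seed)
    states = {}
    tips = {}
    for node in tree._tree.preorder_node_iter():
        if node.parent_node is None:
            states[node] = float(root_state)
        else:
            bl = float(node.edge.length)
            states[node] = states[node.parent_node] + rng.normal(0.0, np.sqrt(sigma2 * bl))
        if node.is_leaf():
            tips[node.taxon.label] = states[node]
    return tips


def early_burst_rescale(tree: Phylogeny, rate: float) -> Phylogeny:
    """Rescale branch lengths so evolutionary rate decays through time.

    A branch spanning ages t0→t1 from the root gets effective length
    (e^(−rate·t0) − e^(−rate·t1))/rate, i.e. Brownian change accumulates
    mostly on deep branches.  Running plain Brownian motion on the
    rescaled tree yields clade-structured ("early burst") trait variation
    — the classic generating model for phylogenetic niche conservatism,
    where major climatic tolerances diverge early and are retained within
    clades.  ``rate = 0`` returns the tree unchanged.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if rate == 0:
        return tree
    rescaled = tree.copy()
    t = rescaled._tree
    root_dist = {t.seed_node: 0.0}
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            continue
        t0 = root_dist[node.parent_node]
        t1 = t0 + float(node.edge.length)
        root_dist[node] = t1
        node.edge.length = (np.exp(-rate * t0) - np.exp(-rate * t1)) / rate
    rescaled._idx = None
    return Phylogeny(rescaled._tree)


def make_grid_regions(grid_shape: tuple, seed: int) -> pd.DataFrame:
    """Gridded regions with centroids, log-uniform areas and 6 continents.

    Rows span latitudes −55..70, columns longitudes −165..165.  Areas are
    drawn log-uniformly in [10³, 10⁶] km² so the PD area correction is
    exercised.  Continent labels partition the grid into 2×3 contiguous
    blocks.
    """
    nrow, ncol = grid_shape
    rng = np.random.default_rng(seed)
    lats = np.linspace(-55.0, 70.0, nrow)
    lons = np.linspace(-165.0, 165.0, ncol)
    rows = []
    for r in range(nrow):
        for c in range(ncol):
            block = (r * 2 // nrow) * 3 + (c * 3 // ncol)
            rows.append({
                "region_id": f"r{r * ncol + c:04d}",
                "row": r,
                "col": c,
                "lon": lons[c],
                "lat": lats[r],
                "continent": CONTINENT_NAMES[block],
            })
    df = pd.DataFrame(rows)
    df["area_km2"] = 10 ** rng.uniform(3.0, 6.0, len(df))
    return df


def grid_rook_weights(regions: pd.DataFrame) -> SpatialWeights:
    """Row-standardized rook-adjacency weights on the region grid."""
    n = len(regions)
    raw = np.zeros((n, n))
    pos = {(r, c): i for i, (r, c) in enumerate(zip(regions["row"], regions["col"]))}
    for (r, c), i in pos.items():
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            j = pos.get((r + dr, c + dc))
            if j is not None:
                raw[i, j] = 1.0
    return _row_standardize(raw, list(regions["region_id"]), "rook")


def sar_surface(W: SpatialWeights, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Standardized draw of x = (I − ρW)⁻¹ ε with iid normal ε."""
    if not -1.0 < rho < 1.0:
        raise ValueError(
            f"(I - rho W) is singular or unstable at rho={rho}; need |rho| < 1")
    n = W.n
    eps = rng.standard_normal(n)
    A = np.eye(n) - rho * W.matrix
    try:
        x = np.linalg.solve(A, eps)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"(I - rho W) is singular at rho={rho}") from exc
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def _spatial_gradient(values: np.ndarray, regions: pd.DataFrame,
                      W: SpatialWeights) -> np.ndarray:
    """Mean |Δvalue|/distance over each region's grid neighbours (per km)."""
    lon = regions["lon"].to_numpy()
    lat = regions["lat"].to_numpy()
    link = W.matrix > 0
    D = great_circle_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    grad = np.zeros(len(values))
    for i in range(len(values)):
        nb = np.flatnonzero(link[i])
        if len(nb):
            grad[i] = np.mean(np.abs(values[nb] - values[i]) / D[i, nb])
    return np.maximum(grad, GRADIENT_FLOOR)


def generate_environment(
    regions: pd.DataFrame,
    W: SpatialWeights,
    rho: float,
    epoch_shift: dict,
    n_subcells: int,
    seed: int,
) -> tuple[pd.DataFrame, dict]:
    """The 13-column environment table plus sub-cell surfaces.

    Current-climate surfaces are spatially autocorrelated latent fields
    mapped onto realistic units with a latitudinal temperature gradient;
    anomalies are present minus past (past = present − epoch shift
    surface); velocities divide the temporal rate of change by the local
    spatial gradient (floored); heterogeneity columns are standard
    deviations over each region's sub-cells.
    """
    rng = np.random.default_rng(seed)
    abslat = np.abs(regions["lat"].to_numpy())
    n = len(regions)

    z = {name: sar_surface(W, rho, rng) for name in
         ("t", "toff", "tseas", "p", "pmin", "pseas",
          "tshift", "pshift", "elev", "relief", "relief_p")}

    # regional (non-latitudinal) temperature structure is substantial, so
    # climate retains explanatory signal after spatial filtering
    t_mean = 27.0 - 0.35 * abslat + 4.0 * z["t"]
    t_min = t_mean - (2.0 + 0.22 * abslat + 1.0 * np.abs(z["toff"]))
    t_seas = np.clip(0.8 + 0.16 * abslat + 1.2 * z["tseas"], 0.0, None)
    p_mean = np.exp(7.3 + 0.7 * z["p"] - 0.012 * abslat)
    p_min = p_mean / 12.0 * expit(z["pmin"] - 0.5)
    p_seas = 15.0 + 60.0 * expit(z["pseas"])

    # past epoch: cooler/drier by a shift surface with its own spatial
    # structure (mildly latitude-weighted, dominated by regional variation)
    t_shift = epoch_shift["temperature"] * (0.8 + 0.2 * abslat / 90.0) + 1.8 * z["tshift"]
    p_shift = epoch_shift["precipitation"] * (0.8 + 0.2 * abslat / 90.0) + 120.0 * z["pshift"]
    t_past = t_mean - t_shift
    p_past = np.clip(p_mean - p_shift, 0.0, None)
    t_anom = t_mean - t_past
    p_anom = p_mean - p_past

    t_vel = (np.abs(t_anom) / EPOCH_YEARS) / _spatial_gradient(t_mean, regions, W)
    p_vel = (np.abs(p_anom) / EPOCH_YEARS) / _spatial_gradient(p_mean, regions, W)

    # heterogeneity is topography-driven: sub-cell spread follows the
    # relief surfaces, independent of the climate means
    elev_mean = 200.0 + 500.0 * np.abs(z["elev"])
    relief = 40.0 + 350.0 * np.abs(z["relief"])
    relief_p = 30.0 + 250.0 * np.abs(z["relief_p"])
    elev_sub = elev_mean[:, None] + relief[:, None] * rng.standard_normal((n, n_subcells))
    t_sub = (t_mean[:, None] - 0.0065 * (elev_sub - elev_mean[:, None])
             + 0.3 * rng.standard_normal((n, n_subcells)))
    p_sub = np.clip(p_mean[:, None] + relief_p[:, None] * rng.standard_normal((n, n_subcells)),
                    0.0, None)

    env = pd.DataFrame({
        "region_id": regions["region_id"].to_numpy(),
        "T_mean": t_mean,
        "T_min": t_min,
        "T_seas": t_seas,
        "P_mean": p_mean,
        "P_min": p_min,
        "P_seas": p_seas,
        "T_anom": t_anom,
        "T_vel": t_vel,
        "P_anom": p_anom,
        "P_vel": p_vel,
        "E_sd": elev_sub.std(axis=1, ddof=1),
        "T_sd": t_sub.std(axis=1, ddof=1),
        "P_sd": p_sub.std(axis=1, ddof=1),
    })
    subcells = {"elevation": elev_sub, "temperature": t_sub, "precipitation": p_sub}
    return env, subcells


AXIS_TO_ENV = {"temperature": "T_mean", "precipitation": "P_mean"}


def assemble(niches: dict, env: pd.DataFrame, tolerance: dict) -> pd.DataFrame:
    """Environmental filtering: a species occurs in a region iff its niche
    optimum is within the tolerance of the region's environment on every
    axis.  Deterministic; regions may end up empty."""
    axes = list(niches)
    missing = [a for a in axes if a not in AXIS_TO_ENV]
    if missing:
        raise ValueError(f"unknown niche axes: {missing}")
    species = sorted(niches[axes[0]])
    region_ids = env["region_id"].to_numpy()
    ok = np.ones((len(region_ids), len(species)), dtype=bool)
    for axis in axes:
        opt = np.array([niches[axis][s] for s in species])
        vals = env[AXIS_TO_ENV[axis]].to_numpy()
        ok &= np.abs(opt[None, :] - vals[:, None]) <= tolerance[axis]
    r_idx, s_idx = np.nonzero(ok)
    return pd.DataFrame({
        "region_id": region_ids[r_idx],
        "species": [species[j] for j in s_idx],
    })


def generate_world(config: SyntheticConfig) -> World:
    """Generate one complete synthetic world from the master seed."""
    ss = np.random.SeedSequence(config.seed)
    s_tree, s_bm_t, s_bm_p, s_regions, s_env = (
        _child_seed(c) for c in ss.spawn(5)
    )
    tree = simulate_tree(config.n_tips, config.birth, config.death, s_tree)
    trait_tree = early_burst_rescale(tree, config.conservatism_rate)
    niches = {
        "temperature": evolve_bm(trait_tree, config.bm_sigma2["temperature"],
                                 config.root_state["temperature"], s_bm_t),
        "precipitation": evolve_bm(trait_tree, config.bm_sigma2["precipitation"],
                                   config.root_state["precipitation"], s_bm_p),
    }
    regions = make_grid_regions(config.grid_shape, s_regions)
    W = grid_rook_weights(regions)
    env, subcells = generate_environment(
        regions, W, config.rho, config.epoch_shift, config.n_subcells, s_env
    )
    assemblages = assemble(niches, env, config.tolerance)
    manifest = {"config": asdict(config), "seed": config.seed}
    manifest["config"]["grid_shape"] = list(config.grid_shape)
    return World(config, tree, niches, regions, env, subcells, assemblages, manifest)


def write_world(world: World, outdir) -> dict:
    """Write the world in the formats the pipeline reads; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tree": outdir / "tree.nwk",
        "assemblages": outdir / "assemblages.tsv",
        "regions": outdir / "regions.tsv",
        "environment": outdir / "environment.tsv",
        "manifest": outdir / "manifest.json",
    }
    paths["tree"].write_text(world.tree.to_newick() + "\n")
    world.assemblages.to_csv(paths["assemblages"], sep="\t", index=False)
    world.regions.to_csv(paths["regions"], sep="\t", index=False, float_format="%.10g")
    world.env.to_csv(paths["environment"], sep="\t", index=False, float_format="%.10g")
    paths["manifest"].write_text(json.dumps(world.manifest, indent=2, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
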