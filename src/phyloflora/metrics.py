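"""Phylogenetic community-structure metrics for regional assemblages.

Five metrics are computed per region:

* ``PD_raw`` — Faith's phylogenetic diversity: the summed branch length of
  the union of root-to-tip paths spanning the assemblage.  The root-to-MRCA
  segment is included, which keeps PD defined for single-species regions.
* ``PD`` — PD_raw divided by log10(region area in km²), since PD grows with
  species richness and richness grows with log area.
* ``MPD`` — mean patristic distance over all unordered species pairs.
* ``RPD`` — PD on the observed tree over PD on a comparison tree of
  identical topology whose branch lengths are all one, both trees first
  rescaled to unit total branch length; values above 1 indicate an excess
  of long branches in the assemblage.
* ``PD_ses`` / ``MPD_ses`` — standardized effect sizes of PD and MPD under
  a null drawing equally sized tip sets uniformly (without replacement)
  from the pool of all tree tips.  Positive values mean phylogenetic
  overdispersion, negative values phylogenetic clustering.
"""

from __future__ import annotations

import logging
import math
import warnings
import zlib
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from phyloflora.phylo_core import Phylogeny, PhylogenyError

__all__ = [
    "NullSpec",
    "SESResult",
    "faith_pd",
    "area_corrected_pd",
    "mpd",
    "rpd",
    "ses_metric",
    "null_seed",
    "compute_metric_table",
    "METRIC_COLUMNS",
]

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ["region_id", "richness", "PD_raw", "PD", "MPD", "RPD", "PD_ses", "MPD_ses"]


@dataclass(frozen=True)
class NullSpec:
    """Specification of the tip-randomization null.

    ``monte_carlo`` draws ``n_randomizations`` uniform tip subsets with the
    given seed; ``exhaustive`` enumerates all C(pool, k) subsets and is only
    allowed while that count stays below ``exhaustive_cap``.
    """

    model: str = "uniform"
    n_randomizations: int = 999
    seed: int | None = None
    mode: str = "monte_carlo"
    exhaustive_cap: int = 500_000

    def __post_init__(self):
        if self.model != "uniform":
            raise ValueError(f"unknown null model {self.model!r}")
        if self.mode not in ("monte_carlo", "exhaustive"):
            raise ValueError(f"unknown null mode {self.mode!r}")
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be >= 1")


@dataclass(frozen=True)
class SESResult:
    observed: float
    null_mean: float
    null_sd: float
    ses: float          # NaN when undefined
    reason: str = ""    # non-empty when ses is undefined


def _tip_cols(tree: Phylogeny, tips) -> np.ndarray:
    idx = tree._index()
    cols = []
    for lab in tips:
        j = idx.tip_index.get(lab)
        if j is None:
            raise PhylogenyError(f"unknown tip label {lab!r}")
        cols.append(j)
    if not cols:
        raise PhylogenyError("empty tip set")
    return np.asarray(sorted(set(cols)), dtype=int)


def faith_pd(tree: Phylogeny, tips) -> float:
    """Faith's PD of a tip set (root-inclusive)."""
    idx = tree._index()
    cols = _tip_cols(tree, tips)
    covered = idx.edge_tips[:, cols].any(axis=1)
    return float(idx.branch_lengths[covered].sum())


def area_corrected_pd(pd_value: float, area: float) -> float:
    """PD divided by log10(area in km²).

    Areas at or below 1 km² make the divisor non-positive and raise;
    areas in (1, 10] give a divisor below 1 and trigger a warning.
    """
    if area <= 1.0:
        raise ValueError(f"area {area} km² gives log10(area) <= 0")
    if area <= 10.0:
        warnings.warn(
            f"area {area} km² is at or below 10 km²; the log10 divisor is <= 1",
            stacklevel=2,
        )
    return float(pd_value) / math.log10(area)


def mpd(tree: Phylogeny, tips) -> float:
    """Mean patristic distance over all unordered pairs of the tip set."""
    idx = tree._index()
    cols = _tip_cols(tree, tips)
    k = len(cols)
    if k < 2:
        raise PhylogenyError("MPD requires at least 2 distinct tips")
    D = idx.distance_matrix()
    sub = D[np.ix_(cols, cols)]
    return float(sub.sum() / (k * (k - 1)))


def rpd(tree: Phylogeny, tips) -> float:
    """Relative phylogenetic diversity.

    PD fraction on the observed tree divided by the PD fraction on the
    unit-branch-length comparison tree (identical topology); each fraction
    is that tree's assemblage PD over its total branch length.
    """
    idx = tree._index()
    cols = _tip_cols(tree, tips)
    covered = idx.edge_tips[:, cols].any(axis=1)
    obs = idx.branch_lengths[covered].sum() / idx.branch_lengths.sum()
    comp = covered.sum() / idx.edge_tips.shape[0]
    if comp == 0:
        raise PhylogenyError("comparison-tree PD is zero")
    return float(obs / comp)


# ----------------------------------------------------------------- SES null


def null_seed(seed: int, region_id: str, metric: str) -> int:
    """Stable per-(region, metric) child seed below 2**31.

    Lets a batch run and a standalone :func:`ses_metric` call reproduce the
    identical null draw for the same region.
    """
    h = zlib.crc32(f"{seed}|{region_id}|{metric}".encode())
    return int(h % (2**31 - 1))


def _metric_values_for_draws(idx, draws: np.ndarray, metric: str) -> np.ndarray:
    """Metric value for each row of a (n_draws, k) tip-column matrix."""
    n, k = draws.shape
    S = np.zeros((n, idx.n_tips))
    np.put_along_axis(S, draws, 1.0, axis=1)
    if metric == "PD":
        covered = (S @ idx.edge_tips.T.astype(float)) > 0.5
        return covered @ idx.branch_lengths
    if metric == "MPD":
        D = idx.distance_matrix()
        return ((S @ D) * S).sum(axis=1) / (k * (k - 1))
    raise ValueError(f"unknown metric {metric!r}")


def _observed(tree: Phylogeny, tips, metric: str) -> float:
    return faith_pd(tree, tips) if metric == "PD" else mpd(tree, tips)


def ses_metric(tree: Phylogeny, tips, metric: str, null: NullSpec) -> SESResult:
    """Standardized effect size of PD or MPD under the uniform tip null.

    ses = (observed − null mean) / null sd.  The pool is the full set of
    tree tips; draws keep the observed richness.  When the null has zero
    spread (e.g. the assemblage is the whole pool, or every equal-sized
    subset scores identically) the SES is undefined and reported as NaN
    with a reason, never as an exception.
    """
    idx = tree._index()
    cols = _tip_cols(tree, tips)
    k = len(cols)
    if k < 2:
        raise PhylogenyError("SES requires at least 2 distinct tips")
    observed = _observed(tree, tips, metric)
    pool = idx.n_tips

    if null.mode == "exhaustive":
        n_subsets = math.comb(pool, k)
        if n_subsets > null.exhaustive_cap:
            raise ValueError(
                f"exhaustive null needs {n_subsets} subsets "
                f"(cap {null.exhaustive_cap}); use monte_carlo"
            )
        draws = np.array(list(combinations(range(pool), k)), dtype=int)
        values = _metric_values_for_draws(idx, draws, metric)
        null_mean = float(values.mean())
        null_sd = float(values.std(ddof=0))   # full population of subsets
    else:
        if null.seed is None:
            raise ValueError("monte_carlo null requires a seed")
        rng = np.random.default_rng(null.seed)
        u = rng.random((null.n_randomizations, pool))
        draws = np.argpartition(u, k - 1, axis=1)[:, :k]
        values = _metric_values_for_draws(idx, draws, metric)
        null_mean = float(values.mean())
        null_sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0

    # spreads at floating-point noise level count as degenerate
    if null_sd <= 1e-12 * max(abs(null_mean), 1.0) or not np.isfinite(null_sd):
        return SESResult(observed, null_mean, null_sd, float("nan"),
                         reason="null distribution has zero spread")
    return SESResult(observed, null_mean, null_sd,
                     (observed - null_mean) / null_sd)


# ----------------------------------------------------------- batch metrics


def compute_metric_table(
    tree: Phylogeny,
    assemblages: pd.DataFrame,
    regions: pd.DataFrame,
    null: NullSpec,
) -> pd.DataFrame:
    """Per-region metric table (one row per region, fixed column order).

    ``assemblages`` is long-format with columns ``region_id`` and
    ``species``; ``regions`` must carry ``region_id`` and ``area_km2``.
    Species absent from the tree are dropped (count logged); regions left
    with no matched species are excluded with a warning.  SES columns are
    NaN where undefined (richness < 2 or a degenerate null).
    """
    if null.seed is None:
        raise ValueError("compute_metric_table requires a seeded NullSpec")
    tip_set = set(tree.tip_labels)
    asm = assemblages[["region_id", "species"]].drop_duplicates()
    matched = asm[asm["species"].isin(tip_set)]
    n_dropped = len(asm) - len(matched)
    if n_dropped:
        logger.info("dropped %d assemblage records with species not in tree", n_dropped)

    areas = regions.set_index("region_id")["area_km2"]
    rows = []
    for region_id in regions["region_id"]:
        tips = matched.loc[matched["region_id"] == region_id, "species"].tolist()
        if not tips:
            warnings.warn(f"region {region_id!r} has no species matched to the tree",
                          stacklevel=2)
            continue
        richness = len(tips)
        pd_raw = faith_pd(tree, tips)
        pd_area = area_corrected_pd(pd_raw, float(areas[region_id]))
        row = {
            "region_id": region_id,
            "richness": richness,
            "PD_raw": pd_raw,
            "PD": pd_area,
            "MPD": np.nan,
            "RPD": rpd(tree, tips),
            "PD_ses": np.nan,
            "MPD_ses": np.nan,
        }
        if richness >= 2:
            row["MPD"] = mpd(tree, tips)
            for metric, col in (("PD", "PD_ses"), ("MPD", "MPD_ses")):
                spec = NullSpec(
                    model=null.model,
                    n_randomizations=null.n_randomizations,
                    seed=null_seed(null.seed, str(region_id), metric),
                    mode=null.mode,
                    exhaustive_cap=null.exhaustive_cap,
                )
                row[col] = ses_metric(tree, tips, metric, spec).ses
        rows.append(row)
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)
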