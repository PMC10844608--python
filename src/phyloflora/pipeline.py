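"""Full analysis orchestration: metrics → SAR coefficients → partitions.

The pipeline runs every analysis at the global scope and once per
continent.  Continent membership is taken from the region table, never
re-derived from coordinates; spatial weights are rebuilt inside each scope
so continental models have no cross-continent neighbours.  Missing metric
values (e.g. undefined SES) are removed pairwise per (metric, scope).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from phyloflora import io as pfio
from phyloflora.metrics import NullSpec, compute_metric_table
from phyloflora.spatial_stats import (
    build_weights,
    coefficients_frame,
    standardized_sar_fit,
)
from phyloflora.synthetic_data import SyntheticConfig, generate_world, write_world
from phyloflora.varpart import ENV_COLUMNS, VARIABLE_GROUPS, varpart2, varpart3

__all__ = [
    "AnalysisScope",
    "METRICS",
    "DESIGNS",
    "make_scopes",
    "run_coefficients",
    "run_partition_suite",
    "summarize",
    "run_all",
    "default_config",
]

logger = logging.getLogger(__name__)

METRICS = ["PD", "MPD", "RPD", "PD_ses", "MPD_ses"]

#: the six partition designs run per (scope, metric): three pairwise
#: comparisons of the major variable groups, the full three-set design,
#: and the two current-climate subgroup comparisons.
DESIGNS = [
    ("two_set", ("C", "H")),
    ("two_set", ("C", "V")),
    ("two_set", ("H", "V")),
    ("three_set", ("C", "H", "V")),
    ("two_set", ("T", "P")),
    ("two_set", ("E", "S")),
]


@dataclass
class AnalysisScope:
    """A named subset of regions: ``global`` or ``continent:<name>``."""

    label: str
    region_ids: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.region_ids)


def make_scopes(regions: pd.DataFrame, min_n: int = 17) -> list:
    """Global scope plus one scope per continent label.

    Continental scopes smaller than ``min_n`` regions are skipped with a
    warning, since the SAR fits and 13-predictor partitions need degrees
    of freedom.
    """
    scopes = [AnalysisScope("global", list(regions["region_id"]))]
    for name, grp in regions.groupby("continent", sort=True):
        ids = list(grp["region_id"])
        if len(ids) < min_n:
            warnings.warn(
                f"scope continent:{name} has {len(ids)} regions "
                f"(< {min_n}); skipped", stacklevel=2,
            )
            continue
        scopes.append(AnalysisScope(f"continent:{name}", ids))
    return scopes


def _scope_frame(metric_table, env, regions, scope):
    merged = (metric_table.merge(env, on="region_id")
              .merge(regions[["region_id", "lon", "lat"]], on="region_id"))
    return merged[merged["region_id"].isin(set(scope.region_ids))]


def run_coefficients(
    metric_table: pd.DataFrame,
    env: pd.DataFrame,
    regions: pd.DataFrame,
    scopes: list,
    k: int = 8,
) -> pd.DataFrame:
    """Single-predictor standardized SAR coefficients.

    One row per (metric, variable, scope): 5 × 13 = 65 rows per scope.
    Rows where the metric is undefined or constant within the scope carry
    NaN coefficients; weights are rebuilt from the centroids of the
    regions that survive pairwise deletion for that metric.
    """
    rows = []
    for scope in scopes:
        frame = _scope_frame(metric_table, env, regions, scope)
        weights_cache: dict = {}
        for metric in METRICS:
            sub = frame[np.isfinite(frame[metric])]
            n = len(sub)
            y = sub[metric].to_numpy(dtype=float)
            degenerate = n < 4 or np.ptp(y) == 0
            if not degenerate:
                key = tuple(sub["region_id"])
                if key not in weights_cache:
                    kk = min(k, n - 1)
                    weights_cache[key] = build_weights(
                        sub["region_id"], sub["lon"], sub["lat"], k=kk)
                W = weights_cache[key]
            for variable in ENV_COLUMNS:
                if degenerate:
                    rows.append({"metric": metric, "variable": variable,
                                 "scope": scope.label, "std_coef": np.nan,
                                 "lambda": np.nan, "pseudo_r2": np.nan, "n": n})
                    continue
                x = sub[variable].to_numpy(dtype=float)
                fit = standardized_sar_fit(y, x, W)
                rows.append({"metric": metric, "variable": variable,
                             "scope": scope.label,
                             "std_coef": float(fit.beta[1]),
                             "lambda": fit.lambda_,
                             "pseudo_r2": fit.pseudo_r2, "n": n})
    return coefficients_frame(rows)


def run_partition_suite(
    metric_table: pd.DataFrame,
    env: pd.DataFrame,
    scopes: list,
    regions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """All six variation-partitioning designs per (scope, metric).

    Returns a long table (metric, scope, design, fraction_label, value);
    fractions may be negative and always sum (with the residual) to one.
    """
    if regions is None:
        regions = pd.DataFrame({
            "region_id": metric_table["region_id"],
            "lon": 0.0, "lat": 0.0,
        })
    rows = []
    for scope in scopes:
        frame = _scope_frame(metric_table, env, regions, scope)
        for metric in METRICS:
            sub = frame[np.isfinite(frame[metric])]
            y = sub[metric].to_numpy(dtype=float)
            if len(sub) < len(ENV_COLUMNS) + 2 or np.ptp(y) == 0:
                logger.info("partition skipped for %s in %s (n=%d)",
                            metric, scope.label, len(sub))
                continue
            for kind, names in DESIGNS:
                groups = [VARIABLE_GROUPS[g] for g in names]
                if kind == "two_set":
                    result = varpart2(y, sub, *groups, names=names)
                else:
                    result = varpart3(y, sub, *groups, names=names)
                rows.extend(result.to_rows(metric=metric, scope=scope.label))
    return pd.DataFrame(rows, columns=["metric", "scope", "design",
                                       "fraction_label", "value"])


def summarize(coefficients: pd.DataFrame, partitions: pd.DataFrame) -> dict:
    """Summary tables mirroring the headline aggregations.

    * ``mean_abs_coef`` — per (scope, variable): mean |standardized
      coefficient| across the five metrics.
    * ``continental_mean_coef`` — per (metric, variable): mean coefficient
      across the continental scopes.
    * ``fractions_by_scope`` — per (scope, design, fraction): mean across
      metrics.
    * ``fractions_by_metric`` — per (metric, design, fraction): mean
      across the continental scopes.
    Missing cells are excluded from means, with the contributing count
    reported alongside each average.
    """
    coef = coefficients.dropna(subset=["std_coef"]).copy()
    coef["abs_coef"] = coef["std_coef"].abs()
    mean_abs = (coef.groupby(["scope", "variable"], sort=True)["abs_coef"]
                .agg(mean_abs_coef="mean", n_metrics="count").reset_index())

    cont = coef[coef["scope"].str.startswith("continent:")]
    cont_mean = (cont.groupby(["metric", "variable"], sort=True)["std_coef"]
                 .agg(mean_coef="mean", n_continents="count").reset_index())

    part = partitions.dropna(subset=["value"])
    by_scope = (part.groupby(["scope", "design", "fraction_label"], sort=True)["value"]
                .agg(mean_value="mean", n_metrics="count").reset_index())
    cont_part = part[part["scope"].str.startswith("continent:")]
    by_metric = (cont_part.groupby(["metric", "design", "fraction_label"], sort=True)["value"]
                 .agg(mean_value="mean", n_continents="count").reset_index())

    return {
        "mean_abs_coef": mean_abs,
        "continental_mean_coef": cont_mean,
        "fractions_by_scope": by_scope,
        "fractions_by_metric": by_metric,
    }


# ------------------------------------------------------------------ run-all


def default_config(seed: int = 0, outdir: str = "runs/world") -> dict:
    """Default plain-text run configuration (YAML-serializable)."""
    return {
        "seed": int(seed),
        "outdir": str(outdir),
        "synthetic": {},          # overrides for SyntheticConfig fields
        "weights": {"k": 8},
        "null": {"n_randomizations": 999},
        "scope_min_n": 17,
    }


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path) -> dict:
    cfg = default_config()
    user = yaml.safe_load(Path(path).read_text()) or {}
    # YAML reads the bare key `null:` as None; map it back to the section name
    if None in user:
        user["null"] = user.pop(None)
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def run_all(config: dict, outdir=None) -> dict:
    """Simulate a world and run the complete analysis; write all tables.

    Returns the output paths.  Every run writes a manifest carrying the
    configuration and its hash, so reruns are fully reproducible.
    """
    outdir = Path(outdir or config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)

    syn = SyntheticConfig(seed=config["seed"], **config.get("synthetic", {}))
    world = generate_world(syn)
    input_paths = write_world(world, outdir / "inputs")

    null = NullSpec(n_randomizations=config["null"]["n_randomizations"],
                    seed=config["seed"])
    metric_table = compute_metric_table(world.tree, world.assemblages,
                                        world.regions, null)
    scopes = make_scopes(world.regions, min_n=config["scope_min_n"])
    coefficients = run_coefficients(metric_table, world.env, world.regions,
                                    scopes, k=config["weights"]["k"])
    partitions = run_partition_suite(metric_table, world.env, scopes,
                                     regions=world.regions)
    summaries = summarize(coefficients, partitions)

    paths = dict(input_paths)
    for name, df in [("metric_table", metric_table),
                     ("coefficients", coefficients),
                     ("partitions", partitions)]:
        paths[name] = str(outdir / f"{name}.tsv")
        pfio.write_table(df, paths[name])
    for name, df in summaries.items():
        paths[name] = str(outdir / f"summary_{name}.tsv")
        pfio.write_table(df, paths[name])

    manifest = {"config": config, "config_hash": _config_hash(config),
                "outputs": sorted(paths)}
    (outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str))
    paths["run_manifest"] = str(outdir / "run_manifest.json")
    return paths
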