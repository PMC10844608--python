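"""Readers and writers for the delimited input/output tables.

All tables are tab-separated text.  The assemblage table is accepted either
long-format (columns ``region_id, species``) or as a wide 0/1 incidence
matrix with regions as rows; it is always normalized to long format.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from phyloflora.phylo_core import Phylogeny
from phyloflora.varpart import ENV_COLUMNS

__all__ = [
    "read_tree",
    "read_assemblage_table",
    "read_region_table",
    "read_environment_table",
    "write_table",
]

REGION_COLUMNS = ["region_id", "area_km2", "continent", "lon", "lat"]


def read_tree(path) -> Phylogeny:
    return Phylogeny.from_newick(Path(path).read_text())


def read_assemblage_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if {"region_id", "species"}.issubset(df.columns):
        return df[["region_id", "species"]].astype(str)
    # wide incidence matrix: first column region ids, remaining species 0/1
    region_col = df.columns[0]
    long = df.melt(id_vars=region_col, var_name="species", value_name="present")
    long = long[long["present"].astype(float) > 0]
    return (long.rename(columns={region_col: "region_id"})
            [["region_id", "species"]].astype(str).reset_index(drop=True))


def read_region_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REGION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"region table missing columns: {missing}")
    df["region_id"] = df["region_id"].astype(str)
    return df


def read_environment_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ENV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"environment table missing columns: {missing}")
    df["region_id"] = df["region_id"].astype(str)
    return df[["region_id"] + ENV_COLUMNS]


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
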