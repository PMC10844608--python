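"""Variation partitioning of a response among predictor sets.

Fractions are inclusion–exclusion combinations of adjusted R² values from
ordinary least-squares fits of the response on each union of predictor
sets.  Adjusted R² corrects each component model for its own predictor
count, so individual fractions can legitimately be negative; they are
reported as computed, never truncated at zero.  All members of a group
always enter the model together — there is no within-group selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VARIABLE_GROUPS",
    "PartitionResult",
    "adjusted_r2",
    "ols_adjusted_r2",
    "varpart2",
    "varpart3",
]

# Environmental variable groups: C current climate, H historical climate
# change since the Last Glacial Maximum, V within-region heterogeneity;
# plus the current-climate subgroups T/P (temperature- vs precipitation-
# related) and E/S (extremes vs seasonality).
VARIABLE_GROUPS: dict = {
    "C": ["T_mean", "T_min", "T_seas", "P_mean", "P_min", "P_seas"],
    "H": ["T_anom", "T_vel", "P_anom", "P_vel"],
    "V": ["E_sd", "T_sd", "P_sd"],
    "T": ["T_mean", "T_min", "T_seas"],
    "P": ["P_mean", "P_min", "P_seas"],
    "E": ["T_min", "P_min"],
    "S": ["T_seas", "P_seas"],
}

ENV_COLUMNS = VARIABLE_GROUPS["C"] + VARIABLE_GROUPS["H"] + VARIABLE_GROUPS["V"]


@dataclass
class PartitionResult:
    """Named adjusted-R² fractions of a 2- or 3-set partition.

    The fractions (excluding ``residual``) sum to the adjusted R² of the
    full-union model; ``residual`` is one minus that value.
    """

    design: str                  # "two_set" or "three_set"
    groups: tuple
    fractions: dict              # label -> value; may be negative
    residual: float

    @property
    def total_explained(self) -> float:
        return float(sum(self.fractions.values()))

    def to_rows(self, metric: str = "", scope: str = "", design_label: str | None = None):
        label = design_label or "|".join(self.groups)
        rows = [
            {"metric": metric, "scope": scope, "design": label,
             "fraction_label": k, "value": v}
            for k, v in self.fractions.items()
        ]
        rows.append({"metric": metric, "scope": scope, "design": label,
                     "fraction_label": "residual", "value": self.residual})
        return rows


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted coefficient of determination 1 − (1 − R²)(n − 1)/(n − p − 1)."""
    if not 0.0 <= r2 <= 1.0:
        raise ValueError(f"r2 must be in [0, 1], got {r2}")
    if n <= p + 1:
        raise ValueError(f"need n >= p + 2 (n={n}, p={p})")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def ols_adjusted_r2(y: np.ndarray, X: np.ndarray) -> float:
    """Adjusted R² of an OLS fit with intercept."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    Xd = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    resid = y - Xd @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise ValueError("constant response")
    r2 = 1.0 - float(resid @ resid) / tss
    return adjusted_r2(min(max(r2, 0.0), 1.0), n, p)


def _columns(table: pd.DataFrame, cols) -> np.ndarray:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"missing predictor columns: {missing}")
    return table[list(cols)].to_numpy(dtype=float)


def varpart2(
    y,
    table: pd.DataFrame,
    group1,
    group2,
    names: tuple = ("X1", "X2"),
    r2_func=ols_adjusted_r2,
) -> PartitionResult:
    """Two-set partition: pure fractions of each set plus their overlap.

    With A = adjR²(X1), B = adjR²(X2), AB = adjR²(X1 ∪ X2):
    pure1 = AB − B, pure2 = AB − A, shared = A + B − AB, residual = 1 − AB.
    ``r2_func`` defaults to the OLS adjusted R²; an alternative (e.g. a SAR
    trend pseudo-R²) may be passed for sensitivity analyses.
    """
    y = np.asarray(y, dtype=float)
    g1, g2 = list(group1), list(group2)
    a = r2_func(y, _columns(table, g1))
    b = r2_func(y, _columns(table, g2))
    union = list(dict.fromkeys(g1 + g2))
    ab = r2_func(y, _columns(table, union))
    n1, n2 = names
    fractions = {
        f"pure_{n1}": ab - b,
        f"pure_{n2}": ab - a,
        "shared": a + b - ab,
    }
    return PartitionResult("two_set", (n1, n2), fractions, 1.0 - ab)


def varpart3(
    y,
    table: pd.DataFrame,
    group1,
    group2,
    group3,
    names: tuple = ("X1", "X2", "X3"),
    r2_func=ols_adjusted_r2,
) -> PartitionResult:
    """Three-set partition: 3 pure, 3 pairwise-shared and 1 triple-shared
    fraction from adjusted R² of the 7 union models."""
    y = np.asarray(y, dtype=float)
    gs = [list(group1), list(group2), list(group3)]

    def fit(*parts):
        union = list(dict.fromkeys(sum(parts, [])))
        return r2_func(y, _columns(table, union))

    a1, a2, a3 = fit(gs[0]), fit(gs[1]), fit(gs[2])
    a12, a13, a23 = fit(gs[0], gs[1]), fit(gs[0], gs[2]), fit(gs[1], gs[2])
    a123 = fit(gs[0], gs[1], gs[2])

    pure1 = a123 - a23
    pure2 = a123 - a13
    pure3 = a123 - a12
    shared12 = a123 - a3 - pure1 - pure2
    shared13 = a123 - a2 - pure1 - pure3
    shared23 = a123 - a1 - pure2 - pure3
    shared123 = a123 - pure1 - pure2 - pure3 - shared12 - shared13 - shared23

    n1, n2, n3 = names
    fractions = {
        f"pure_{n1}": pure1,
        f"pure_{n2}": pure2,
        f"pure_{n3}": pure3,
        f"shared_{n1}{n2}": shared12,
        f"shared_{n1}{n3}": shared13,
        f"shared_{n2}{n3}": shared23,
        f"shared_{n1}{n2}{n3}": shared123,
    }
    return PartitionResult("three_set", (n1, n2, n3), fractions, 1.0 - a123)
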