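"""Spatial weights, Moran's I and maximum-likelihood SAR error models.

The SAR error model is ``y = Xβ + u`` with ``u = λWu + ε`` and iid normal
ε.  λ is estimated by profile likelihood: for each candidate λ the data are
filtered with (I − λW), β comes from OLS on the filtered data, and the
log-likelihood adds the Jacobian term log|det(I − λW)| evaluated from the
(possibly complex) eigenvalues of W.  The reported ``pseudo_r2`` is
1 − RSS(Xβ̂)/TSS(y), i.e. based on the non-spatial trend predictions only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

__all__ = [
    "SpatialWeights",
    "SarFit",
    "great_circle_km",
    "build_weights",
    "morans_i",
    "sar_error_fit",
    "sar_profile_loglik",
    "standardized_sar",
]

EARTH_RADIUS_KM = 6371.0088


def great_circle_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Haversine great-circle distance in km (inputs in degrees, broadcast)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass
class SpatialWeights:
    """Row-standardized spatial weights among region centroids.

    ``matrix`` has a zero diagonal and every non-empty row sums to one.
    Regions without any neighbour (possible under a distance threshold)
    are listed in ``islands`` and keep an all-zero row.
    """

    matrix: np.ndarray
    ids: list
    scheme: str
    islands: list = field(default_factory=list)
    _eigvals: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.ids)

    def eigenvalues(self) -> np.ndarray:
        """Eigenvalues of W (cached; used for the SAR Jacobian and λ bounds)."""
        if self._eigvals is None:
            self._eigvals = linalg.eigvals(self.matrix)
        return self._eigvals

    def subset(self, ids) -> "SpatialWeights":
        pos = {r: i for i, r in enumerate(self.ids)}
        take = [pos[r] for r in ids]
        sub = self.matrix[np.ix_(take, take)]
        return _row_standardize(sub, list(ids), self.scheme + "|subset")


def _row_standardize(raw: np.ndarray, ids: list, scheme: str) -> SpatialWeights:
    np.fill_diagonal(raw, 0.0)
    sums = raw.sum(axis=1)
    islands = [ids[i] for i in np.flatnonzero(sums == 0)]
    W = np.divide(raw, np.where(sums == 0, 1.0, sums)[:, None])
    return SpatialWeights(W, list(ids), scheme, islands)


def build_weights(
    ids,
    lon,
    lat,
    k: int | None = 8,
    threshold_km: float | None = None,
) -> SpatialWeights:
    """k-nearest-neighbour (default k=8) or distance-threshold weights.

    Distances are great-circle km between centroids.  kNN links may be
    asymmetric; ties in distance are broken deterministically by position
    in the supplied id order.  The result is row-standardized.
    """
    ids = list(ids)
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 regions")
    if np.any(np.abs(lon) > 180) or np.any(np.abs(lat) > 90):
        raise ValueError("coordinates out of range [-180,180]x[-90,90]")
    D = great_circle_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    raw = np.zeros((n, n))
    if threshold_km is not None:
        raw[(D <= threshold_km)] = 1.0
        np.fill_diagonal(raw, 0.0)
        scheme = f"threshold:{threshold_km}km"
    else:
        if k is None or not (1 <= k <= n - 1):
            raise ValueError(f"k must be in [1, {n - 1}]")
        order = np.arange(n)
        for i in range(n):
            cand = np.delete(order, i)
            # stable tie-break: sort by (distance, position in id order)
            nearest = cand[np.lexsort((cand, D[i, cand]))][:k]
            raw[i, nearest] = 1.0
        scheme = f"knn:{k}"
    return _row_standardize(raw, ids, scheme)


def morans_i(values, W: SpatialWeights) -> float:
    """Moran's I spatial autocorrelation statistic.

    Expected value under no autocorrelation is −1/(n−1).  Constant input
    (zero variance) raises, as the statistic is then undefined.
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values")
    z = x - x.mean()
    denom = (z**2).sum()
    if denom == 0:
        raise ValueError("zero variance in values; Moran's I undefined")
    s0 = W.matrix.sum()
    if s0 == 0:
        raise ValueError("weights matrix has no links")
    return float(len(x) / s0 * (z @ W.matrix @ z) / denom)


# ---------------------------------------------------------------- SAR error


@dataclass
class SarFit:
    beta: np.ndarray          # intercept first
    beta_se: np.ndarray
    lambda_: float
    log_likelihood: float
    pseudo_r2: float          # 1 - RSS(trend)/TSS
    n: int
    p: int                    # predictors excluding intercept
    converged: bool
    names: list


def _design(X, names):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1:
        X = X.T
    n = X.shape[0]
    Xd = np.column_stack([np.ones(n), X])
    if names is None:
        names = [f"x{j + 1}" for j in range(X.shape[1])]
    return Xd, ["const"] + list(names)


def _check_rank(Xd, names):
    rank = np.linalg.matrix_rank(Xd)
    if rank < Xd.shape[1]:
        # identify offending columns by incremental rank
        bad, cols = [], Xd[:, :1]
        for j in range(1, Xd.shape[1]):
            trial = np.column_stack([cols, Xd[:, j]])
            if np.linalg.matrix_rank(trial) == cols.shape[1]:
                bad.append(names[j])
            else:
                cols = trial
        raise np.linalg.LinAlgError(f"design matrix rank deficient; collinear: {bad}")


def _log_jacobian(lam: float, eigvals: np.ndarray) -> float:
    """log|det(I − λW)| from the eigenvalues of W."""
    vals = 1.0 - lam * eigvals
    mods = np.abs(vals)
    if np.any(mods <= 0):
        return -np.inf
    return float(np.sum(np.log(mods)))


def _concentrated(lam, y, Xd, W, eigvals):
    """Profile log-likelihood and the GLS pieces at a fixed λ."""
    A = np.eye(len(y)) - lam * W
    ys, Xs = A @ y, A @ Xd
    beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    resid = ys - Xs @ beta
    n = len(y)
    sigma2 = float(resid @ resid) / n
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    ll = (
        -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        + _log_jacobian(lam, eigvals)
    )
    return ll, beta, Xs, sigma2


def sar_profile_loglik(y, X, W: SpatialWeights, lam: float, names=None) -> float:
    """Profile log-likelihood of the SAR error model at a fixed λ."""
    y = np.asarray(y, dtype=float)
    Xd, _ = _design(X, names)
    return _concentrated(lam, y, Xd, W.matrix, W.eigenvalues())[0]


def lambda_bounds(W: SpatialWeights, shrink: float = 1e-6) -> tuple[float, float]:
    """Open λ interval (1/e_min, 1/e_max) from W's real eigenvalues."""
    ev = W.eigenvalues()
    real = ev.real[np.abs(ev.imag) < 1e-9]
    neg = real[real < -1e-12]
    pos = real[real > 1e-12]
    lo = 1.0 / neg.min() if len(neg) else -1.0
    hi = 1.0 / pos.max() if len(pos) else 1.0
    return lo + shrink * max(abs(lo), 1.0), hi - shrink * max(abs(hi), 1.0)


def sar_error_fit(y, X, W: SpatialWeights, names=None) -> SarFit:
    """Maximum-likelihood fit of the SAR error model.

    λ is found by bounded scalar minimization of the negative profile
    likelihood over the open eigenvalue interval; β is the GLS estimate at
    λ̂.  An all-zero W collapses the model to OLS with λ = 0.
    """
    y = np.asarray(y, dtype=float)
    Xd, names = _design(X, names)
    n, pplus1 = Xd.shape
    if n <= pplus1 + 1:
        raise ValueError(f"need n > p + 2 (n={n}, p={pplus1 - 1})")
    _check_rank(Xd, names)

    Wm = W.matrix
    if not np.any(Wm):
        lam_hat, converged = 0.0, True
        eigvals = np.zeros(n)
    else:
        eigvals = W.eigenvalues()
        lo, hi = lambda_bounds(W)
        res = optimize.minimize_scalar(
            lambda lam: -_concentrated(lam, y, Xd, Wm, eigvals)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        lam_hat = float(res.x)
        converged = bool(res.success)

    ll, beta, Xs, sigma2 = _concentrated(lam_hat, y, Xd, Wm, eigvals)
    XtX_inv = np.linalg.pinv(Xs.T @ Xs)
    beta_se = np.sqrt(np.clip(np.diag(XtX_inv) * sigma2 * n / (n - pplus1), 0, None))

    trend = Xd @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    rss = float(((y - trend) ** 2).sum())
    pseudo_r2 = 1.0 - rss / tss if tss > 0 else np.nan
    return SarFit(
        beta=beta,
        beta_se=beta_se,
        lambda_=lam_hat,
        log_likelihood=float(ll),
        pseudo_r2=pseudo_r2,
        n=n,
        p=pplus1 - 1,
        converged=converged,
        names=names,
    )


def standardized_sar_fit(y, x, W: SpatialWeights) -> SarFit:
    """SAR error fit of a single predictor with both variables z-scored.

    Standardization uses the sample standard deviation (n−1 denominator),
    making the slope invariant to affine rescaling of either variable.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    sy, sx = y.std(ddof=1), x.std(ddof=1)
    if sy == 0 or sx == 0:
        raise ValueError("constant input; standardized coefficient undefined")
    yz = (y - y.mean()) / sy
    xz = (x - x.mean()) / sx
    return sar_error_fit(yz, xz[:, None], W, names=["x"])


def standardized_sar(y, x, W: SpatialWeights) -> float:
    """Standardized SAR slope of a single predictor (see
    :func:`standardized_sar_fit`)."""
    return float(standardized_sar_fit(y, x, W).beta[1])


def append_coefficient_row(table: list, metric: str, variable: str, scope: str,
                           fit: SarFit | None) -> None:
    """Append one row of the long-format coefficients table."""
    if fit is None:
        table.append({"metric": metric, "variable": variable, "scope": scope,
                      "std_coef": np.nan, "lambda": np.nan,
                      "pseudo_r2": np.nan, "n": 0})
    else:
        table.append({"metric": metric, "variable": variable, "scope": scope,
                      "std_coef": float(fit.beta[1]), "lambda": fit.lambda_,
                      "pseudo_r2": fit.pseudo_r2, "n": fit.n})


def coefficients_frame(rows: list) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["metric", "variable", "scope",
                                       "std_coef", "lambda", "pseudo_r2", "n"])
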