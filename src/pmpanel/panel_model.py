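"""Quasi-Poisson rate regression with offsets and cluster-robust variance.

The admission model is a log-linear rate model

    log E[count] = b0 + b1 * exposure + b' Z + log(beneficiaries)

with variance ``phi * mu`` (quasi-Poisson): point estimates equal Poisson
maximum likelihood; the dispersion ``phi`` only rescales model-based standard
errors.  Autocorrelation of a ZIP code's counts across years is handled with
a CR0 cluster-robust sandwich, clustered on ZIP by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

from .constants import COVARIATES

__all__ = [
    "GLMFit",
    "RateRatioEstimate",
    "build_design",
    "fit_quasipoisson",
    "rr_per_delta",
    "restrict_panel",
]

Z975 = 1.96  # conventional 95% Wald multiplier


@dataclass
class GLMFit:
    """A converged quasi-Poisson fit and both covariance estimates."""

    params: pd.Series
    dispersion: float
    cov_model: pd.DataFrame
    cov_cluster: pd.DataFrame
    n_obs: int
    n_clusters: int
    converged: bool
    outcome: str
    exposure: str | None
    covariates: tuple
    offset: str

    def se(self, name: str, robust: bool = True) -> float:
        cov = self.cov_cluster if robust else self.cov_model
        return float(np.sqrt(cov.loc[name, name]))


@dataclass
class RateRatioEstimate:
    """Rate ratio per ``delta`` units of exposure with a 95% Wald CI."""

    rr: float
    ci_low: float
    ci_high: float
    delta: float
    outcome: str
    exposure: str

    @property
    def pct_increase(self) -> float:
        """(RR - 1) * 100, the percent increase in admission rate."""
        return (self.rr - 1.0) * 100.0


def build_design(
    panel: pd.DataFrame,
    exposure: str | Sequence[str] | None,
    covariates: Sequence[str] = COVARIATES,
    year_indicators: bool = True,
) -> pd.DataFrame:
    """Design matrix: intercept, exposure column(s), covariates, year dummies."""
    cols = [pd.Series(1.0, index=panel.index, name="intercept")]
    if exposure is not None:
        names = [exposure] if isinstance(exposure, str) else list(exposure)
        for name in names:
            cols.append(panel[name].astype(float))
    for c in covariates:
        cols.append(panel[c].astype(float))
    X = pd.concat(cols, axis=1)
    if year_indicators and panel["year"].nunique() > 1:
        dummies = pd.get_dummies(
            panel["year"].astype(int), prefix="year", drop_first=True, dtype=float
        )
        X = pd.concat([X, dummies], axis=1)
    return X


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    norm = arr / np.maximum(np.linalg.norm(arr, axis=0), 1e-300)
    rank = np.linalg.matrix_rank(norm)
    if rank < X.shape[1]:
        # name the columns involved via pivoted QR
        _, _, piv = scipy.linalg.qr(norm, pivoting=True)
        dep = [X.columns[piv[i]] for i in range(rank, X.shape[1])]
        raise ValueError(f"singular design; collinear columns: {dep}")


def _cluster_sandwich(
    X: np.ndarray, y: np.ndarray, mu: np.ndarray, groups: np.ndarray
) -> np.ndarray:
    """CR0 sandwich for the Poisson score, clustered on ``groups``.

    bread = (X' diag(mu) X)^-1, meat = sum_g s_g s_g' with
    s_g = X_g'(y_g - mu_g).  The quasi-Poisson scale cancels.
    """
    bread = np.linalg.inv(X.T @ (X * mu[:, None]))
    resid = y - mu
    df = pd.DataFrame(X * resid[:, None])
    sums = df.groupby(groups).sum().to_numpy()
    meat = sums.T @ sums
    return bread @ meat @ bread


def fit_quasipoisson(
    panel: pd.DataFrame,
    outcome: str,
    exposure: str | Sequence[str] | None = "pm25",
    covariates: Sequence[str] = COVARIATES,
    offset: str = "beneficiaries",
    cluster_by: str = "zip_id",
    year_indicators: bool = True,
    robust: str = "cluster",
    phi_method: str = "pearson",
) -> GLMFit:
    """Fit the quasi-Poisson rate model by IRLS.

    ``offset`` names the person-time column; its log enters with coefficient
    fixed at one.  ``robust`` is "cluster" (CR0 on ``cluster_by``) or "hc0"
    (heteroskedasticity-only sandwich).  Dispersion is the Pearson
    chi-square over residual degrees of freedom by default
    (``phi_method="deviance"`` uses the scaled deviance instead).
    """
    y = panel[f"count_{outcome}"] if f"count_{outcome}" in panel else panel[outcome]
    y = y.to_numpy(dtype=float)
    if (y < 0).any() or not np.allclose(y, np.rint(y)):
        raise ValueError("counts must be non-negative integers")
    off = panel[offset].to_numpy(dtype=float)
    if (off <= 0).any():
        raise ValueError("offset must be positive")
    groups = panel[cluster_by].to_numpy()
    n_clusters = len(pd.unique(groups))
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters for a cluster-robust fit")

    Xdf = build_design(panel, exposure, covariates, year_indicators)
    _check_rank(Xdf)
    X = Xdf.to_numpy(dtype=float)

    model = sm.GLM(y, X, family=sm.families.Poisson(), offset=np.log(off))
    res = model.fit(maxiter=100, tol=1e-10)
    if not res.converged:
        raise RuntimeError(
            f"IRLS did not converge in {res.fit_history['iteration']} iterations; "
            f"deviance trace: {res.fit_history.get('deviance', [])[-5:]}"
        )
    mu = res.mu
    df_resid = len(y) - X.shape[1]
    if phi_method == "pearson":
        phi = float(np.sum((y - mu) ** 2 / mu) / df_resid)
    elif phi_method == "deviance":
        phi = float(res.deviance / df_resid)
    else:
        raise ValueError(f"unknown phi_method {phi_method!r}")

    bread = np.linalg.inv(X.T @ (X * mu[:, None]))
    cov_model = phi * bread
    if robust == "cluster":
        cov_rob = _cluster_sandwich(X, y, mu, groups)
    elif robust == "hc0":
        s = X * (y - mu)[:, None]
        cov_rob = bread @ (s.T @ s) @ bread
    else:
        raise ValueError(f"unknown robust option {robust!r}")

    names = list(Xdf.columns)
    return GLMFit(
        params=pd.Series(res.params, index=names),
        dispersion=phi,
        cov_model=pd.DataFrame(cov_model, index=names, columns=names),
        cov_cluster=pd.DataFrame(cov_rob, index=names, columns=names),
        n_obs=len(y),
        n_clusters=n_clusters,
        converged=True,
        outcome=outcome,
        exposure=exposure if isinstance(exposure, str) else None,
        covariates=tuple(covariates),
        offset=offset,
    )


def rr_per_delta(
    fit: GLMFit,
    exposure: str | None = None,
    delta: float = 3.7,
    robust: bool = True,
) -> RateRatioEstimate:
    """Rate ratio (with 95% Wald CI) per ``delta`` exposure units."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    name = exposure or fit.exposure
    if name is None or name not in fit.params.index:
        raise KeyError(f"exposure {name!r} not in fit")
    b = float(fit.params[name])
    se = fit.se(name, robust=robust)
    return RateRatioEstimate(
        rr=float(np.exp(b * delta)),
        ci_low=float(np.exp((b - Z975 * se) * delta)),
        ci_high=float(np.exp((b + Z975 * se) * delta)),
        delta=delta,
        outcome=fit.outcome,
        exposure=name,
    )


def restrict_panel(panel: pd.DataFrame, predicate) -> pd.DataFrame:
    """Subset a panel by a row predicate, e.g. ``lambda d: d.pm25 <= 9``.

    The low-exposure sensitivity analysis keeps zip-years with PM2.5 at or
    below 9 µg/m³ (inclusive).  An empty result is an error: nothing is
    fittable.
    """
    mask = predicate(panel)
    out = panel.loc[mask].reset_index(drop=True)
    if out.empty:
        raise ValueError("restriction removed every row")
    return out
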