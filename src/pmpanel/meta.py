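"""Mutually adjusted stratum regressions and random-effects pooling.

Within each stratum, a single quasi-Poisson model includes all identified
source factors simultaneously (per-SD scale), the covariates, year
indicators and the person-time offset; cluster-robust SEs are taken per
source.  Per-source effects are then pooled across strata with
DerSimonian-Laird random-effects meta-analysis:

    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)),  w_i = 1/se_i^2
    pooled = sum w*_i y_i / sum w*_i,  w*_i = 1/(se_i^2 + tau^2)

Sources absent from a stratum simply contribute no record; the number of
contributing strata is reported per source.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from .constants import COVARIATES, UNASSIGNED
from .panel_model import Z975, fit_quasipoisson
from .sources import Apportionment

__all__ = [
    "StratumEffect",
    "PooledEffect",
    "fit_stratum_models",
    "pool_random_effects",
    "pool_all",
]


@dataclass
class StratumEffect:
    stratum: str
    source: str
    outcome: str
    log_rr: float      # per SD of source-specific mass
    se: float          # cluster-robust
    n_obs: int


@dataclass
class PooledEffect:
    source: str
    outcome: str
    log_rr: float
    ci_low: float      # log scale
    ci_high: float
    tau2: float
    k_strata: int

    @property
    def rr(self) -> float:
        return float(np.exp(self.log_rr))

    @property
    def pct_increase(self) -> float:
        return (self.rr - 1.0) * 100.0

    @property
    def rr_ci(self) -> tuple:
        return (float(np.exp(self.ci_low)), float(np.exp(self.ci_high)))


def fit_stratum_models(
    panel: pd.DataFrame,
    apportionment: Apportionment,
    outcome: str,
    covariates: Sequence[str] = COVARIATES,
    offset: str = "beneficiaries",
    include_unassigned: bool = True,
    max_factor_corr: float = 0.99,
) -> list[StratumEffect]:
    """One mutually adjusted quasi-Poisson fit per stratum.

    All factors (optionally including unlabeled ones) enter the design
    together; effects are reported only for labeled sources.  Near-duplicate
    factor exposures (|r| > ``max_factor_corr``) are an error.
    """
    effects: list[StratumEffect] = []
    for stratum, model in apportionment.models.items():
        scaled = model.scaled.dropna(axis=1, how="all")
        cols = list(scaled.columns)
        labels = {
            f"factor_{j}": lab
            for j, lab in enumerate(model.labels)
            if f"factor_{j}" in cols
        }
        if not include_unassigned:
            cols = [c for c in cols if labels.get(c, UNASSIGNED) != UNASSIGNED]
        if len(cols) < 2:
            warnings.warn(f"stratum {stratum}: fewer than 2 source factors")
        corr = scaled[cols].corr().abs()
        for i, a in enumerate(cols):
            for b in cols[i + 1 :]:
                if corr.loc[a, b] > max_factor_corr:
                    raise ValueError(
                        f"stratum {stratum}: factors {a} and {b} nearly "
                        f"collinear (|r|={corr.loc[a, b]:.4f})"
                    )
        sub = panel.loc[model.index].copy()
        for c in cols:
            sub[c] = scaled[c].to_numpy()
        fit = fit_quasipoisson(
            sub, outcome, exposure=cols, covariates=covariates, offset=offset
        )
        for c in cols:
            lab = labels.get(c, UNASSIGNED)
            if lab == UNASSIGNED:
                continue
            effects.append(
                StratumEffect(
                    stratum=stratum,
                    source=lab,
                    outcome=outcome,
                    log_rr=float(fit.params[c]),
                    se=fit.se(c),
                    n_obs=fit.n_obs,
                )
            )
    return effects


def _reml_tau2(y: np.ndarray, se: np.ndarray) -> float:
    """Restricted maximum-likelihood tau^2 (1-D bounded search)."""
    from scipy.optimize import minimize_scalar

    def neg_restricted_ll(tau2):
        v = se**2 + tau2
        w = 1.0 / v
        mu = np.sum(w * y) / np.sum(w)
        return 0.5 * (
            np.sum(np.log(v)) + np.log(np.sum(w)) + np.sum(w * (y - mu) ** 2)
        )

    hi = max(float(np.var(y)), float(np.max(se) ** 2)) * 10 + 1e-8
    res = minimize_scalar(neg_restricted_ll, bounds=(0.0, hi), method="bounded")
    return float(res.x) if res.fun < neg_restricted_ll(0.0) else 0.0


def pool_random_effects(
    effects: Sequence[StratumEffect], method: str = "dl"
) -> PooledEffect:
    """Random-effects pooling of one source/outcome across strata.

    ``method`` selects the between-stratum variance estimator:
    DerSimonian-Laird moments (``"dl"``, the default) or ``"reml"``.
    """
    if len(effects) == 0:
        raise ValueError("no effects to pool")
    sources = {e.source for e in effects}
    outcomes = {e.outcome for e in effects}
    if len(sources) > 1 or len(outcomes) > 1:
        raise ValueError("pool one (source, outcome) at a time")
    y = np.array([e.log_rr for e in effects], dtype=float)
    se = np.array([e.se for e in effects], dtype=float)
    if (se <= 0).any():
        raise ValueError("standard errors must be positive")
    k = len(y)
    if k == 1:
        warnings.warn("single stratum: pass-through, no pooling")
        return PooledEffect(
            source=effects[0].source,
            outcome=effects[0].outcome,
            log_rr=float(y[0]),
            ci_low=float(y[0] - Z975 * se[0]),
            ci_high=float(y[0] + Z975 * se[0]),
            tau2=0.0,
            k_strata=1,
        )
    if method == "dl":
        w = 1.0 / se**2
        ybar = float(np.sum(w * y) / np.sum(w))
        Q = float(np.sum(w * (y - ybar) ** 2))
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (Q - (k - 1)) / denom)
    elif method == "reml":
        tau2 = _reml_tau2(y, se)
    else:
        raise ValueError(f"unknown pooling method {method!r}")
    ws = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(ws * y) / np.sum(ws))
    se_p = float(np.sqrt(1.0 / np.sum(ws)))
    return PooledEffect(
        source=effects[0].source,
        outcome=effects[0].outcome,
        log_rr=pooled,
        ci_low=pooled - Z975 * se_p,
        ci_high=pooled + Z975 * se_p,
        tau2=float(tau2),
        k_strata=k,
    )


def pool_all(effects: Sequence[StratumEffect]) -> pd.DataFrame:
    """Pool every (source, outcome) pair; one row per pooled effect."""
    rows = []
    keys = sorted({(e.source, e.outcome) for e in effects})
    for source, outcome in keys:
        sel = [e for e in effects if e.source == source and e.outcome == outcome]
        p = pool_random_effects(sel)
        rows.append(
            {
                "source": source,
                "outcome": outcome,
                "rr": p.rr,
                "rr_low": p.rr_ci[0],
                "rr_high": p.rr_ci[1],
                "pct_increase": p.pct_increase,
                "tau2": p.tau2,
                "k_strata": p.k_strata,
            }
        )
    return pd.DataFrame(rows)
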