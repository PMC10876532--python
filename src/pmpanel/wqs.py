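"""Weighted quantile sum (WQS) regression for the 15-constituent mixture.

Each constituent is scored into deciles; the mixture index is the weighted
sum ``sum_i w_i q_i`` with weights on the simplex (w_i >= 0, sum w_i = 1).
The index coefficient and the weights are estimated jointly by maximizing
the Poisson likelihood of

    log mu = b0 + b1 * (Q w) + b' Z + log(beneficiaries)

with the simplex handled by a softmax reparameterization.  Weights are
estimated on bootstrap resamples of zip-year rows and aggregated by signal
strength (|b1|/SE); the final index effect is then re-estimated on the full
data with the index frozen at the aggregated weights, using a cluster-robust
quasi-Poisson fit.  A weight above 1/15 (the uniform share) marks an
influential constituent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import rankdata

from .constants import CONSTITUENTS, COVARIATES
from .panel_model import GLMFit, build_design, fit_quasipoisson, rr_per_delta

__all__ = [
    "QuantizedMixture",
    "WQSFit",
    "quantize",
    "estimate_weights_single",
    "fit_wqs_bootstrap",
    "influential_constituents",
]


@dataclass
class QuantizedMixture:
    """Integer quantile scores (0..q-1) per constituent plus cut points."""

    scores: np.ndarray        # obs x n_constituents, integer-valued floats
    names: tuple
    q: int
    cut_points: dict          # name -> array of interior quantile cuts

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, columns=list(self.names))


def quantize(raw: pd.DataFrame, q: int = 10) -> QuantizedMixture:
    """Score each column into ``q`` near-equal quantile bins (0..q-1).

    Binning is by ordinal rank: ties are broken by row position, so bins
    are always within one row of equal size and tied raw values may span
    adjacent bins (documented tie rule).  Scores are invariant to strictly
    monotone transforms of a column.  A column with fewer than ``q``
    distinct values cannot support ``q`` quantiles and raises.
    """
    if q < 2:
        raise ValueError("q must be at least 2")
    n = len(raw)
    scores = np.empty((n, raw.shape[1]), dtype=float)
    cuts = {}
    for j, name in enumerate(raw.columns):
        x = raw[name].to_numpy(dtype=float)
        if len(np.unique(x)) < q:
            raise ValueError(
                f"constituent {name!r} has fewer than {q} distinct values"
            )
        r = rankdata(x, method="ordinal") - 1
        scores[:, j] = np.floor(r * q / n)
        cuts[name] = np.quantile(x, np.arange(1, q) / q)
    return QuantizedMixture(
        scores=scores, names=tuple(raw.columns), q=q, cut_points=cuts
    )


def _softmax(a: np.ndarray) -> np.ndarray:
    e = np.exp(a - a.max())
    return e / e.sum()


def _negloglik_and_grad(
    params: np.ndarray,
    Q: np.ndarray,
    Z: np.ndarray,
    y: np.ndarray,
    log_off: np.ndarray,
):
    """Mean negative Poisson log-likelihood and its gradient.

    params = [a (softmax logits, len m), b0, b1, gamma (len p)].
    """
    m = Q.shape[1]
    a, b0, b1, gamma = (
        params[:m],
        params[m],
        params[m + 1],
        params[m + 2 :],
    )
    w = _softmax(a)
    idx = Q @ w
    eta = b0 + b1 * idx + Z @ gamma + log_off
    eta = np.clip(eta, -500, 500)
    mu = np.exp(eta)
    n = len(y)
    nll = (mu - y * eta).sum() / n
    resid = mu - y
    g = np.empty_like(params)
    qr = Q.T @ resid / n                      # d nll / d idx-weights
    g[:m] = b1 * (w * (qr - w @ qr))          # softmax Jacobian
    g[m] = resid.sum() / n
    g[m + 1] = resid @ idx / n
    g[m + 2 :] = Z.T @ resid / n
    return nll, g


def estimate_weights_single(
    Q: np.ndarray,
    Z: np.ndarray,
    y: np.ndarray,
    log_off: np.ndarray,
    x0: np.ndarray | None = None,
    n_starts: int = 3,
    rng: np.random.Generator | None = None,
    tol: float = 1e-8,
) -> dict:
    """Maximize the constrained WQS likelihood on one (resampled) dataset.

    Returns weights, the index coefficient ``beta1`` with its model-based
    SE (quasi-Poisson, evaluated at the fixed fitted index), the objective
    value and a convergence flag.  ``x0`` warm-starts the optimizer;
    otherwise ``n_starts`` random restarts are used and the best kept.
    """
    m, p = Q.shape[1], Z.shape[1]
    if rng is None:
        rng = np.random.default_rng(0)

    base_rate = np.log(max(y.sum() / np.exp(log_off).sum(), 1e-12))
    flat = np.concatenate([np.zeros(m), [base_rate, 0.0], np.zeros(p)])
    starts = [np.asarray(x0, dtype=float) if x0 is not None else flat]
    for _ in range(n_starts - 1):
        jitter = flat.copy()
        jitter[:m] = rng.normal(0, 1.0, m)
        jitter[m + 1] = rng.normal(0, 0.05)
        starts.append(jitter)

    best = None
    for s in starts:
        res = minimize(
            _negloglik_and_grad,
            s,
            args=(Q, Z, y, log_off),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": tol, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res

    params = best.x
    w = _softmax(params[:m])
    b1 = float(params[m + 1])

    # model-based SE of b1 at the fitted index, with Pearson dispersion
    idx = Q @ w
    G = np.column_stack([np.ones(len(y)), idx, Z])
    eta = G @ np.concatenate([[params[m], b1], params[m + 2 :]]) + log_off
    mu = np.exp(np.clip(eta, -500, 500))
    phi = float(np.sum((y - mu) ** 2 / mu) / max(len(y) - G.shape[1] - m + 1, 1))
    try:
        cov = phi * np.linalg.inv(G.T @ (G * mu[:, None]))
        se = float(np.sqrt(cov[1, 1]))
    except np.linalg.LinAlgError:
        se = np.nan
    return {
        "weights": w,
        "beta1": b1,
        "se": se,
        "objective": float(best.fun),
        "converged": bool(best.success or best.fun < np.inf),
        "x": params,
    }


@dataclass
class WQSFit:
    """Aggregated WQS result for one outcome."""

    weights: pd.Series                 # length-15 simplex
    beta_index: float                  # log RR per decile of the index
    ci: tuple                          # 95% CI on the per-decile RR scale offsets
    rr_per_decile: float
    rr_ci: tuple
    bootstrap_weights: pd.DataFrame    # B x 15
    bootstrap_beta: np.ndarray
    influence_flags: pd.Series         # weight > 1/15
    final_fit: GLMFit
    n_failed: int
    seed: int

    @property
    def pct_per_decile(self) -> float:
        return (self.rr_per_decile - 1.0) * 100.0


def influential_constituents(fit: WQSFit | pd.Series) -> list:
    """Constituents whose aggregated weight exceeds the uniform share 1/15."""
    w = fit.weights if isinstance(fit, WQSFit) else fit
    thr = 1.0 / len(w)
    return [name for name, v in w.items() if v > thr]


def fit_wqs_bootstrap(
    panel: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str] = COVARIATES,
    constituents: Sequence[str] = CONSTITUENTS,
    offset: str = "beneficiaries",
    B: int = 100,
    q: int = 10,
    seed: int = 0,
    n_starts: int = 3,
    aggregate: str = "signal",
    train_frac: float | None = None,
) -> WQSFit:
    """Bootstrap WQS: estimate weights on B resamples and pool them.

    Decile cut points are computed once on the full data so the index is
    comparable across bootstraps.  Aggregation is a weighted mean of the
    bootstrap weight vectors with weights |beta1|/SE (``aggregate="signal"``)
    or a plain mean (``aggregate="mean"``).  The final index coefficient and
    its cluster-robust CI come from refitting the full panel with the index
    frozen at the aggregated weights.  ``train_frac`` optionally estimates
    the weights on a random row split only, holding out the remainder for
    the final index fit (off by default).
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap samples")
    rng = np.random.default_rng(seed)
    qm = quantize(panel[list(constituents)], q=q)
    Qfull = qm.scores
    Zfull = build_design(panel, None, covariates).to_numpy(dtype=float)[:, 1:]
    yfull = panel[f"count_{outcome}"].to_numpy(dtype=float)
    off_full = np.log(panel[offset].to_numpy(dtype=float))

    if train_frac is not None:
        if not 0.0 < train_frac < 1.0:
            raise ValueError("train_frac must be in (0, 1)")
        train = rng.random(len(yfull)) < train_frac
        final_rows = ~train
    else:
        train = np.ones(len(yfull), dtype=bool)
        final_rows = train
    Q, Z = Qfull[train], Zfull[train]
    y, log_off = yfull[train], off_full[train]
    n = len(y)

    full = estimate_weights_single(
        Q, Z, y, log_off, n_starts=n_starts, rng=rng
    )

    boot_w, boot_b, boot_s = [], [], []
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        try:
            fit_b = estimate_weights_single(
                Q[idx], Z[idx], y[idx], log_off[idx], x0=full["x"], n_starts=1
            )
            # warm-starting every bootstrap at the full-data solution would
            # correlate the weight vectors when there is no real signal; if
            # the index effect is not clearly nonzero, try a random-weight
            # restart (keeping the fitted covariate part) and keep the better
            if abs(fit_b["beta1"]) < 2 * fit_b["se"]:
                x0r = np.array(full["x"], dtype=float)
                x0r[: Q.shape[1]] = rng.normal(0.0, 1.0, Q.shape[1])
                alt = estimate_weights_single(
                    Q[idx], Z[idx], y[idx], log_off[idx], x0=x0r, n_starts=1
                )
                if alt["objective"] < fit_b["objective"]:
                    fit_b = alt
        except Exception:
            n_failed += 1
            continue
        if not fit_b["converged"] or not np.isfinite(fit_b["se"]):
            n_failed += 1
            continue
        boot_w.append(fit_b["weights"])
        boot_b.append(fit_b["beta1"])
        boot_s.append(fit_b["se"])
    if n_failed > B / 2:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap fits failed; aborting WQS"
        )

    W = np.array(boot_w)
    betas = np.array(boot_b)
    if aggregate == "signal":
        sw = np.abs(betas) / np.array(boot_s)
        sw = np.where(np.isfinite(sw), sw, 0.0)
        if sw.sum() == 0:
            sw = np.ones(len(betas))
        w_agg = (W * sw[:, None]).sum(axis=0) / sw.sum()
    elif aggregate == "mean":
        w_agg = W.mean(axis=0)
    else:
        raise ValueError(f"unknown aggregate rule {aggregate!r}")
    w_agg = w_agg / w_agg.sum()

    # final fit with the index frozen at the aggregated weights
    panel_f = panel.loc[final_rows].copy()
    panel_f["wqs_index"] = Qfull[final_rows] @ w_agg
    final = fit_quasipoisson(
        panel_f, outcome, exposure="wqs_index", covariates=covariates, offset=offset
    )
    rr = rr_per_delta(final, "wqs_index", delta=1.0)

    weights = pd.Series(w_agg, index=list(constituents), name="weight")
    return WQSFit(
        weights=weights,
        beta_index=float(final.params["wqs_index"]),
        ci=(np.log(rr.ci_low), np.log(rr.ci_high)),
        rr_per_decile=rr.rr,
        rr_ci=(rr.ci_low, rr.ci_high),
        bootstrap_weights=pd.DataFrame(W, columns=list(constituents)),
        bootstrap_beta=betas,
        influence_flags=weights > 1.0 / len(weights),
        final_fit=final,
        n_failed=n_failed,
        seed=seed,
    )
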