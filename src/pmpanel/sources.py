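"""Stratified NMF source apportionment with tracer-based labeling.

The panel is split into 3 time periods x 3 Ward clusters of ZIP codes
(9 strata).  Within each stratum the zip-year constituent matrix is
factorized as ``X ~ scores @ loadings.T`` with both factors non-negative;
loadings are normalized to unit column sum so each score is the factor's
mass contribution in µg/m³.  Factors are labeled by tracer enrichment
(Ni/V -> oil combustion, SO4/NH4 -> coal, Cu/Fe/Zn/EC -> traffic, Si/Ca ->
soil, K/OC -> biomass, NO3/NH4 -> nitrate) and the mass scores are rescaled
to unit SD within the stratum before regression.

NMF is fit on column mean-scaled concentrations: Frobenius error on the raw
mass scale is dominated by the high-mass species (SO4, NO3, OC) and cannot
resolve factors marked by trace elements with tiny mass (Ni, V); scaling
puts every species on a comparable footing and loadings are converted back
to mass units afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import NMF

from .constants import CONSTITUENTS, PERIODS, TRACER_RULES, UNASSIGNED

__all__ = [
    "Stratification",
    "SourceModel",
    "mean_profiles",
    "ward_cluster",
    "stratify",
    "fit_nmf",
    "choose_rank",
    "label_sources",
    "massify_and_scale",
    "apportion",
]


def period_label(lo: int, hi: int) -> str:
    return f"{lo}-{hi}"


def assign_periods(years: pd.Series, periods=PERIODS) -> pd.Series:
    """Map each year to its period label; years outside any period raise."""
    out = pd.Series(pd.NA, index=years.index, dtype="object")
    for lo, hi in periods:
        out[(years >= lo) & (years <= hi)] = period_label(lo, hi)
    if out.isna().any():
        bad = sorted(years[out.isna()].unique().tolist())
        raise ValueError(f"years {bad} not covered by periods {periods}")
    return out


def mean_profiles(
    panel: pd.DataFrame, period: tuple, constituents=CONSTITUENTS
) -> pd.DataFrame:
    """Per-ZIP mean constituent concentrations over the years of a period."""
    lo, hi = period
    sub = panel[(panel["year"] >= lo) & (panel["year"] <= hi)]
    if sub.empty:
        raise ValueError(f"no rows in period {period}")
    prof = sub.groupby("zip_id")[list(constituents)].mean()
    return prof.sort_index()


def ward_cluster(
    profiles: pd.DataFrame, k: int = 3, standardize: bool = True
) -> pd.Series:
    """Ward minimum-variance clustering of ZIP profiles, cut at k clusters.

    Profiles are standardized per constituent before computing Euclidean
    distances (otherwise the high-mass species dominate).  Cluster labels
    are canonicalized by descending cluster size (ties by centroid norm) so
    the output does not depend on input row order.
    """
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds number of profiles ({len(profiles)})")
    prof = profiles.sort_index()
    X = prof.to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    raw = fcluster(linkage(X, method="ward"), t=k, criterion="maxclust")
    # canonical relabeling: 0 = largest cluster
    order = sorted(
        np.unique(raw),
        key=lambda c: (-(raw == c).sum(), float(np.linalg.norm(X[raw == c].mean(0)))),
    )
    remap = {c: i for i, c in enumerate(order)}
    return pd.Series([remap[c] for c in raw], index=prof.index, name="cluster")


@dataclass
class Stratification:
    """Row-level stratum assignment: period x Ward cluster."""

    table: pd.DataFrame      # columns: zip_id, year, period, cluster, stratum
    periods: tuple
    k: int

    @property
    def strata(self) -> list:
        return sorted(self.table["stratum"].unique())


def stratify(
    panel: pd.DataFrame, periods=PERIODS, k: int = 3
) -> Stratification:
    """Assign every zip-year to one of the period x cluster strata."""
    per = assign_periods(panel["year"], periods)
    rows = []
    for lo, hi in periods:
        lab = period_label(lo, hi)
        prof = mean_profiles(panel, (lo, hi))
        clusters = ward_cluster(prof, k=k)
        sub = panel.loc[per == lab, ["zip_id", "year"]].copy()
        sub["period"] = lab
        sub["cluster"] = sub["zip_id"].map(clusters)
        rows.append(sub)
    table = pd.concat(rows, ignore_index=True)
    table["stratum"] = table["period"] + "/c" + table["cluster"].astype(str)
    return Stratification(table=table, periods=tuple(periods), k=k)


def fit_nmf(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 2000,
    scale: str = "mean",
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-``n_init`` non-negative factorization ``X ~ scores @ loadings.T``.

    Returns ``(loadings, scores, relative_error)`` where ``loadings`` is
    constituents x k with unit column sums (mass-fraction convention) and
    ``scores`` carries the compensating scale, so ``scores[:, j]`` is factor
    j's mass contribution per observation.  ``relative_error`` is Frobenius,
    measured in the scaled space the solver saw.
    """
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValueError("X must be non-negative")
    if k >= min(X.shape):
        raise ValueError(f"k={k} must be below min(X.shape)={min(X.shape)}")
    if scale == "mean":
        col = X.mean(axis=0)
        col[col == 0] = 1.0
    elif scale is None or scale == "none":
        col = np.ones(X.shape[1])
    else:
        raise ValueError(f"unknown scale {scale!r}")
    Xs = X / col

    best = None
    for i in range(n_init):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = NMF(
                n_components=k,
                init="random",
                solver="mu",
                beta_loss="frobenius",
                max_iter=max_iter,
                tol=tol,
                random_state=int(seed) + i,
            )
            S = model.fit_transform(Xs)   # obs x k
        err = model.reconstruction_err_
        if best is None or err < best[2]:
            best = (S, model.components_, err)
    S, H, err = best
    loadings = (H * col[None, :]).T       # constituents x k, mass units
    colsum = loadings.sum(axis=0)
    colsum[colsum == 0] = 1.0
    loadings = loadings / colsum
    scores = S * colsum[None, :]
    rel_err = float(err / np.linalg.norm(Xs))
    return loadings, scores, rel_err


def choose_rank(
    X: np.ndarray,
    ks=(4, 5),
    seed: int = 0,
    n_init: int = 10,
    gain_threshold: float = 0.01,
) -> int:
    """Pick the factorization rank from ``ks`` (ordered ascending).

    The larger rank is kept only when its explained-variance gain over the
    smaller exceeds ``gain_threshold`` (evaluated in the scaled space).
    """
    X = np.asarray(X, dtype=float)
    evs = {}
    for k in ks:
        _, _, rel = fit_nmf(X, k, seed=seed, n_init=n_init)
        evs[k] = 1.0 - rel**2
    ks = sorted(ks)
    chosen = ks[0]
    for k_prev, k_next in zip(ks, ks[1:]):
        if evs[k_next] - evs[k_prev] > gain_threshold:
            chosen = k_next
    return chosen


def label_sources(
    loadings: np.ndarray,
    tracer_rules: dict = TRACER_RULES,
    constituents=CONSTITUENTS,
    min_enrichment: float = 1.5,
) -> list:
    """Label factors by greedy tracer enrichment.

    For rule r and factor f the score is the factor's summed loading on the
    rule's tracers divided by the mean summed loading of those tracers over
    the *other* factors (for a single factor, over the uniform expectation
    |tracers|/15); uniform loadings score 1 everywhere.  Labels are assigned
    greedily from the highest score down, each label and each factor at most
    once; scores below ``min_enrichment`` stay unassigned.
    """
    W = np.asarray(loadings, dtype=float)
    idx = {c: i for i, c in enumerate(constituents)}
    k = W.shape[1]
    rules = list(tracer_rules.items())
    score = np.zeros((len(rules), k))
    for r, (_, tracers) in enumerate(rules):
        rows = [idx[t] for t in tracers]
        tr = W[rows, :].sum(axis=0)
        if k == 1:
            denom = np.array([len(tracers) / W.shape[0]])
        else:
            denom = (tr.sum() - tr) / (k - 1)
        score[r, :] = tr / np.maximum(denom, 1e-12)

    labels = [UNASSIGNED] * k
    used_rules: set = set()
    used_factors: set = set()
    order = np.dstack(np.unravel_index(np.argsort(-score, axis=None), score.shape))[0]
    for r, f in order:
        if r in used_rules or f in used_factors:
            continue
        if score[r, f] < min_enrichment:
            continue
        labels[f] = rules[r][0]
        used_rules.add(r)
        used_factors.add(f)
    return labels


def massify_and_scale(
    loadings: np.ndarray,
    scores: np.ndarray,
    X: np.ndarray | None = None,
    method: str = "unit_sum",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mass contributions (µg/m³) and their SD-rescaled versions.

    Under the unit-column-sum loading convention (``method="unit_sum"``,
    default) the factor-j mass contribution per observation is
    ``scores[:, j] * loadings[:, j].sum()``.  With ``method="regress"`` the
    per-factor mass scale comes instead from a non-negative regression of
    the observed row totals of ``X`` on the scores.  Each mass series is
    then divided by its SD so regression coefficients read per-SD.
    Zero-variance factors are flagged (returned mask False) and excluded
    from scaling.
    """
    W = np.asarray(loadings, dtype=float)
    S = np.asarray(scores, dtype=float)
    if method == "unit_sum":
        mass = S * W.sum(axis=0)[None, :]
    elif method == "regress":
        if X is None:
            raise ValueError("method='regress' requires the data matrix X")
        from scipy.optimize import nnls

        b, _ = nnls(S, np.asarray(X, dtype=float).sum(axis=1))
        mass = S * b[None, :]
    else:
        raise ValueError(f"unknown massification method {method!r}")
    sd = mass.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn("zero-variance factor(s) excluded from SD scaling")
    scaled = np.full_like(mass, np.nan)
    scaled[:, keep] = mass[:, keep] / sd[keep]
    return mass, scaled, keep


@dataclass
class SourceModel:
    """Per-stratum factorization: loadings, labels, mass and scaled scores."""

    stratum: str
    k: int
    loadings: pd.DataFrame        # constituents x k, unit column sums
    labels: list
    mass: pd.DataFrame            # obs x k, µg/m³
    scaled: pd.DataFrame          # obs x k, SD = 1
    rel_error: float
    index: pd.Index               # row index into the original panel


@dataclass
class Apportionment:
    """All stratum models plus a long exposure table for regression."""

    stratification: Stratification
    models: dict                  # stratum -> SourceModel
    exposures: pd.DataFrame       # panel-indexed; columns factor_0..; labels per stratum

    def labels_by_stratum(self) -> pd.DataFrame:
        rows = []
        for s, m in self.models.items():
            for j, lab in enumerate(m.labels):
                rows.append({"stratum": s, "factor": j, "label": lab, "k": m.k})
        return pd.DataFrame(rows)


def apportion(
    panel: pd.DataFrame,
    periods=PERIODS,
    k_clusters: int = 3,
    ranks=(4, 5),
    seed: int = 0,
    n_init: int = 10,
    tracer_rules: dict = TRACER_RULES,
    constituents=CONSTITUENTS,
) -> Apportionment:
    """Run the full stratified apportionment on a panel.

    Every zip-year row within a stratum enters the NMF.  Returns per-stratum
    models and the combined SD-scaled exposure series.
    """
    strat = stratify(panel, periods=periods, k=k_clusters)
    key = panel["zip_id"].astype(str) + "|" + panel["year"].astype(str)
    skey = strat.table["zip_id"].astype(str) + "|" + strat.table["year"].astype(str)
    stratum_of = pd.Series(strat.table["stratum"].to_numpy(), index=skey.to_numpy())
    row_stratum = key.map(stratum_of)

    models = {}
    for s in strat.strata:
        mask = (row_stratum == s).to_numpy()
        X = panel.loc[mask, list(constituents)].to_numpy(dtype=float)
        k = choose_rank(X, ks=ranks, seed=seed, n_init=n_init)
        loadings, scores, rel = fit_nmf(X, k, seed=seed, n_init=n_init)
        labels = label_sources(loadings, tracer_rules, constituents)
        mass, scaled, keep = massify_and_scale(loadings, scores)
        fac_cols = [f"factor_{j}" for j in range(k)]
        models[s] = SourceModel(
            stratum=s,
            k=k,
            loadings=pd.DataFrame(
                loadings, index=list(constituents), columns=fac_cols
            ),
            labels=labels,
            mass=pd.DataFrame(mass, columns=fac_cols, index=panel.index[mask]),
            scaled=pd.DataFrame(scaled, columns=fac_cols, index=panel.index[mask]),
            rel_error=rel,
            index=panel.index[mask],
        )
    return Apportionment(
        stratification=strat,
        models=models,
        exposures=row_stratum.rename("stratum").to_frame(),
    )
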