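"""Synthetic ZIP-code-year admission panels with known ground truth.

The generator emulates the structure of an aggregated Medicare-style panel:
latent emission sources with non-negative constituent signatures, region- and
period-specific source intensities, ZIP-level frailties, correlated covariates
(one confounder), person-time offsets, and overdispersed admission counts from
a log-linear rate model.  Every true parameter is recorded in a
:class:`SyntheticTruth` so downstream stages can be checked for recovery.

Counts can be driven by one of three data-generating mechanisms
(``config.count_model``):

``"pm25"``
    log-rate linear in total PM2.5, with an optional two-segment (piecewise)
    slope around a breakpoint;
``"wqs"``
    log-rate linear in a weighted decile index of the 15 constituents
    (the weighted-quantile-sum truth);
``"sources"``
    log-rate linear in the per-source mass scores, standardized to unit SD
    within each (period, region) stratum.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import CONSTITUENTS, COVARIATES, OUTCOMES, PERIODS

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_source_scores",
    "generate_constituents",
    "generate_counts",
    "generate_panel",
]

#: Default source order for the 5-source generator.
DEFAULT_SOURCES = (
    "coal burning",
    "traffic",
    "oil combustion",
    "soil",
    "regionally transported nitrate",
)

# Mass-fraction signatures (columns sum to ~1; normalized exactly at load).
# Rows follow CONSTITUENTS order:
# EC   NH4  NO3  OC   SO4  Br    Ca   Cu    Fe   K    Ni    Pb    Si   V     Zn
_RAW_LOADINGS = np.array(
    [
        # coal burning: secondary sulfate-dominated with ammonium
        [.03, .18, .01, .14, .55, .005, .01, .001, .02, .02, .001, .015, .01, .001, .01],
        # traffic: EC/OC plus brake/tyre metals Cu, Fe, Zn
        [.25, .005, .05, .33, .02, .02, .04, .045, .18, .01, .001, .02, .01, .001, .05],
        # residual-oil combustion: Ni and V tracers on a sulfate/OC base
        [.10, .04, .01, .24, .33, .005, .005, .005, .05, .005, .12, .005, .005, .10, .02],
        # soil / crustal dust: Si, Ca, Fe
        [.02, .005, .02, .10, .02, .005, .20, .005, .20, .06, .001, .005, .36, .001, .01],
        # regionally transported nitrate: NH4NO3
        [.02, .21, .58, .10, .06, .002, .005, .001, .01, .01, .001, .002, .005, .001, .005],
    ]
).T  # -> 15 x 5

DEFAULT_LOADINGS = _RAW_LOADINGS / _RAW_LOADINGS.sum(axis=0, keepdims=True)

#: Mean mass contribution per source (µg/m³), national scale.
DEFAULT_SOURCE_MEANS = np.array([3.0, 1.8, 0.5, 1.0, 1.9])

#: Region multipliers (3 regions x 5 sources): an industrial/oil east, an
#: agricultural nitrate belt, and a dusty/traffic west.
DEFAULT_REGION_PROFILES = np.array(
    [
        [1.35, 1.00, 1.60, 0.60, 0.90],
        [1.00, 0.90, 0.60, 1.00, 1.50],
        [0.65, 1.20, 0.80, 1.50, 0.70],
    ]
)

#: Period multipliers (3 periods x 5 sources): declining coal/oil/traffic.
DEFAULT_PERIOD_TRENDS = np.array(
    [
        [1.25, 1.15, 1.20, 1.00, 1.10],
        [1.00, 1.00, 1.00, 1.00, 1.00],
        [0.60, 0.85, 0.75, 1.00, 0.85],
    ]
)

# Rate ratios per SD (3.7 µg/m³) of total PM2.5, by outcome.
DEFAULT_RR_PER_SD = {
    "non_respiratory": 1.108,
    "cns": 1.007,
    "intestinal": 1.068,
    "urinary": 1.120,
    "septicemia": 1.128,
}

# Rate ratios per decile of the constituent mixture index, by outcome.
DEFAULT_RR_PER_DECILE = {
    "non_respiratory": 1.103,
    "cns": 1.042,
    "intestinal": 1.127,
    "urinary": 1.120,
    "septicemia": 1.102,
}

# Rate ratios per SD of source-specific mass, by outcome (source order =
# DEFAULT_SOURCES: coal, traffic, oil, soil, nitrate).
DEFAULT_SOURCE_RR = {
    "non_respiratory": (1.182, 1.206, 1.145, 1.089, 1.078),
    "cns": (1.007, 1.056, 1.004, 1.112, 0.987),
    "intestinal": (1.161, 1.239, 1.171, 1.105, 0.992),
    "urinary": (1.226, 1.278, 1.148, 1.153, 1.051),
    "septicemia": (1.154, 1.187, 1.135, 1.032, 1.112),
}

# Baseline admission rates per person-year (overall rate 25.1/1000; the
# subtype baselines are plausible splits of that total).
DEFAULT_BASELINE_RATE = {
    "non_respiratory": 0.0251,
    "cns": 0.0004,
    "intestinal": 0.0040,
    "urinary": 0.0090,
    "septicemia": 0.0080,
}

#: WQS truth: SO4 0.308, Ni 0.225, Cu 0.153, remaining 12 uniform.
def default_wqs_weights() -> np.ndarray:
    w = np.full(15, (1.0 - 0.308 - 0.225 - 0.153) / 12.0)
    idx = {c: i for i, c in enumerate(CONSTITUENTS)}
    w[idx["SO4"]] = 0.308
    w[idx["Ni"]] = 0.225
    w[idx["Cu"]] = 0.153
    return w


@dataclass
class SyntheticConfig:
    """Ground-truth parameters of the panel generator.

    The exposure side is calibrated so the marginal PM2.5 distribution of a
    default panel matches the national annual distribution (median ~9.7,
    SD ~3.7 µg/m³).  ``mass_fraction`` is the share of total PM2.5 mass
    covered by the 15 modeled constituents (they cover most, but not all,
    of the total mass).
    """

    n_zips: int = 300
    year_start: int = 2000
    year_end: int = 2016
    n_sources: int = 5
    source_names: tuple = DEFAULT_SOURCES
    loading_matrix: np.ndarray = field(default_factory=lambda: DEFAULT_LOADINGS.copy())
    source_means: np.ndarray = field(default_factory=lambda: DEFAULT_SOURCE_MEANS.copy())
    region_profiles: np.ndarray = field(
        default_factory=lambda: DEFAULT_REGION_PROFILES.copy()
    )
    period_trends: np.ndarray = field(
        default_factory=lambda: DEFAULT_PERIOD_TRENDS.copy()
    )
    periods: tuple = PERIODS
    mass_scale: float = 1.07         # global multiplier on source means
    score_shape: float = 4.0         # gamma shape of obs-level source activity
    zip_frailty_sd: float = 0.20     # lognormal sigma, per-ZIP source intensity
    noise_cv: float = 0.30           # constituent-level multiplicative noise CV
    mass_fraction: float = 0.85      # constituent sum / total PM2.5
    sd_ref_pm25: float = 3.7         # µg/m³; "per SD" reference for effects

    count_model: str = "pm25"        # "pm25" | "wqs" | "sources"
    true_rr_per_sd_pm25: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RR_PER_SD)
    )
    rr_high_segment: float | None = None   # piecewise slope above breakpoint
    pm25_breakpoint: float = 9.0
    true_wqs_weights: np.ndarray = field(default_factory=default_wqs_weights)
    true_rr_per_decile: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RR_PER_DECILE)
    )
    true_source_rr: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_SOURCE_RR.items()}
    )
    baseline_rate: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_RATE)
    )
    dispersion: float = 1.5          # phi: Var(count) = phi * mu
    rate_frailty_sd: float = 0.02    # lognormal sigma of per-ZIP rate frailty
    covariate_effects: np.ndarray = field(
        default_factory=lambda: np.array([0.02, 0.10, 0.08, -0.06, 0.03])
    )
    confounding_r: float = 0.30      # corr(poverty covariate, ZIP-mean PM2.5)
    year_drift: float = -0.004       # log-rate drift per calendar year
    beneficiary_range: tuple = (101, 50_000)
    beneficiary_median: float = 536.0
    beneficiary_sigma: float = 1.43  # lognormal sigma (IQR 222-1530)
    seed: int = 0

    def validate(self) -> None:
        if self.n_zips < 1:
            raise ValueError("n_zips must be positive")
        if self.year_end < self.year_start:
            raise ValueError("year range is empty")
        if not 1 <= self.n_sources <= 6:
            raise ValueError("n_sources must be in [1, 6]")
        W = np.asarray(self.loading_matrix, dtype=float)
        if W.shape != (len(CONSTITUENTS), self.n_sources):
            raise ValueError(
                f"loading_matrix must be {len(CONSTITUENTS)} x {self.n_sources}, "
                f"got {W.shape}"
            )
        if (W < 0).any():
            raise ValueError("loading_matrix entries must be non-negative")
        w = np.asarray(self.true_wqs_weights, dtype=float)
        if w.shape != (len(CONSTITUENTS),):
            raise ValueError("true_wqs_weights must have length 15")
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("true_wqs_weights must be a simplex vector")
        if self.dispersion < 1.0:
            raise ValueError("dispersion must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.beneficiary_range[0] <= 100:
            raise ValueError("beneficiary minimum must exceed 100")
        if self.count_model not in ("pm25", "wqs", "sources"):
            raise ValueError(f"unknown count_model {self.count_model!r}")
        if np.asarray(self.source_means).shape != (self.n_sources,):
            raise ValueError("source_means must have one entry per source")
        if np.asarray(self.region_profiles).shape[1] != self.n_sources:
            raise ValueError("region_profiles must have one column per source")
        if np.asarray(self.period_trends).shape != (
            len(self.periods),
            self.n_sources,
        ):
            raise ValueError("period_trends must be n_periods x n_sources")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    def replace(self, **kw) -> "SyntheticConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SyntheticTruth:
    """Everything the generator knew: parameters plus realized latents."""

    config: SyntheticConfig
    scores: pd.DataFrame                  # obs x sources, µg/m³ mass scores
    region: pd.Series                     # per zip_id
    constituent_sds: pd.Series            # realized per-constituent SD
    pm25_sd: float                        # realized SD of total PM2.5
    beta0: dict                           # per-outcome intercept (log rate)
    exposure_coef: dict                   # per-outcome true exposure coefficient(s)
    wqs_index: np.ndarray | None = None   # realized true decile index (wqs mode)
    source_z: pd.DataFrame | None = None  # stratum-standardized scores (sources mode)

    def params_dict(self) -> dict:
        """Scalar/param summary suitable for a structured text file."""
        c = self.config
        return {
            "seed": int(c.seed),
            "n_zips": int(c.n_zips),
            "years": [int(c.year_start), int(c.year_end)],
            "n_sources": int(c.n_sources),
            "source_names": list(c.source_names),
            "count_model": c.count_model,
            "dispersion": float(c.dispersion),
            "sd_ref_pm25": float(c.sd_ref_pm25),
            "realized_pm25_sd": float(self.pm25_sd),
            "true_rr_per_sd_pm25": {k: float(v) for k, v in c.true_rr_per_sd_pm25.items()},
            "true_wqs_weights": {
                name: float(w) for name, w in zip(CONSTITUENTS, c.true_wqs_weights)
            },
            "true_source_rr": {
                k: [float(x) for x in v] for k, v in c.true_source_rr.items()
            },
            "beta0": {k: float(v) for k, v in self.beta0.items()},
            "constituent_sds": {
                k: float(v) for k, v in self.constituent_sds.items()
            },
        }


def _period_index(years: np.ndarray, periods) -> np.ndarray:
    out = np.full(len(years), -1, dtype=int)
    for i, (lo, hi) in enumerate(periods):
        out[(years >= lo) & (years <= hi)] = i
    if (out < 0).any():
        bad = sorted(set(years[out < 0].tolist()))
        raise ValueError(f"years {bad} not covered by periods {periods}")
    return out


def _row_grid(config: SyntheticConfig) -> pd.DataFrame:
    zips = [f"Z{i:05d}" for i in range(config.n_zips)]
    years = config.years
    df = pd.DataFrame(
        {
            "zip_id": np.repeat(zips, len(years)),
            "year": np.tile(years, len(zips)),
        }
    )
    df["zip_index"] = np.repeat(np.arange(config.n_zips), len(years))
    df["period"] = _period_index(df["year"].to_numpy(), config.periods)
    df["region"] = df["zip_index"].to_numpy() % config.region_profiles.shape[0]
    return df


def generate_source_scores(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw per-observation source mass scores (µg/m³).

    Scores are gamma-distributed around a mean that factorizes into a
    national source mean, a region profile, a period trend, and a per-ZIP
    lognormal frailty.  Columns are mutually independent given those means.

    Returns the (zip, year) row grid and the obs x n_sources score matrix.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = _row_grid(config)
    n = len(rows)
    k = config.n_sources

    sigma = config.zip_frailty_sd
    zip_frailty = np.exp(
        rng.normal(-0.5 * sigma**2, sigma, size=(config.n_zips, k))
    )
    means = (
        config.mass_scale
        * np.asarray(config.source_means)[None, :]
        * np.asarray(config.region_profiles)[rows["region"].to_numpy(), :]
        * np.asarray(config.period_trends)[rows["period"].to_numpy(), :]
        * zip_frailty[rows["zip_index"].to_numpy(), :]
    )
    shape = config.score_shape
    scores = rng.gamma(shape, 1.0 / shape, size=(n, k)) * means
    return rows, scores


def generate_constituents(
    scores: np.ndarray,
    loading_matrix: np.ndarray,
    noise_cv: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Mix source scores through the loading matrix with multiplicative noise.

    ``X = (scores @ loadings.T) * lognormal(mean 1, CV noise_cv)``, clipped
    at zero.  With ``noise_cv == 0`` the product is returned exactly.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    scores = np.asarray(scores, dtype=float)
    W = np.asarray(loading_matrix, dtype=float)
    if scores.ndim != 2 or W.ndim != 2 or scores.shape[1] != W.shape[1]:
        raise ValueError(
            f"shape mismatch: scores {scores.shape} vs loadings {W.shape}"
        )
    X = scores @ W.T
    if noise_cv > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        s = np.sqrt(np.log1p(noise_cv**2))
        X = X * rng.lognormal(-0.5 * s**2, s, size=X.shape)
    return np.clip(X, 0.0, None)


def generate_counts(
    log_rate: np.ndarray,
    beneficiaries: np.ndarray,
    dispersion: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw overdispersed counts with mean ``mu = beneficiaries * exp(log_rate)``.

    Uses a gamma-Poisson mixture whose variance is exactly ``phi * mu``
    (quasi-Poisson specifies only this variance function; the mixture with
    gamma shape ``mu/(phi-1)`` matches it in expectation).  ``phi = 1``
    reduces to pure Poisson.
    """
    log_rate = np.asarray(log_rate, dtype=float)
    beneficiaries = np.asarray(beneficiaries, dtype=float)
    if (beneficiaries <= 0).any():
        raise ValueError("beneficiaries must be positive")
    mu = beneficiaries * np.exp(log_rate)
    bad = ~np.isfinite(mu) | (mu > 1e12)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"rate overflow at row {i}: mu={mu[i]:.4g} with "
            f"{beneficiaries[i]:.0f} beneficiaries"
        )
    phi = float(dispersion)
    if phi < 1.0:
        raise ValueError("dispersion must be >= 1")
    if phi == 1.0:
        lam = mu
    else:
        lam = rng.gamma(mu / (phi - 1.0), phi - 1.0)
    return rng.poisson(lam)


def _quantize_for_truth(X: np.ndarray, q: int = 10) -> np.ndarray:
    # local import avoids a cycle (wqs imports nothing from here)
    from .wqs import quantize

    return quantize(pd.DataFrame(X, columns=list(CONSTITUENTS)), q=q).scores


def generate_panel(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a complete ZIP-code-year panel and its ground truth.

    The returned frame has one row per (zip_id, year): admission counts per
    outcome, beneficiary counts, total PM2.5, the 15 constituents, and the
    continuous covariates (one of which is correlated with ZIP-mean PM2.5
    to create confounding).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    rows, scores = generate_source_scores(config, rng)
    X = generate_constituents(scores, config.loading_matrix, config.noise_cv, rng)
    pm25 = X.sum(axis=1) / config.mass_fraction
    n = len(rows)
    zi = rows["zip_index"].to_numpy()

    # beneficiaries: lognormal sized to the observed ZIP-size distribution
    lo, hi = config.beneficiary_range
    benef = np.rint(
        rng.lognormal(np.log(config.beneficiary_median), config.beneficiary_sigma, n)
    ).astype(int)
    benef = np.clip(benef, lo, hi)

    # covariates: ZIP-level draws + yearly jitter; poverty tracks ZIP-mean PM2.5
    zip_mean_pm = pd.Series(pm25).groupby(zi).transform("mean").to_numpy()
    z_pm = (zip_mean_pm - zip_mean_pm.mean()) / zip_mean_pm.std()
    base = rng.normal(size=(config.n_zips, len(COVARIATES)))
    cov = base[zi, :] + rng.normal(0.0, 0.2, size=(n, len(COVARIATES)))
    r = config.confounding_r
    j_pov = COVARIATES.index("pct_poverty")
    cov[:, j_pov] = r * z_pm + np.sqrt(1 - r**2) * (
        base[zi, j_pov] + rng.normal(0.0, 0.2, n)
    ) / np.sqrt(1.04)

    # shared log-rate components
    cov_lp = cov @ np.asarray(config.covariate_effects, dtype=float)
    fs = config.rate_frailty_sd
    frailty = rng.normal(-0.5 * fs**2, fs, size=config.n_zips)[zi] if fs > 0 else 0.0
    drift = config.year_drift * (rows["year"].to_numpy() - 2008)
    shared_lp = cov_lp + frailty + drift

    # exposure terms per mechanism
    exposure_coef: dict = {}
    wqs_index = None
    source_z = None
    if config.count_model == "wqs":
        Q = _quantize_for_truth(X)
        w = np.asarray(config.true_wqs_weights, dtype=float)
        wqs_index = Q @ w
    elif config.count_model == "sources":
        key = pd.Series(
            rows["period"].astype(str) + "/" + rows["region"].astype(str)
        )
        sdf = pd.DataFrame(scores, columns=list(config.source_names))
        source_z = sdf / sdf.groupby(key.to_numpy()).transform("std")

    counts = {}
    beta0 = {}
    for outcome in OUTCOMES:
        if config.count_model == "pm25":
            rr = float(config.true_rr_per_sd_pm25[outcome])
            b1 = np.log(rr) / config.sd_ref_pm25
            if config.rr_high_segment is not None:
                bh = np.log(float(config.rr_high_segment)) / config.sd_ref_pm25
                brk = config.pm25_breakpoint
                term = b1 * np.minimum(pm25, brk) + bh * np.clip(pm25 - brk, 0, None)
                exposure_coef[outcome] = {"low": b1, "high": bh, "breakpoint": brk}
            else:
                term = b1 * pm25
                exposure_coef[outcome] = {"pm25": b1}
        elif config.count_model == "wqs":
            theta = np.log(float(config.true_rr_per_decile[outcome]))
            term = theta * wqs_index
            exposure_coef[outcome] = {"per_decile": theta}
        else:  # sources
            gamma = np.log(np.asarray(config.true_source_rr[outcome], dtype=float))
            term = source_z.to_numpy() @ gamma
            exposure_coef[outcome] = {
                s: float(g) for s, g in zip(config.source_names, gamma)
            }

        lp = shared_lp + term
        b0 = np.log(config.baseline_rate[outcome]) - np.log(np.mean(np.exp(lp)))
        beta0[outcome] = float(b0)
        counts[f"count_{outcome}"] = generate_counts(
            b0 + lp, benef, config.dispersion, rng
        )

    panel = pd.concat(
        [
            rows[["zip_id", "year"]].reset_index(drop=True),
            pd.DataFrame({"beneficiaries": benef}),
            pd.DataFrame(counts),
            pd.DataFrame({"pm25": pm25}),
            pd.DataFrame(X, columns=list(CONSTITUENTS)),
            pd.DataFrame(cov, columns=list(COVARIATES)),
        ],
        axis=1,
    )

    truth = SyntheticTruth(
        config=config,
        scores=pd.DataFrame(scores, columns=list(config.source_names)).assign(
            zip_id=rows["zip_id"].to_numpy(), year=rows["year"].to_numpy()
        ),
        region=pd.Series(
            rows.drop_duplicates("zip_id")["region"].to_numpy(),
            index=rows.drop_duplicates("zip_id")["zip_id"].to_numpy(),
            name="region",
        ),
        constituent_sds=pd.Series(X.std(axis=0), index=list(CONSTITUENTS)),
        pm25_sd=float(pm25.std()),
        beta0=beta0,
        exposure_coef=exposure_coef,
        wqs_index=wqs_index,
        source_z=source_z,
    )
    return panel, truth
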