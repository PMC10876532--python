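# Methods

## The estimation problem

`pmpanel` implements the analytic chain used in registry-scale air-pollution
epidemiology to relate *long-term* fine particulate matter (PM2.5) and its
chemical constituents to *aggregated* hospital-admission counts. The unit of
analysis is the ZIP-code-year: admission counts for an outcome category,
a person-time denominator (beneficiaries alive at the start of the year),
annual total PM2.5 and 15 constituent concentrations (EC, NH4, NO3, OC, SO4,
Br, Ca, Cu, Fe, K, Ni, Pb, Si, V, Zn, µg/m³), and ZIP-level covariates.
Because the registry data such analyses are built on are restricted-access,
the package ships a first-class synthetic panel generator with known ground
truth; every stage is validated by parameter recovery against that truth.

## Rate model (panel_model)

For outcome *k* in ZIP *i*, year *j*:

    log E[count_ijk] = b0 + b1 * PM2.5_ij + b' Z_ij + log(benef_ij)

with quasi-Poisson variance `Var = phi * mu`. Point estimates are Poisson
maximum likelihood (IRLS via statsmodels); `phi` is the Pearson chi-square
over residual degrees of freedom, the standard quasi-likelihood moment
estimator (a deviance-based `phi` is available as an option).
Calendar year enters as indicator variables.
Two covariances are always computed:

* model-based: `phi * (X' W X)^-1`, `W = diag(mu)`;
* cluster-robust CR0, clustered on ZIP by default:
  `B^-1 (sum_g s_g s_g') B^-1` with `s_g = X_g'(y_g - mu_g)`.
  The quasi-Poisson scale cancels in the sandwich. A
  heteroskedasticity-only variant (`robust="hc0"`) is available.

Rate ratios are reported per `delta` µg/m³ (default 3.7, one SD of annual
PM2.5 over included zip-years) as `exp(b1*delta)` with 95% Wald CIs using
z = 1.96. The SD is computed over zip-year rows, not person-weighted; the
increment is a free parameter.

The low-exposure sensitivity analysis re-fits after keeping zip-years with
PM2.5 ≤ 9 µg/m³; the inequality is inclusive and an empty restriction is an
error rather than a silent no-op.

## Weighted quantile sum regression (wqs)

Each constituent is scored into deciles (0–9) by ordinal rank; ties are
broken by row position, so bins are equal-sized and tied raw values may span
adjacent bins. Scores are invariant to strictly monotone transforms. Cut
points are computed once on the full panel so the index is comparable across
bootstrap resamples.

The mixture index is `I(w) = sum_i w_i q_i` with `w` on the simplex. One fit
maximizes the Poisson likelihood of
`log mu = b0 + b1*I(w) + b'Z + log(benef)` jointly in `(w, b0, b1, b')`,
handling the simplex by softmax reparameterization, with analytic gradients
under L-BFGS-B (objective tolerance 1e-8). The index direction is not
pre-constrained; a single signed `b1` applies to the whole index
(one index, one direction per fit).

The full-data fit uses 3 starts (flat plus two random-logit restarts).
Each of the B bootstrap resamples (default B = 100, drawn with replacement
at the zip-year row level) is warm-started at the full-data solution; if the
resulting index coefficient is not clearly nonzero (|b1| < 2 SE) a
random-weight restart is tried and the better objective kept. The warm start
is what makes 100 bootstraps affordable; the conditional restart exists
because warm-starting under a null likelihood (flat in `w` when `b1` is
near 0) would spuriously correlate the bootstrap weight vectors.

Aggregation is the signal-weighted mean of bootstrap weight vectors,
weighted by `|b1|/SE` (plain mean available). There is no train/validation
split by default; a split is available for sensitivity. The final index
coefficient, covariate coefficients and cluster-robust CI come from
refitting the full panel with the index frozen at the aggregated weights
(covariates re-estimated in that final fit). Constituents with aggregated
weight above the uniform share 1/15 are flagged influential.

## Source apportionment (sources)

The panel is stratified into 3 time periods (2000–2005, 2006–2010,
2011–2016) × 3 ZIP clusters. Clustering uses Ward minimum-variance linkage
on Euclidean distances between per-ZIP mean constituent profiles within the
period, standardized per constituent — without standardization the
high-mass species (SO4, NO3, OC) dominate the metric. Cluster labels are
canonicalized by cluster size so results are independent of row order.

Within each of the 9 strata, all zip-year rows (not ZIP means) enter a
non-negative factorization `X ~ scores @ loadings.T` (Frobenius objective,
multiplicative-update solver, 10 seeded restarts, best kept). The solver
sees *column mean-scaled* concentrations: on the raw mass scale the
Frobenius error is dominated by the secondary species and the factorization
cannot resolve a factor marked by trace elements whose absolute mass is
tiny (Ni and V together contribute well under 0.1 µg/m³) — precisely the
factor whose tracers carry the labeling. Loadings are converted back to
mass units and normalized to unit column sum, with the compensating scale
in the scores, so `scores[:, j]` is factor j's mass contribution in µg/m³
and the per-observation factor masses add up to the modeled constituent
mass (mass closure, exact for an exact factorization). An alternative mass
conversion that regresses observed row totals on the scores (non-negative
least squares) is available as an option.

Rank is chosen between 4 and 5: rank 5 is kept when its explained-variance
gain over rank 4 (in the scaled space) exceeds 1%. The gain produced by a
genuine fifth source in panels of this composition is 1.5–2%, while a
spurious extra factor adds a few tenths of a percent, so 1% separates the
two regimes; the threshold is a parameter.

Factors are labeled by tracer enrichment. For each rule (Ni/V → oil
combustion; SO4+NH4 → coal burning; Cu/Fe/Zn/EC → traffic; Si/Ca → soil;
K/OC → biomass burning; NO3/NH4 → regionally transported nitrate) the score
of a factor is its summed tracer loading divided by the mean summed tracer
loading of the *other* factors. Labels are assigned greedily from the
highest score down, each label and factor at most once; scores below 1.5
stay `unassigned` (uniform loadings score exactly 1). The rule table is an
editable dictionary, codified from standard receptor-modelling practice.

Factor mass series are divided by their within-stratum SD before
regression, so coefficients read per SD of source-specific mass;
zero-variance factors are excluded with a warning.

## Stratum models and pooling (meta)

Within each stratum one quasi-Poisson model includes **all** factor
exposures simultaneously (mutual adjustment) plus covariates, year
indicators and the offset; cluster-robust SEs are taken per factor.
Factor pairs with |r| > 0.99 abort with the pair named. Effects are
reported for labeled sources only; a source absent from a stratum simply
contributes no record, and the pooled output reports how many strata each
source was identified in.

Pooling is DerSimonian–Laird:

    tau^2   = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)),  w = 1/se^2
    pooled  = sum w* y / sum w*,  w* = 1/(se^2 + tau^2)

with normal-quantile CIs. With `tau^2 = 0` this reduces exactly to the
fixed-effect inverse-variance average. A single stratum passes through with
a warning.

## Synthetic panel generator (synthetic)

The generator emulates the aggregated panel, not the record-level registry:

* **Sources.** Five latent sources (coal burning, traffic, oil combustion,
  soil, regionally transported nitrate) with fixed mass-fraction signatures
  built around the tracer elements above. Per-observation source activity
  is gamma (shape 4, mean 1) times a national source mean, a region profile
  (3 regions with industrial/agricultural/dusty character), a period trend
  (declining coal/oil/traffic), and a per-ZIP lognormal frailty
  (sigma 0.20). Regions give the Ward step real structure to find; period
  steps keep scores stationary within a stratum so "per SD within stratum"
  is well defined.
* **Constituents.** `X = scores @ loadings.T` times lognormal noise with
  CV 0.30 (mean 1), clipped at 0. Total PM2.5 is the constituent sum
  divided by 0.85: the 15 species cover most but not all of the total mass
  and the covered fraction is a configurable assumption.
* **Calibration.** Source means carry a global scale factor set once so the
  marginal PM2.5 of a default panel matches the published national annual
  distribution: median 9.6 vs 9.7 µg/m³, IQR 7.6–12.1 vs 7.7–11.8,
  SD 3.67 vs 3.7. The per-SD reference for true effects is fixed at
  3.7 µg/m³.
* **Counts.** `count ~ Poisson(Gamma(mu/(phi-1), phi-1))`, a gamma-Poisson
  mixture whose variance is exactly `phi*mu` — quasi-Poisson specifies only
  the variance function, and this mixture matches it in expectation
  (phi = 1 is pure Poisson). Default phi = 1.5, plus a per-ZIP rate frailty
  (lognormal, sigma 0.02) that induces the within-ZIP correlation the
  cluster-robust variance exists for. Beneficiary counts are lognormal
  with median 536 and sigma 1.43 (matching the published ZIP-size median
  and IQR 222–1530), truncated strictly above 100. Baseline rate
  25.1/1000 person-years for non-respiratory infections; subtype baselines
  are plausible splits of that total.
* **Covariates and confounding.** Five continuous standardized ZIP-level
  covariates with yearly jitter (a deliberate scale-down from the ~18 the
  full adjustment set carries, preserving the confounding structure);
  the poverty covariate is constructed with correlation 0.3 to ZIP-mean
  PM2.5 and carries the largest log-rate effect, so unadjusted fits are
  visibly biased and adjusted fits are not. A small calendar drift is
  absorbed by the year indicators.
* **Count mechanisms.** Exactly one of three mechanisms drives the
  log-rate: linear in total PM2.5 (optionally two-segment around
  9 µg/m³), linear in the true weighted decile index, or linear in
  per-stratum SD-standardized source scores. The defaults for each
  mechanism's effect sizes are the published estimates the pipeline is
  asked to recover. A single mechanism per config keeps every stage's
  truth identifiable; mixing them would make each single-stage estimand
  a blend.

What the generator does **not** emulate: spatial geometry (regions are
round-robin labels, not polygons), exposure measurement error from
grid-to-ZIP aggregation, ICD-coded record-level outcomes, migration between
ZIPs, and real constituent correlation structure beyond the five-source
factor model. Passing recovery tests therefore demonstrates correctness of
the estimators under the stated generative assumptions, not robustness to
everything real panels do.

## Problem sizes and numerical choices

Recovery runs use 1,200 ZIPs × 17 years (20,400 zip-years, 25 replicates)
for the single-pollutant and WQS stages, and 300 ZIPs × 17 years across the
9 strata (10 replicates) for the apportionment chain; the coverage study
uses 200 replicates of 120 ZIPs × 6 years. These sizes give Monte-Carlo
error comfortably below the tolerances being checked while keeping a full
run on a laptop-scale machine.

Seeds flow from a single integer through `numpy.random.SeedSequence`; the
same seed reproduces every number, including CSV bytes. Optimizer
tolerances: 1e-8 (WQS objective), 1e-10 (IRLS), NMF tol 1e-6 with 2,000
iterations by default. Degenerate inputs fail loudly: constant constituent
columns (unquantizable), singular designs (collinear columns named),
empty restrictions, non-positive SEs in pooling.

## Known limitations

* CR0 cluster-robust variance is mildly anti-conservative below ~50
  clusters; no small-sample correction (CR2/CR3) is implemented.
* WQS inference on the final index treats the aggregated weights as fixed;
  weight-estimation uncertainty is visible in the bootstrap weight matrix
  but not propagated into the index CI (standard WQS practice).
* NMF factors are identified only up to the quality of the tracer
  separation; heavily overlapping sources (coal vs oil, both
  sulfate-bearing) rely on the trace elements and degrade gracefully to
  `unassigned` rather than mislabeling.
* DerSimonian–Laird tau² is noisy at k = 9 strata; an REML estimator is
  available (`method="reml"`) but the default and all reported numbers use
  the moment estimator.
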