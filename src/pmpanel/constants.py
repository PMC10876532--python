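"""Shared vocabulary: constituent names, sources, outcomes, tracer rules.

The 15 PM2.5 constituents are the species with national annual exposure
surfaces: carbonaceous fractions (EC, OC), secondary inorganic ions
(NH4, NO3, SO4) and trace elements (Br, Ca, Cu, Fe, K, Ni, Pb, Si, V, Zn).
"""

from __future__ import annotations

#: Canonical constituent order used by every matrix in the package.
CONSTITUENTS = (
    "EC", "NH4", "NO3", "OC", "SO4",
    "Br", "Ca", "Cu", "Fe", "K",
    "Ni", "Pb", "Si", "V", "Zn",
)

#: Outcome categories (admission-count columns are ``count_<outcome>``).
OUTCOMES = ("non_respiratory", "cns", "intestinal", "urinary", "septicemia")

#: Continuous ZIP-level covariates carried by the synthetic panel
#: (standardized scale; calendar year enters models as indicators).
COVARIATES = ("pct_female", "pct_poverty", "pct_smokers", "log_income", "winter_tmax")

#: Source labels used in apportionment.
SOURCE_LABELS = (
    "coal burning",
    "traffic",
    "oil combustion",
    "soil",
    "biomass burning",
    "regionally transported nitrate",
)

UNASSIGNED = "unassigned"

#: Tracer rule table: label -> diagnostic constituents. A factor earns a
#: label when its loading on the tracers is enriched relative to the mean
#: loading of those tracers across factors (receptor-modelling practice:
#: Ni/V mark residual-oil combustion, SO4(+NH4) coal, Cu/Fe/Zn/EC
#: brake-and-tailpipe traffic, Si/Ca crustal dust, K/OC biomass smoke,
#: NO3/NH4 transported ammonium nitrate).
TRACER_RULES = {
    "oil combustion": ("Ni", "V"),
    "coal burning": ("SO4", "NH4"),
    "traffic": ("Cu", "Fe", "Zn", "EC"),
    "soil": ("Si", "Ca"),
    "biomass burning": ("K", "OC"),
    "regionally transported nitrate": ("NO3", "NH4"),
}

#: Analysis time periods (inclusive year ranges).
PERIODS = ((2000, 2005), (2006, 2010), (2011, 2016))
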