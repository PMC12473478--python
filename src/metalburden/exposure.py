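"""Toxicity-parameter derivation and inhalation exposure concentrations.

When a metal-disease endpoint has no published inhalation unit risk (IUR),
one is derived from its LOAEL by the standard chain

    NOAEL = LOAEL / 3.81,   BMC10 = 1.96 x NOAEL,   IUR = 0.10 / BMC10,

all on the ug/m^3 scale. Exposure concentrations are lifetime-averaged
fractions of the ambient mean C (ng/m^3):

    EC_nc = C x EF x ED / AT
    EC_c  = C x EF x (ED_<2 ADAF_<2 + ED_2-16 ADAF_2-16 + ED_>16 ADAF_>16) / LT

with EF in days/year, durations in years, AT/LT in days; with the default
constants the carcinogenic age bracket is 2x10 + 14x3 + 14x1 = 76 years.
EC stays in ng/m^3; the single ng->ug conversion happens in the excess-case
step of :mod:`metalburden.burden`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import (
    ConcentrationPanel,
    ExposureConstants,
    ToxicityRecord,
    ValidationError,
)

#: LOAEL -> NOAEL interspecies/LOAEL-to-NOAEL divisor.
LOAEL_TO_NOAEL = 3.81
#: NOAEL -> BMC10 multiplier.
NOAEL_TO_BMC10 = 1.96
#: Benchmark response used for the unit risk (10% incidence).
BENCHMARK_RESPONSE = 0.10


@dataclass(frozen=True)
class DerivedToxicity:
    """Complete toxicity chain for one metal-disease endpoint (ug/m^3 scale)."""

    metal: str
    disease: str
    carcinogenic: bool
    noael: float | None
    bmc10: float | None
    iur: float
    source_of_iur: str  # "given" | "derived"


@dataclass(frozen=True)
class ExposureResult:
    """Carcinogenic and non-carcinogenic exposure concentrations for one metal."""

    metal: str
    mean_concentration: float  # C, ng/m^3
    ec_nc: float               # ng/m^3
    ec_c: float                # ng/m^3


def derive_toxicity(rec: ToxicityRecord) -> DerivedToxicity:
    """Pass a given IUR through, or derive one from the LOAEL chain."""
    rec.validate()
    if rec.iur is not None:
        return DerivedToxicity(
            metal=rec.metal, disease=rec.disease, carcinogenic=rec.carcinogenic,
            noael=None, bmc10=None, iur=rec.iur, source_of_iur="given",
        )
    noael = rec.loael / LOAEL_TO_NOAEL
    bmc10 = NOAEL_TO_BMC10 * noael
    return DerivedToxicity(
        metal=rec.metal, disease=rec.disease, carcinogenic=rec.carcinogenic,
        noael=noael, bmc10=bmc10, iur=BENCHMARK_RESPONSE / bmc10, source_of_iur="derived",
    )


def exposure_nc(c: float, k: ExposureConstants = ExposureConstants()) -> float:
    """Non-carcinogenic exposure concentration EC_nc = C x EF x ED / AT (ng/m^3)."""
    if c < 0:
        raise ValidationError("concentration must be >= 0")
    if k.at_days <= 0:
        raise ValidationError("at_days must be > 0")
    return c * k.ef * k.ed_nc / k.at_days


def carcinogenic_age_bracket(k: ExposureConstants = ExposureConstants()) -> float:
    """ADAF-weighted exposure-duration sum (years) of the carcinogenic EC."""
    return (
        k.ed_infant * k.adaf_infant
        + k.ed_child * k.adaf_child
        + k.ed_adult * k.adaf_adult
    )


def exposure_c(c: float, k: ExposureConstants = ExposureConstants()) -> float:
    """Carcinogenic exposure concentration with early-life ADAF weighting (ng/m^3)."""
    if c < 0:
        raise ValidationError("concentration must be >= 0")
    if k.lt_days <= 0:
        raise ValidationError("lt_days must be > 0")
    return c * k.ef * carcinogenic_age_bracket(k) / k.lt_days


def exposure_for_metal(
    metal: str, c: float, k: ExposureConstants = ExposureConstants()
) -> ExposureResult:
    return ExposureResult(
        metal=metal, mean_concentration=c, ec_nc=exposure_nc(c, k), ec_c=exposure_c(c, k)
    )


def annual_mean_concentration(
    panel: ConcentrationPanel, metal: str, year: int
) -> float:
    """Calendar-year arithmetic mean of a species (ng/m^3).

    Missing cells are excluded; below-MDL cells contribute MDL/2 (the same
    substitution the receptor model uses).
    """
    if metal not in panel.species:
        raise ValidationError(f"species {metal!r} not in panel")
    in_year = panel.values.index.year == year
    vals = panel.values.loc[in_year, metal].copy()
    below = panel.below_mdl.loc[in_year, metal]
    vals.loc[below.to_numpy()] = panel.mdl[metal] / 2.0
    vals = vals.dropna()
    if vals.empty:
        raise ValidationError(f"no observations for {metal} in {year}")
    return float(vals.mean())


def annual_mean_table(panel: ConcentrationPanel) -> pd.DataFrame:
    """Annual means for every species x year with at least one observation."""
    years = sorted(set(panel.values.index.year))
    rows = []
    for year in years:
        for sp in panel.species:
            try:
                c = annual_mean_concentration(panel, sp, year)
            except ValidationError:
                continue
            rows.append({"site": panel.site_id, "year": year, "metal": sp, "mean_ngm3": c})
    return pd.DataFrame(rows)
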