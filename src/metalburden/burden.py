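"""Excess cases and DALY burden, with source/stratum attribution and aggregation.

The per-affected-individual burden of a disease is DALY_ind = YLL/N + YLD/P
(years of life lost per death plus years lived with disability per prevalent
case). Excess cases scale linearly with the exposure concentration:
NP = EC x IUR x TP, with EC converted from ng/m^3 to the IUR's ug/m^3 scale
here and nowhere else. The annualised total burden divides the lifetime-scale
case count by the life expectancy A:

    BOD = sum_endpoints NP x DALY_ind / A   (person-years per year).

Because every step is linear in the ambient concentration C, burden splits
exactly proportionally to the receptor model's per-species source shares;
stratum splits use population fraction x relative DALY weight, renormalised
to preserve totals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_data import (
    BURDEN_COLUMNS,
    BurdenTable,
    DalyWeightRecord,
    ExposureConstants,
    PopulationRecord,
    ToxicityRecord,
    ValidationError,
)
from .exposure import derive_toxicity, exposure_c, exposure_nc

#: ng/m^3 -> ug/m^3; the only unit conversion in the risk product.
NG_TO_UG = 1e-3


def daly_per_case(w: DalyWeightRecord) -> tuple[float, float, float]:
    """(YLL per death, YLD per prevalent case, their sum) for one disease."""
    w.validate()
    yll_ind = w.yll_total / w.deaths if w.yll_total > 0 else 0.0
    yld_ind = w.yld_total / w.prevalent_cases if w.yld_total > 0 else 0.0
    return yll_ind, yld_ind, yll_ind + yld_ind


def excess_cases(ec: float, iur: float, tp: float, carcinogenic: bool = False) -> float:
    """Excess cases NP = (EC in ug/m^3) x IUR x TP.

    The caller passes EC_c for carcinogenic endpoints and EC_nc otherwise;
    the formula itself is identical for both.
    """
    if ec < 0 or iur < 0 or tp < 0:
        raise ValidationError("ec, iur and tp must all be >= 0")
    return ec * NG_TO_UG * iur * tp


def burden_row(
    city: str, year: int, metal: str, disease: str, cases: float,
    daly_ind: float, a: float, tp: float,
    source: str = "total", stratum: str = "all",
) -> dict:
    """One burden record: annualised DALYs = cases x DALY_ind / A."""
    if a <= 0:
        raise ValidationError("life expectancy A must be > 0")
    dalys = cases * daly_ind / a
    return {
        "city": city, "year": year, "metal": metal, "disease": disease,
        "source": source, "stratum": stratum,
        "excess_cases": cases, "dalys": dalys,
        "dalys_per_1000": 1000.0 * dalys / tp,
    }


def total_burden(
    city: str,
    year: int,
    cases: Mapping[tuple[str, str], float],
    daly_ind: Mapping[str, float],
    a: float,
    tp: float,
) -> BurdenTable:
    """Per-(metal, disease) annualised burden rows (source='total', stratum='all')."""
    if a <= 0:
        raise ValidationError("life expectancy A must be > 0")
    rows = [
        burden_row(city, year, metal, disease, n, daly_ind[disease], a, tp)
        for (metal, disease), n in cases.items()
    ]
    if not rows:
        raise ValidationError("no burden rows to compute")
    return BurdenTable(pd.DataFrame(rows))


def burden_for_city_year(
    city: str,
    year: int,
    mean_concentrations: Mapping[str, float],
    toxicity: Sequence[ToxicityRecord],
    daly_weights: Sequence[DalyWeightRecord],
    population: PopulationRecord,
    constants: ExposureConstants = ExposureConstants(),
) -> BurdenTable:
    """Full chain for one city-year: C -> EC -> excess cases -> DALYs.

    Carcinogenic endpoints use EC_c, non-carcinogenic EC_nc; endpoints whose
    metal has no concentration in ``mean_concentrations`` are skipped.
    """
    population.validate()
    daly_ind = {w.disease: daly_per_case(w)[2] for w in daly_weights}
    cases: dict[tuple[str, str], float] = {}
    for rec in toxicity:
        if rec.metal not in mean_concentrations or rec.disease not in daly_ind:
            continue
        c = mean_concentrations[rec.metal]
        tox = derive_toxicity(rec)
        ec = exposure_c(c, constants) if rec.carcinogenic else exposure_nc(c, constants)
        cases[(rec.metal, rec.disease)] = excess_cases(
            ec, tox.iur, population.total_population, rec.carcinogenic
        )
    return total_burden(
        city, year, cases, daly_ind, population.life_expectancy,
        population.total_population,
    )


# ---------------------------------------------------------------------------
# Attribution
# ---------------------------------------------------------------------------

def attribute_burden_to_sources(
    table: BurdenTable, species_shares: pd.DataFrame
) -> BurdenTable:
    """Split each total burden row across emission sources by per-species shares.

    ``species_shares`` has species rows and source columns summing to 1 per
    row. Exact proportional attribution is valid because burden is linear in
    the ambient concentration, hence in each source's contribution to it.
    The source='total' rows are preserved alongside the split rows.
    """
    totals = table.data[table.data["source"] == "total"]
    if totals.empty:
        raise ValidationError("no total rows to attribute")
    rows = [totals]
    for _, row in totals.iterrows():
        metal = row["metal"]
        if metal not in species_shares.index:
            raise ValidationError(f"no source shares for species {metal!r}")
        shares = species_shares.loc[metal]
        if abs(shares.sum() - 1.0) > 1e-6:
            raise ValidationError(f"shares for {metal!r} sum to {shares.sum()}, not 1")
        split = pd.DataFrame([row] * len(shares)).reset_index(drop=True)
        split["source"] = shares.index.to_numpy()
        for col in ("excess_cases", "dalys", "dalys_per_1000"):
            split[col] = row[col] * shares.to_numpy()
        rows.append(split)
    return BurdenTable(pd.concat(rows, ignore_index=True))


def stratify_burden(
    table: BurdenTable,
    population: PopulationRecord,
    stratum_weights: Mapping[tuple[str, str], float],
) -> BurdenTable:
    """Split stratum='all' rows by population share x relative DALY weight.

    Split fractions are renormalised so each stratum set sums exactly to its
    'all' row; the 'all' rows are preserved.
    """
    population.validate()
    if not population.strata:
        raise ValidationError(f"{population.city}: no strata defined")
    raw = np.array(
        [frac * stratum_weights.get((sex, band), 0.0)
         for sex, band, frac in population.strata]
    )
    if raw.sum() <= 0:
        raise ValidationError("stratum weights sum to zero")
    fractions = raw / raw.sum()

    alls = table.data[table.data["stratum"] == "all"]
    rows = [alls]
    labels = [f"{sex}:{band}" for sex, band, _ in population.strata]
    for _, row in alls.iterrows():
        split = pd.DataFrame([row] * len(labels)).reset_index(drop=True)
        split["stratum"] = labels
        for col in ("excess_cases", "dalys", "dalys_per_1000"):
            split[col] = row[col] * fractions
        rows.append(split)
    return BurdenTable(pd.concat(rows, ignore_index=True))


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

@dataclass
class CityYearSummary:
    """City x year DALYs-per-1000 matrix with its marginal means."""

    table: pd.DataFrame      # index: city, columns: year, NaN where no data
    year_means: pd.Series    # unweighted mean across cities reporting that year
    city_means: pd.Series    # per-city mean across available years


def aggregate_city_year(data: BurdenTable | pd.DataFrame) -> CityYearSummary:
    """Summarise total burden per city-year and its marginal means.

    Accepts either a burden table (total/all rows are summed over metals and
    diseases per city-year) or an already-summed long frame with columns
    city, year, dalys_per_1000. Years missing for a city stay NA and are
    excluded from both the yearly mean across cities and the multi-year city
    mean.
    """
    if isinstance(data, BurdenTable):
        sub = data.data
        sub = sub[(sub["source"] == "total") & (sub["stratum"] == "all")]
        long = sub.groupby(["city", "year"], sort=False)["dalys_per_1000"].sum().reset_index()
    else:
        long = data[["city", "year", "dalys_per_1000"]].dropna(subset=["dalys_per_1000"])
    if long.empty:
        raise ValidationError("no city-year burden values to aggregate")
    pivot = long.pivot(index="city", columns="year", values="dalys_per_1000")
    pivot = pivot.reindex(index=pd.unique(long["city"]))
    return CityYearSummary(
        table=pivot,
        year_means=pivot.mean(axis=0, skipna=True),
        city_means=pivot.mean(axis=1, skipna=True),
    )
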