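"""Domain types and CSV readers/writers for PM2.5-bound-metal panels and tables.

All concentration values are ng/m^3; toxicity parameters (LOAEL, BMC10, IUR)
are on the ug/m^3 scale used by inhalation toxicology databases. The single
ng->ug conversion in the whole pipeline happens inside the excess-case
computation in :mod:`metalburden.burden`.

Files are plain CSV (UTF-8, "." decimal separator); an empty value cell means
a missing observation. Timestamps are ISO-8601 text in files and pandas
``DatetimeIndex`` in memory; time zones are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The 17 metals monitored in the study, in canonical order.
DEFAULT_SPECIES: tuple[str, ...] = (
    "Si", "K", "Ca", "Cr", "Mn", "Co", "Ni", "Cu", "Zn",
    "As", "Ag", "Cd", "Sn", "Sb", "Ba", "Pb", "Hg",
)

#: Emission-source categories resolved by the receptor model.
SOURCE_NAMES: tuple[str, ...] = (
    "vehicle", "fuel oil", "industrial", "dust", "coal/biomass",
)

REGION_CLASSES = ("inland", "coastal")

# Municipal heating window (northern-China convention), inclusive.
HEATING_SEASON_START = (11, 15)  # (month, day)
HEATING_SEASON_END = (3, 15)


class SchemaError(ValueError):
    """A CSV does not expose a required column."""


class ValidationError(ValueError):
    """Input data violates a domain-type invariant."""


def canonical_species(name: str) -> str:
    """Trim whitespace; element symbols are case-sensitive after trimming."""
    return name.strip()


def heating_season_mask(
    timestamps: pd.DatetimeIndex,
    start: tuple[int, int] = HEATING_SEASON_START,
    end: tuple[int, int] = HEATING_SEASON_END,
) -> pd.Series:
    """Boolean mask of time points inside the (possibly year-wrapping) heating window."""
    md = list(zip(timestamps.month, timestamps.day))
    if start > end:  # wraps over new year, e.g. 15 Nov - 15 Mar
        vals = [(m, d) >= start or (m, d) <= end for m, d in md]
    else:
        vals = [start <= (m, d) <= end for m, d in md]
    return pd.Series(vals, index=timestamps)


# ---------------------------------------------------------------------------
# Concentration panel
# ---------------------------------------------------------------------------

@dataclass
class ConcentrationPanel:
    """Site x time x species concentration matrix with detection limits.

    ``values`` holds concentrations in ng/m^3 with NaN at missing cells
    (``missing_mask`` mirrors that). Cells flagged in ``below_mdl`` retain the
    generated/raw value; any substitution policy (e.g. MDL/2 for the receptor
    model) is applied downstream, never at storage time.
    """

    site_id: str
    values: pd.DataFrame                 # index: DatetimeIndex, columns: species
    mdl: pd.Series                       # per-species MDL, ng/m^3
    below_mdl: pd.DataFrame              # bool, same shape as values
    region_class: str = "inland"
    heating_mask: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.heating_mask is None:
            self.heating_mask = heating_season_mask(self.values.index)

    @property
    def species(self) -> list[str]:
        return list(self.values.columns)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.values.index

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_times(self) -> int:
        return len(self.values.index)

    def validate(self) -> "ConcentrationPanel":
        """Check every type invariant; raise :class:`ValidationError` on the first failure."""
        if self.region_class not in REGION_CLASSES:
            raise ValidationError(f"region_class must be one of {REGION_CLASSES}")
        if len(set(self.species)) != len(self.species):
            raise ValidationError("species names must be unique")
        if not self.values.index.is_monotonic_increasing or self.values.index.has_duplicates:
            raise ValidationError("timestamps must be strictly increasing")
        if not (self.mdl.reindex(self.species) > 0).all():
            raise ValidationError("mdl must be > 0 for every species")
        obs = self.values.to_numpy()
        neg = np.nan_to_num(obs, nan=0.0) < 0
        if neg.any():
            i, j = np.argwhere(neg)[0]
            raise ValidationError(
                f"negative concentration at {self.values.index[i]} / {self.species[j]}"
            )
        if self.below_mdl.shape != self.values.shape:
            raise ValidationError("below_mdl mask shape mismatch")
        return self

    def working_values(self) -> pd.DataFrame:
        """Concentrations with the receptor-model substitution policy applied.

        Below-MDL cells are replaced by MDL/2 and missing cells by the species
        median of the observed values (EPA PMF user-guide conventions).
        """
        out = self.values.copy()
        for sp in self.species:
            col = out[sp].copy()
            col.loc[self.below_mdl[sp]] = self.mdl[sp] / 2.0
            med = col.median(skipna=True)
            if np.isnan(med):
                med = self.mdl[sp] / 2.0
            out[sp] = col.fillna(med)
        return out


@dataclass
class UncertaintyMatrix:
    """Per-cell measurement uncertainty u_ij (ng/m^3) matching a panel."""

    values: pd.DataFrame
    error_fraction: float = 0.05

    def validate(self, panel: ConcentrationPanel | None = None) -> "UncertaintyMatrix":
        if not (self.values.to_numpy() > 0).all():
            raise ValidationError("uncertainty must be strictly positive everywhere")
        if panel is not None and self.values.shape != panel.values.shape:
            raise ValidationError("uncertainty shape must match its panel")
        return self


# ---------------------------------------------------------------------------
# Toxicity / demographic records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToxicityRecord:
    """One metal-disease endpoint: either a LOAEL (ug/m^3) or a ready IUR (per ug/m^3)."""

    metal: str
    disease: str
    carcinogenic: bool
    loael: float | None = None
    iur: float | None = None

    @property
    def derivation(self) -> str:
        return "given_iur" if self.iur is not None else "derived_from_loael"

    def validate(self) -> "ToxicityRecord":
        if self.loael is None and self.iur is None:
            raise ValidationError(f"{self.metal}/{self.disease}: need LOAEL or IUR")
        if self.loael is not None and self.loael <= 0:
            raise ValidationError(f"{self.metal}/{self.disease}: LOAEL must be > 0")
        if self.iur is not None and self.iur <= 0:
            raise ValidationError(f"{self.metal}/{self.disease}: IUR must be > 0")
        return self


@dataclass(frozen=True)
class PopulationRecord:
    """City population with an optional sex x age-band breakdown (fractions sum to 1)."""

    city: str
    total_population: float
    life_expectancy: float = 79.18
    strata: tuple[tuple[str, str, float], ...] = ()  # (sex, age_band, fraction)

    def validate(self) -> "PopulationRecord":
        if self.total_population <= 0:
            raise ValidationError(f"{self.city}: total_population must be > 0")
        if self.life_expectancy <= 0:
            raise ValidationError(f"{self.city}: life_expectancy must be > 0")
        if self.strata:
            tot = sum(f for _, _, f in self.strata)
            if abs(tot - 1.0) > 1e-9:
                raise ValidationError(f"{self.city}: stratum fractions sum to {tot}, not 1")
        return self


@dataclass(frozen=True)
class DalyWeightRecord:
    """GBD-style burden weights for one disease.

    ``yll_total``/``deaths`` and ``yld_total``/``prevalent_cases`` give the
    per-affected-individual years lost / lived with disability; see
    :func:`metalburden.burden.daly_per_case`.
    """

    disease: str
    yll_total: float
    yld_total: float
    deaths: float
    prevalent_cases: float
    stratum_weights: Mapping[tuple[str, str], float] | None = None

    def validate(self) -> "DalyWeightRecord":
        for name in ("yll_total", "yld_total", "deaths", "prevalent_cases"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{self.disease}: {name} must be >= 0")
        if self.yll_total > 0 and self.deaths <= 0:
            raise ValidationError(f"{self.disease}: YLL > 0 requires deaths > 0")
        if self.yld_total > 0 and self.prevalent_cases <= 0:
            raise ValidationError(f"{self.disease}: YLD > 0 requires prevalent cases > 0")
        return self


@dataclass(frozen=True)
class ExposureConstants:
    """EPA-style inhalation exposure factors.

    ef is exposure frequency in days/year; durations in years; ADAF are the
    age-dependent adjustment factors for the <2 / 2-16 / >16 carcinogenic
    exposure windows; at_days and lt_days the averaging and lifetime windows.
    """

    ef: float = 350.0
    ed_nc: float = 30.0
    ed_infant: float = 2.0
    ed_child: float = 14.0
    ed_adult: float = 14.0
    adaf_infant: float = 10.0
    adaf_child: float = 3.0
    adaf_adult: float = 1.0
    at_days: float = 30.0 * 365.0
    lt_days: float = 79.18 * 365.0

    def validate(self) -> "ExposureConstants":
        if not (0 < self.ef <= 366):
            raise ValidationError("ef must be in (0, 366] days/year")
        for name in ("ed_nc", "ed_infant", "ed_child", "ed_adult", "at_days", "lt_days"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        for name in ("adaf_infant", "adaf_child", "adaf_adult"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        return self


# ---------------------------------------------------------------------------
# Burden table
# ---------------------------------------------------------------------------

BURDEN_COLUMNS = (
    "city", "year", "metal", "disease", "source", "stratum",
    "excess_cases", "dalys", "dalys_per_1000",
)


@dataclass
class BurdenTable:
    """Long-format excess cases and DALYs indexed by city/year/metal/disease/source/stratum."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(BURDEN_COLUMNS) - set(self.data.columns)
        if missing:
            raise SchemaError(f"burden table missing columns: {sorted(missing)}")
        self.data = self.data[list(BURDEN_COLUMNS)].reset_index(drop=True)

    def validate(self, rel_tol: float = 1e-9) -> "BurdenTable":
        num = self.data[["excess_cases", "dalys", "dalys_per_1000"]].to_numpy()
        if (num < 0).any():
            raise ValidationError("burden quantities must be >= 0")
        split = self.data[self.data["source"] != "total"]
        if not split.empty:
            keys = ["city", "year", "metal", "disease", "stratum"]
            sums = split.groupby(keys)["dalys"].sum()
            totals = (
                self.data[self.data["source"] == "total"]
                .set_index(keys)["dalys"]
            )
            joined = pd.concat([sums, totals], axis=1, keys=["split", "total"]).dropna()
            bad = ~np.isclose(joined["split"], joined["total"], rtol=rel_tol, atol=1e-300)
            if bad.any():
                raise ValidationError("source rows do not sum to their total row")
        return self


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_PANEL_SCHEMA = {
    "site": "site", "timestamp": "timestamp", "species": "species", "value": "value",
    "mdl": "mdl", "below_mdl": "below_mdl", "region_class": "region_class",
}


def read_concentration_csv(
    path,
    schema: Mapping[str, str] | None = None,
    mdl: Mapping[str, float] | None = None,
    region_class: str | None = None,
) -> ConcentrationPanel:
    """Read a single-site long-format concentration CSV.

    Required columns (via ``schema`` mapping logical -> actual names): site,
    timestamp, species, value. Optional: mdl, below_mdl, region_class; per-species
    MDLs may instead be passed as the ``mdl`` argument.
    An empty value cell marks a missing observation.
    """
    sch = dict(_PANEL_SCHEMA)
    if schema:
        sch.update(schema)
    df = pd.read_csv(path, dtype={sch["site"]: str})
    for logical in ("site", "timestamp", "species", "value"):
        if sch[logical] not in df.columns:
            raise SchemaError(f"required column {sch[logical]!r} ({logical}) not in {path}")

    sites = df[sch["site"]].unique()
    if len(sites) != 1:
        raise ValidationError(f"expected one site per file, found {list(sites)}")
    site = sites[0]

    df = df.copy()
    df[sch["species"]] = df[sch["species"]].map(canonical_species)
    df[sch["timestamp"]] = pd.to_datetime(df[sch["timestamp"]])
    dup = df.duplicated([sch["site"], sch["timestamp"], sch["species"]])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"duplicate (site, timestamp, species) entry: "
            f"({row[sch['site']]}, {row[sch['timestamp']]}, {row[sch['species']]})"
        )
    neg = df[sch["value"]] < 0
    if neg.any():
        raise ValidationError(f"negative concentration in row {int(np.flatnonzero(neg)[0])}")

    species = list(dict.fromkeys(df[sch["species"]]))
    values = df.pivot(index=sch["timestamp"], columns=sch["species"], values=sch["value"])
    values = values.reindex(columns=species).sort_index()
    values.index.name = None
    values.columns.name = None

    if sch["below_mdl"] in df.columns:
        bm = df.pivot(index=sch["timestamp"], columns=sch["species"], values=sch["below_mdl"])
        bm = bm.reindex(columns=species).sort_index().fillna(False).astype(bool)
        bm.index.name = None
        bm.columns.name = None
    else:
        bm = pd.DataFrame(False, index=values.index, columns=values.columns)

    if mdl is not None:
        mdl_s = pd.Series({sp: float(mdl[sp]) for sp in species})
    elif sch["mdl"] in df.columns:
        mdl_s = df.groupby(sch["species"])[sch["mdl"]].first().reindex(species)
    else:
        raise SchemaError("no MDL column in file and no mdl mapping supplied")

    if region_class is None:
        region_class = (
            str(df[sch["region_class"]].iloc[0]) if sch["region_class"] in df.columns else "inland"
        )

    return ConcentrationPanel(
        site_id=str(site), values=values, mdl=mdl_s, below_mdl=bm, region_class=region_class
    ).validate()


def write_concentration_csv(panel: ConcentrationPanel, path) -> None:
    """Write a panel as a long-format CSV that round-trips through the reader."""
    n, m = panel.values.shape
    long = pd.DataFrame(
        {
            "site": panel.site_id,
            "timestamp": np.repeat(panel.values.index, m),
            "species": np.tile(panel.species, n),
            "value": panel.values.to_numpy().ravel(),
            "below_mdl": panel.below_mdl.to_numpy().ravel(),
        }
    )
    long["mdl"] = long["species"].map(panel.mdl)
    long["region_class"] = panel.region_class
    long["timestamp"] = long["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    long.to_csv(path, index=False, float_format="%.12g")


def write_burden_csv(table: BurdenTable, path) -> None:
    """Write a burden table; numeric fields keep 12 significant digits."""
    if table.data.empty:
        raise ValidationError("refusing to write an empty burden table")
    table.data.to_csv(path, index=False, float_format="%.12g")


def read_burden_csv(path) -> BurdenTable:
    df = pd.read_csv(path)
    return BurdenTable(df)


def write_toxicity_csv(records: Sequence[ToxicityRecord], path) -> None:
    rows = [
        {
            "metal": r.metal, "disease": r.disease, "carcinogenic": r.carcinogenic,
            "loael": r.loael, "iur": r.iur,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_toxicity_csv(path) -> list[ToxicityRecord]:
    df = pd.read_csv(path)
    for col in ("metal", "disease", "carcinogenic"):
        if col not in df.columns:
            raise SchemaError(f"toxicity table missing column {col!r}")
    out = []
    for _, row in df.iterrows():
        out.append(
            ToxicityRecord(
                metal=canonical_species(str(row["metal"])),
                disease=str(row["disease"]),
                carcinogenic=bool(row["carcinogenic"]),
                loael=None if pd.isna(row.get("loael")) else float(row["loael"]),
                iur=None if pd.isna(row.get("iur")) else float(row["iur"]),
            ).validate()
        )
    return out


def write_daly_weights_csv(records: Sequence[DalyWeightRecord], path) -> None:
    rows = [
        {
            "disease": r.disease, "yll_total": r.yll_total, "yld_total": r.yld_total,
            "deaths": r.deaths, "prevalent_cases": r.prevalent_cases,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_daly_weights_csv(path) -> list[DalyWeightRecord]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(
            DalyWeightRecord(
                disease=str(row["disease"]),
                yll_total=float(row["yll_total"]),
                yld_total=float(row["yld_total"]),
                deaths=float(row["deaths"]),
                prevalent_cases=float(row["prevalent_cases"]),
            ).validate()
        )
    return out


def write_population_csv(records: Sequence[PopulationRecord], path) -> None:
    rows = []
    for r in records:
        strata = r.strata or (("all", "all", 1.0),)
        for sex, band, frac in strata:
            rows.append(
                {
                    "city": r.city, "total_population": r.total_population,
                    "life_expectancy": r.life_expectancy,
                    "sex": sex, "age_band": band, "fraction": frac,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_population_csv(path) -> list[PopulationRecord]:
    df = pd.read_csv(path)
    out = []
    for city, grp in df.groupby("city", sort=False):
        strata = tuple(
            (str(r["sex"]), str(r["age_band"]), float(r["fraction"])) for _, r in grp.iterrows()
        )
        if len(strata) == 1 and strata[0][:2] == ("all", "all"):
            strata = ()
        out.append(
            PopulationRecord(
                city=str(city),
                total_population=float(grp["total_population"].iloc[0]),
                life_expectancy=float(grp["life_expectancy"].iloc[0]),
                strata=strata,
            ).validate()
        )
    return out
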