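"""Burden arithmetic, conservation under splits, and city-year aggregation."""

import numpy as np
import pandas as pd
import pytest

import metalburden as mb
from metalburden.core_data import DalyWeightRecord, PopulationRecord, ValidationError
from metalburden import synthetic as syn

from conftest import city_year_frame


def test_daly_per_case_arithmetic():
    w = DalyWeightRecord("d", yll_total=1000, yld_total=500, deaths=100, prevalent_cases=250)
    yll, yld, total = mb.daly_per_case(w)
    assert (yll, yld, total) == (10.0, 2.0, 12.0)
    assert mb.daly_per_case(
        DalyWeightRecord("d", 0, 0, deaths=10, prevalent_cases=10)
    ) == (0.0, 0.0, 0.0)
    with pytest.raises(ValidationError):
        mb.daly_per_case(DalyWeightRecord("d", yll_total=10, yld_total=0, deaths=0, prevalent_cases=1))


def test_excess_cases_unit_conversion_and_linearity():
    # 1000 ng/m^3 -> 1 ug/m^3; x IUR 0.01 x 1e6 people = 10000 cases
    assert mb.excess_cases(1000.0, 0.01, 1e6) == pytest.approx(10000.0)
    assert mb.excess_cases(0.0, 0.01, 1e6) == 0.0
    assert mb.excess_cases(1000.0, 0.01, 2e6) == pytest.approx(2 * mb.excess_cases(1000.0, 0.01, 1e6))
    with pytest.raises(ValidationError):
        mb.excess_cases(-1.0, 0.01, 1e6)


def test_total_burden_rows():
    table = mb.total_burden(
        "X", 2022, {("Cd", "ckd"): 100.0}, {"ckd": 12.0}, a=79.18, tp=1e6
    )
    row = table.data.iloc[0]
    assert row["dalys"] == pytest.approx(100 * 12 / 79.18)
    assert row["dalys_per_1000"] == pytest.approx(1000 * row["dalys"] / 1e6, rel=1e-12)
    with pytest.raises(ValidationError):
        mb.total_burden("X", 2022, {}, {}, a=79.18, tp=1e6)
    with pytest.raises(ValidationError):
        mb.total_burden("X", 2022, {("Cd", "ckd"): 1.0}, {"ckd": 1.0}, a=0.0, tp=1e6)


def _simple_table():
    return mb.total_burden(
        "X", 2022,
        {("Cd", "ckd"): 80.0, ("Pb", "ckd"): 20.0},
        {"ckd": 10.0}, a=79.18, tp=1e6,
    )


def test_attribution_proportionality_and_conservation():
    shares = pd.DataFrame(
        {"industrial": [0.25, 1.0], "dust": [0.75, 0.0]}, index=["Cd", "Pb"]
    )
    out = mb.attribute_burden_to_sources(_simple_table(), shares)
    cd = out.data[(out.data.metal == "Cd") & (out.data.source != "total")]
    np.testing.assert_allclose(
        sorted(cd["dalys"]), sorted([0.25, 0.75] * np.array(80.0 * 10 / 79.18))
    )
    out.validate()  # source rows sum to totals within 1e-9 relative
    pb = out.data[(out.data.metal == "Pb") & (out.data.source == "industrial")]
    total_pb = out.data[(out.data.metal == "Pb") & (out.data.source == "total")]
    assert pb["dalys"].iloc[0] == total_pb["dalys"].iloc[0]  # single-source passthrough
    with pytest.raises(ValidationError):
        mb.attribute_burden_to_sources(_simple_table(), shares.drop("Pb"))


def test_stratification_preserves_totals():
    pop = PopulationRecord(
        "X", 1e6, strata=(("male", "adult", 0.5), ("female", "adult", 0.5))
    )
    out = mb.stratify_burden(_simple_table(), pop, {("male", "adult"): 1.0, ("female", "adult"): 1.0})
    split = out.data[out.data.stratum != "all"]
    alls = out.data[out.data.stratum == "all"]
    # uniform weights, equal strata: 50/50
    np.testing.assert_allclose(
        split.groupby("metal")["dalys"].max(), split.groupby("metal")["dalys"].min()
    )
    np.testing.assert_allclose(
        split.groupby("metal")["dalys"].sum().sort_index(),
        alls.groupby("metal")["dalys"].sum().sort_index(),
        rtol=1e-12,
    )
    with pytest.raises(ValidationError):
        mb.stratify_burden(_simple_table(), pop, {("male", "adult"): 0.0, ("female", "adult"): 0.0})


def test_elderly_weight_share_flows_through():
    """A stratum holding 1/6 of the weighted burden receives ~16.67% of DALYs."""
    pop = PopulationRecord(
        "X", 1e6,
        strata=(("all", "young", 0.5), ("all", "mid", 0.3), ("all", "65+", 0.2)),
    )
    weights = {("all", "young"): 0.5, ("all", "mid"): 1.0 / 3.0, ("all", "65+"): 5.0 / 6.0}
    # raw stratum masses: .25, .1, 1/6 -> elderly share = (1/6)/(sum)
    out = mb.stratify_burden(_simple_table(), pop, weights)
    split = out.data[out.data.stratum != "all"]
    share = (
        split[split.stratum == "all:65+"]["dalys"].sum() / split["dalys"].sum()
    )
    raw = {"young": 0.25, "mid": 0.1, "eld": 1.0 / 6.0}
    assert share == pytest.approx(raw["eld"] / sum(raw.values()), rel=1e-9)


def test_burden_linearity_in_concentration(toxicity_records, daly_records, population_record):
    conc = {"Cd": 25.0, "Cr": 6.12, "Pb": 40.0, "Ni": 8.0, "Co": 1.2, "As": 7.0, "Sb": 3.0}
    base = mb.burden_for_city_year("X", 2022, conc, toxicity_records, daly_records, population_record)
    doubled = mb.burden_for_city_year(
        "X", 2022, {k: 2 * v for k, v in conc.items()},
        toxicity_records, daly_records, population_record,
    )
    np.testing.assert_array_equal(doubled.data["dalys"], 2 * base.data["dalys"])
    np.testing.assert_array_equal(doubled.data["excess_cases"], 2 * base.data["excess_cases"])


def test_aggregate_city_year_passthrough_and_errors():
    one = pd.DataFrame([{"city": "A", "year": 2022, "dalys_per_1000": 1.5}])
    summary = mb.aggregate_city_year(one)
    assert summary.year_means[2022] == 1.5
    assert summary.city_means["A"] == 1.5
    with pytest.raises(ValidationError):
        mb.aggregate_city_year(pd.DataFrame(columns=["city", "year", "dalys_per_1000"]))


def test_aggregate_excludes_missing_years():
    summary = mb.aggregate_city_year(city_year_frame())
    # city with partial coverage averages only observed years
    assert summary.city_means["Weifang"] == pytest.approx((2.44 + 3.52) / 2)
    assert np.isnan(summary.table.loc["Weifang", 2024])
    # yearly mean over only the cities reporting that year
    assert summary.year_means[2022] == pytest.approx(
        np.mean([3.60, 2.31, 1.01, 1.05, 0.62, 0.80, 2.15, 0.93, 2.44, 1.75])
    )
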