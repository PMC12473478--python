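import numpy as np
import pandas as pd
import pytest

import metalburden as mb
from metalburden import synthetic as syn

# City-year DALYs-per-1000 input for the aggregation reproduction checks
# (NaN = city not monitored that year).
CITY_YEAR_DALYS = {
    "Zibo": {2022: 3.60, 2023: 3.55, 2024: 4.19},
    "Zaozhuang": {2022: 2.31, 2023: 1.78, 2024: 1.52},
    "Jinan": {2022: 1.01, 2023: 3.57, 2024: 9.44},
    "Linyi": {2022: 1.05, 2023: 1.31, 2024: 0.92},
    "Heze": {2022: 0.62, 2023: 0.95, 2024: 0.78},
    "Dongying": {2022: 0.80, 2023: 1.00, 2024: 0.81},
    "Binzhou": {2022: 2.15, 2023: 1.46, 2024: 2.64},
    "Liaocheng": {2022: 0.93, 2023: 0.95, 2024: 1.00},
    "Weifang": {2022: 2.44, 2023: 3.52},
    "Taian": {2023: 1.80, 2024: 1.44},
    "Rizhao": {2023: 3.01, 2024: 2.58},
    "Qingdao": {2023: 1.55, 2024: 2.58},
    "Dezhou": {2022: 1.75, 2023: 1.96},
    "Weihai": {2024: 1.05},
    "Yantai": {2024: 0.82},
}


def city_year_frame() -> pd.DataFrame:
    rows = [
        {"city": city, "year": year, "dalys_per_1000": v}
        for city, years in CITY_YEAR_DALYS.items()
        for year, v in years.items()
    ]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_panel() -> mb.ConcentrationPanel:
    """Fast inland panel for unit tests (120 days, default noise)."""
    return mb.generate_panel(site_id="unit-site", n_times=120, seed=3)


@pytest.fixture(scope="session")
def recovery_setup():
    """Acceptance-scale panel (5 sources, 17 species, 500 days, CV=0.05) and its fit."""
    panel = mb.generate_panel(site_id="recovery", n_times=500, noise_cv=0.05, seed=1)
    u = mb.build_uncertainty(panel)
    model = mb.fit_pmf(panel, u=u, p=5, restarts=10, seed=1, max_iter=300)
    return panel, u, model


@pytest.fixture(scope="session")
def toxicity_records():
    return syn.make_toxicity_fixture()


@pytest.fixture(scope="session")
def daly_records():
    return syn.make_daly_fixture()


@pytest.fixture(scope="session")
def population_record():
    return syn.make_population_fixture()[0]
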