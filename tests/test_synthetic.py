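"""Generator properties: tracer structure, forward model, regimes, determinism."""

import numpy as np
import pandas as pd
import pytest

import metalburden as mb
from metalburden import synthetic as syn
from metalburden.core_data import ValidationError


def test_profiles_tracer_structure():
    f = syn.make_source_profiles(seed=0)
    np.testing.assert_allclose(f.sum(axis=1), 1.0, atol=1e-12)
    dust = f.loc["dust"]
    assert dust.idxmax() in ("Ca", "Si")
    # distinctness: pairwise cosine similarity below 0.9
    a = f.to_numpy()
    an = a / np.linalg.norm(a, axis=1, keepdims=True)
    cos = an @ an.T
    np.fill_diagonal(cos, 0.0)
    assert cos.max() < 0.9


def test_profiles_bad_factor_counts():
    with pytest.raises(ValidationError):
        syn.make_source_profiles(p=1)
    with pytest.raises(ValidationError):
        syn.make_source_profiles(p=6)


def test_noise_free_panel_equals_reconstruction():
    """With zero noise the observed matrix is exactly G @ F (censoring only flags)."""
    profiles = syn.make_source_profiles(seed=5)
    contrib = syn.make_contributions(60, sources=list(profiles.index), seed=5)
    truth = syn.GroundTruth(profiles=profiles, contributions=contrib, noise_cv=0.0, seed=5)
    panel = syn.simulate_panel(truth, missing_frac=0.0)
    expected = panel.truth.contributions.to_numpy() @ profiles.to_numpy()
    np.testing.assert_array_equal(panel.values.to_numpy(), expected)


def test_forward_model_q_zero_at_truth():
    """Noise-free, censor-free data reconstructs exactly: Q = 0 at the truth."""
    profiles = syn.make_source_profiles(seed=5)
    contrib = syn.make_contributions(60, sources=list(profiles.index), seed=5)
    truth = syn.GroundTruth(profiles=profiles, contributions=contrib, noise_cv=0.0, seed=5)
    panel = syn.simulate_panel(truth, mdl=pd.Series(1e-9, index=profiles.columns),
                               missing_frac=0.0)
    u = mb.build_uncertainty(panel)
    q = mb.q_statistic(
        panel.values.to_numpy(), u.values.to_numpy(),
        panel.truth.contributions.to_numpy(), profiles.to_numpy(),
    )
    assert q < 1e-16


def test_seeded_determinism():
    a = mb.generate_panel(n_times=50, seed=9)
    b = mb.generate_panel(n_times=50, seed=9)
    pd.testing.assert_frame_equal(a.values, b.values)
    pd.testing.assert_frame_equal(a.below_mdl, b.below_mdl)
    c = mb.generate_panel(n_times=50, seed=10)
    assert not a.values.equals(c.values)


def test_coastal_ni_share_exceeds_inland():
    inland = mb.generate_panel(site_id="s", region_class="inland", n_times=200, seed=4)
    coastal = mb.generate_panel(site_id="s", region_class="coastal", n_times=200, seed=4)

    def ni_share(p):
        tot = p.values.sum(axis=1)
        return float((p.values["Ni"] / tot).mean())

    assert ni_share(coastal) > ni_share(inland)


def test_heating_amplitude_monotonicity():
    """More heating-season coal burning means more K and As at inland sites."""

    def heating_means(amplitude):
        profiles = syn.make_source_profiles(seed=6)
        contrib = syn.make_contributions(365, sources=list(profiles.index), seed=6)
        truth = syn.GroundTruth(profiles=profiles, contributions=contrib, noise_cv=0.05, seed=6)
        panel = syn.simulate_panel(truth, region_class="inland",
                                   heating_amplitude=amplitude, missing_frac=0.0)
        mask = panel.heating_mask.to_numpy()
        return panel.values.loc[mask, ["K", "As"]].mean()

    low, high = heating_means(0.4), heating_means(1.2)
    assert high["K"] > low["K"]
    assert high["As"] > low["As"]
    with pytest.raises(ValidationError):
        profiles = syn.make_source_profiles(seed=6)
        contrib = syn.make_contributions(10, sources=list(profiles.index), seed=6)
        truth = syn.GroundTruth(profiles=profiles, contributions=contrib, noise_cv=0.0, seed=6)
        syn.simulate_panel(truth, heating_amplitude=-0.5)


def test_censoring_rates_in_design_band():
    """Cd/Ag/Hg censor at low single-digit to ~10% rates; major species never."""
    panel = mb.generate_panel(n_times=400, seed=1)
    frac = panel.below_mdl.mean(axis=0)
    for sp in ("Cd", "Ag", "Hg"):
        assert 0.01 <= frac[sp] <= 0.15, f"{sp}: {frac[sp]}"
    for sp in ("K", "Ca", "Zn"):
        assert frac[sp] <= 0.01


def test_toxicity_fixture_endpoint_structure():
    recs = syn.make_toxicity_fixture()
    by_disease = {}
    for r in recs:
        r.validate()
        by_disease.setdefault(r.disease, set()).add(r.metal)
    assert {"Cd", "Pb", "Cr"} <= by_disease["chronic kidney disease"]
    assert by_disease["asthma"] == {"Co"}
    # restricting the species list filters records
    only_cd = syn.make_toxicity_fixture(species=("Cd",))
    assert {r.metal for r in only_cd} == {"Cd"}
    with pytest.raises(ValidationError):
        syn.make_toxicity_fixture(species=())


def test_attribution_truth_isolates_metal():
    truth, mdl = syn.make_attribution_truth(seed=2)
    truth.validate()
    cd = truth.profiles["Cd"]
    assert cd["industrial"] > 0
    assert (cd.drop("industrial") == 0).all()
    assert (mdl > 0).all()
    # sources genuinely switch off on some days
    assert (truth.contributions.to_numpy() == 0).mean() > 0.05
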