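"""Receptor-model unit tests: uncertainty rules, Q oracle, labeling, shares."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import metalburden as mb
from metalburden import pmf as pmf_mod
from metalburden.core_data import ValidationError


# --- uncertainty rules -----------------------------------------------------

def test_uncertainty_arithmetic():
    assert pmf_mod.uncertainty_below_mdl(0.6) == pytest.approx(0.5)
    assert pmf_mod.uncertainty_above_mdl(100.0, 0.0, 0.05) == pytest.approx(5.0)
    assert pmf_mod.uncertainty_above_mdl(10.0, 2.0, 0.05) == pytest.approx(
        np.sqrt(0.25 + 1.0)
    )


def test_build_uncertainty_cell_rules(small_panel):
    u = mb.build_uncertainty(small_panel, error_fraction=0.05)
    work = small_panel.working_values()
    uu = u.values
    assert (uu.to_numpy() > 0).all()
    below = small_panel.below_mdl
    missing = small_panel.missing_mask
    plain = ~(below | missing)
    for sp in small_panel.species:
        mdl = small_panel.mdl[sp]
        if below[sp].any():
            np.testing.assert_allclose(uu.loc[below[sp], sp], 5.0 / 6.0 * mdl)
        if missing[sp].any():
            med = work[sp].median()
            np.testing.assert_allclose(uu.loc[missing[sp], sp], 4.0 * med)
        expect = np.sqrt((0.05 * small_panel.values.loc[plain[sp], sp]) ** 2 + (0.5 * mdl) ** 2)
        np.testing.assert_allclose(uu.loc[plain[sp], sp], expect, rtol=1e-12)


def test_build_uncertainty_rejects_nonpositive_mdl(small_panel):
    bad = mb.ConcentrationPanel(
        site_id="x", values=small_panel.values, mdl=small_panel.mdl * 0.0,
        below_mdl=small_panel.below_mdl,
    )
    with pytest.raises(ValidationError):
        mb.build_uncertainty(bad)


# --- Q statistic -----------------------------------------------------------

def brute_force_q(x, u, g, f):
    """Independent double-loop oracle for the weighted residual sum of squares."""
    n, m = x.shape
    total = 0.0
    for i in range(n):
        for j in range(m):
            fit = 0.0
            for k in range(g.shape[1]):
                fit += g[i, k] * f[k, j]
            total += ((x[i, j] - fit) / u[i, j]) ** 2
    return total


def test_q_simple_cases():
    x = np.array([[3.0]])
    u = np.array([[1.0]])
    g = np.array([[1.0]])
    f = np.array([[1.0]])
    assert mb.q_statistic(x, u, g, f) == pytest.approx(4.0)  # ((3-1)/1)^2
    assert mb.q_statistic(f @ g, u, f, g) == 0.0
    with pytest.raises(ValidationError):
        mb.q_statistic(x, np.zeros((1, 1)), g, f)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_q_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    x = rng.random((5, 5)) * 10
    u = rng.random((5, 5)) + 0.1
    g = rng.random((5, 2))
    f = rng.random((2, 5))
    assert mb.q_statistic(x, u, g, f) == pytest.approx(brute_force_q(x, u, g, f), rel=1e-12)


# --- solver ----------------------------------------------------------------

def _toy_panel(seed=0):
    rng = np.random.default_rng(seed)
    g = rng.random((6, 2)) * 10
    f = rng.dirichlet(np.ones(4), size=2)
    x = g @ f * rng.lognormal(0, 0.05, size=(6, 4))
    idx = pd.date_range("2022-01-01", periods=6)
    species = ["Cu", "Ni", "Cd", "Ca"]
    values = pd.DataFrame(x, index=idx, columns=species)
    mdl = pd.Series(1e-3, index=species)
    return mb.ConcentrationPanel(
        site_id="toy", values=values, mdl=mdl,
        below_mdl=pd.DataFrame(False, index=idx, columns=species),
    )


def test_fit_reports_q_consistent_with_oracle():
    panel = _toy_panel()
    u = mb.build_uncertainty(panel)
    model = mb.fit_pmf(panel, u=u, p=2, restarts=5, seed=0, max_iter=200)
    oracle = brute_force_q(
        panel.working_values().to_numpy(), u.values.to_numpy(),
        model.G.to_numpy(), model.F.to_numpy(),
    )
    assert model.Q == pytest.approx(oracle, rel=1e-8)
    assert model.validate() is model
    # monotone descent within the winning restart
    qh = np.asarray(model.q_history)
    assert (np.diff(qh) <= 1e-10).all()


def test_fit_dimension_errors():
    panel = _toy_panel()
    with pytest.raises(ValidationError):
        mb.fit_pmf(panel, p=0)
    with pytest.raises(ValidationError):
        mb.fit_pmf(panel, p=3)  # 3*(6+4) >= 24 cells


def test_renormalization_preserves_reconstruction():
    """F rows sum to 1 and G carries the scale; G @ F matches the data closely."""
    panel = _toy_panel(seed=2)
    model = mb.fit_pmf(panel, p=2, restarts=5, seed=2, max_iter=300)
    np.testing.assert_allclose(model.F.sum(axis=1), 1.0, atol=1e-9)
    recon = model.reconstruction()
    x = panel.working_values().to_numpy()
    assert np.abs(recon - x).max() / x.max() < 0.2


# --- labeling and shares ---------------------------------------------------

def test_label_factors_on_true_profiles():
    f = mb.make_source_profiles(seed=1)
    shuffled = f.iloc[[3, 1, 4, 0, 2]]
    labels = mb.label_factors(shuffled)
    assert labels == list(shuffled.index)


def test_label_ni_profile_is_fuel_oil():
    species = list(mb.DEFAULT_SPECIES)
    row = np.full((1, len(species)), 1e-4)
    row[0, species.index("Ni")] = 1.0
    f = pd.DataFrame(row / row.sum(), index=["factor_1"], columns=species)
    assert mb.label_factors(f) == ["fuel oil"]


def test_label_ties_are_deterministic():
    species = list(mb.DEFAULT_SPECIES)
    row = np.ones((2, len(species))) / len(species)
    f = pd.DataFrame(row, index=["a", "b"], columns=species)
    first = mb.label_factors(f)
    assert first == mb.label_factors(f)
    assert first[0] == "dust"  # highest-priority source goes to the first factor


def test_shares_single_source_and_normalization(recovery_setup):
    panel, u, model = recovery_setup
    per_species, total = mb.source_contribution_shares(model)
    np.testing.assert_allclose(per_species.sum(axis=1), 1.0, atol=1e-12)
    assert total.sum() == pytest.approx(1.0, abs=1e-12)

    species = list(mb.DEFAULT_SPECIES)
    one = mb.FactorModel(
        G=pd.DataFrame({"factor_1": np.ones(10)}),
        F=pd.DataFrame(np.full((1, len(species)), 1.0 / len(species)),
                       index=["factor_1"], columns=species),
        Q=0.0, Q_expected=1.0, restarts=1, best_seed=0, converged=True,
    )
    ps, tot = mb.source_contribution_shares(one)
    np.testing.assert_allclose(ps.to_numpy(), 1.0)
    np.testing.assert_allclose(tot.to_numpy(), 1.0)


def test_total_mass_share_recovery(recovery_setup):
    """Fitted total-mass source shares track the ground truth within 0.05."""
    panel, u, model = recovery_setup
    labels = mb.label_factors(model.F)
    _, total = mb.source_contribution_shares(model)
    total.index = labels
    true_shares = panel.truth.total_mass_shares()
    err = (total.reindex(true_shares.index) - true_shares).abs().max()
    assert err < 0.05
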