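"""Uncertainty-weighted positive matrix factorization (receptor model).

Decomposes a concentration panel X (n samples x m species) into nonnegative
source contributions G (n x p) and row-stochastic source profiles F (p x m)
by minimising the weighted residual sum of squares

    Q = sum_ij ( (x_ij - sum_k g_ik f_kj) / u_ij )^2,

where u_ij is the per-cell measurement uncertainty. Uncertainties follow the
EPA receptor-model conventions: below-detection cells get u = (5/6) x MDL,
observed cells u = sqrt((error_fraction x c)^2 + (0.5 x MDL)^2), and missing
cells (median-substituted) get u = 4 x species median so they carry near-zero
weight.

The solver is alternating nonnegative least squares: each iteration solves
every row of G and every column of F exactly (scipy NNLS on 1/u-scaled
systems), which guarantees nonnegativity and monotone descent of Q. Multiple
random restarts guard against local minima; the best-Q restart is returned
with F rows renormalised to sum to 1 and the scale absorbed into G (a
reparameterisation that leaves the reconstruction G @ F unchanged).

Rotational-ambiguity exploration (FPEAK-style) is not implemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment, lsq_linear, nnls

from .core_data import (
    ConcentrationPanel,
    UncertaintyMatrix,
    ValidationError,
)
from .synthetic import TRACERS

#: Fixed order in which ties between equally-scoring source labels resolve.
LABEL_TIE_ORDER = ("dust", "coal/biomass", "vehicle", "industrial", "fuel oil")


class FitError(RuntimeError):
    """Every restart of the factorization diverged."""


# ---------------------------------------------------------------------------
# Uncertainty construction
# ---------------------------------------------------------------------------

def uncertainty_below_mdl(mdl: float) -> float:
    """u for a below-detection observation: (5/6) x MDL."""
    return (5.0 / 6.0) * mdl


def uncertainty_above_mdl(concentration: float, mdl: float, error_fraction: float = 0.05):
    """u for a quantified observation: sqrt((error_fraction*c)^2 + (0.5*MDL)^2)."""
    return np.sqrt((error_fraction * np.asarray(concentration)) ** 2 + (0.5 * mdl) ** 2)


def build_uncertainty(
    panel: ConcentrationPanel, error_fraction: float = 0.05
) -> UncertaintyMatrix:
    """Per-cell uncertainties for a panel under the EPA conventions.

    Missing cells receive 4 x the species median concentration (computed on
    substituted values), matching the weight-downgrade convention for
    median-filled data.
    """
    panel.validate()
    if (panel.mdl <= 0).any():
        raise ValidationError("MDL must be > 0 for every species")
    work = panel.working_values()
    u = uncertainty_above_mdl(
        work.to_numpy(), panel.mdl.to_numpy()[None, :], error_fraction
    )
    u = pd.DataFrame(u, index=work.index, columns=work.columns)

    below = panel.below_mdl
    u_low = (5.0 / 6.0) * panel.mdl
    for sp in panel.species:
        u.loc[below[sp].to_numpy(), sp] = u_low[sp]

    missing = panel.missing_mask
    medians = work.median(axis=0)
    for sp in panel.species:
        u.loc[missing[sp].to_numpy(), sp] = 4.0 * medians[sp]

    return UncertaintyMatrix(values=u, error_fraction=error_fraction).validate(panel)


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------

def q_statistic(x: np.ndarray, u: np.ndarray, g: np.ndarray, f: np.ndarray) -> float:
    """Weighted residual sum of squares Q = sum((x - g@f)/u)^2 (exact double sum)."""
    x = np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    if (u <= 0).any():
        raise ValidationError("uncertainty must be strictly positive")
    resid = (x - np.asarray(g) @ np.asarray(f)) / u
    return float(np.sum(resid * resid))


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------

@dataclass
class FactorModel:
    """Fitted factorization with diagnostics.

    Q_expected is the degrees-of-freedom proxy n*m - p*(n+m); q_history the
    per-iteration Q trace of the winning restart.
    """

    G: pd.DataFrame          # n x p contributions, ng/m^3 scale
    F: pd.DataFrame          # p x m row-stochastic profiles
    Q: float
    Q_expected: float
    restarts: int
    best_seed: int
    converged: bool
    q_history: list = field(default_factory=list)

    @property
    def n_factors(self) -> int:
        return self.F.shape[0]

    def reconstruction(self) -> pd.DataFrame:
        return self.G.to_numpy() @ self.F.to_numpy()

    def validate(self) -> "FactorModel":
        if (self.G.to_numpy() < 0).any() or (self.F.to_numpy() < 0).any():
            raise ValidationError("G and F must be nonnegative")
        if not np.allclose(self.F.sum(axis=1).to_numpy(), 1.0, rtol=0, atol=1e-9):
            raise ValidationError("F rows must sum to 1")
        if self.Q < 0:
            raise ValidationError("Q must be nonnegative")
        return self


def _nnls(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Nonnegative least squares, falling back to bounded LSQ on ill-conditioned systems."""
    try:
        sol, _ = nnls(a, b, maxiter=max(200, 30 * a.shape[1]))
        return sol
    except RuntimeError:
        res = lsq_linear(a, b, bounds=(0.0, np.inf), method="bvls")
        return np.clip(res.x, 0.0, None)


def _anls_restart(
    x: np.ndarray,
    u: np.ndarray,
    p: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    """One alternating-NNLS run from a random start; returns (G, F, Q trace, converged)."""
    n, m = x.shape
    f = rng.random((p, m)) + 0.1
    f /= f.sum(axis=1, keepdims=True)
    g = rng.random((n, p)) * x.mean()

    q_hist: list[float] = []
    converged = False
    for _ in range(max_iter):
        # exact WLS-NNLS update of each contribution row
        for i in range(n):
            a = (f / u[i][None, :]).T          # m x p
            g[i] = _nnls(a, x[i] / u[i])
        # exact WLS-NNLS update of each profile column
        for j in range(m):
            a = g / u[:, j][:, None]           # n x p
            f[:, j] = _nnls(a, x[:, j] / u[:, j])
        q = q_statistic(x, u, g, f)
        if q_hist and not np.isfinite(q):
            break
        q_hist.append(q)
        if len(q_hist) > 1:
            prev = q_hist[-2]
            if abs(prev - q) <= tol * max(prev, 1e-300):
                converged = True
                break
    return g, f, q_hist, converged


def fit_pmf(
    panel: ConcentrationPanel,
    u: UncertaintyMatrix | None = None,
    p: int = 5,
    restarts: int = 20,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-8,
) -> FactorModel:
    """Fit a p-factor model; the lowest-Q restart wins (ties: lowest restart index)."""
    if u is None:
        u = build_uncertainty(panel)
    x = panel.working_values().to_numpy(dtype=float)
    uu = u.values.to_numpy(dtype=float)
    n, m = x.shape
    if p < 1:
        raise ValidationError("p must be >= 1")
    if p * (n + m) >= n * m:
        raise ValidationError(
            f"p={p} over-parameterises an {n}x{m} panel (p*(n+m) must be < n*m)"
        )

    best = None
    for r in range(restarts):
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), r)))
        g, f, q_hist, conv = _anls_restart(x, uu, p, rng, max_iter, tol)
        if not q_hist or not np.isfinite(q_hist[-1]):
            continue
        if best is None or q_hist[-1] < best[2][-1]:
            best = (g, f, q_hist, conv, r)
    if best is None:
        raise FitError("all restarts produced non-finite Q")

    g, f, q_hist, conv, r = best
    # push scale into G so that F rows sum to 1 (reconstruction unchanged)
    s = f.sum(axis=1)
    dead = s <= 0
    if dead.any():
        f[dead] = 1.0 / m
        g[:, dead] = 0.0
        s = f.sum(axis=1)
    f = f / s[:, None]
    g = g * s[None, :]

    factors = [f"factor_{k + 1}" for k in range(p)]
    return FactorModel(
        G=pd.DataFrame(g, index=panel.values.index, columns=factors),
        F=pd.DataFrame(f, index=factors, columns=panel.species),
        Q=float(q_hist[-1]),
        Q_expected=float(n * m - p * (n + m)),
        restarts=restarts,
        best_seed=r,
        converged=conv,
        q_history=q_hist,
    ).validate()


def q_over_factor_range(
    panel: ConcentrationPanel,
    p_values: list[int],
    u: UncertaintyMatrix | None = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Diagnostic Q / Q_expected scan over candidate factor counts."""
    rows = []
    for p in p_values:
        model = fit_pmf(panel, u=u, p=p, **fit_kwargs)
        rows.append(
            {"p": p, "Q": model.Q, "Q_expected": model.Q_expected,
             "Q_ratio": model.Q / model.Q_expected}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Factor labeling and contribution shares
# ---------------------------------------------------------------------------

def label_factors(f: pd.DataFrame) -> list[str]:
    """Assign each factor an emission-source label by tracer-share matching.

    The score of source s for a factor is the mean profile share over s's
    tracer elements; labels are assigned one-to-one by maximising the total
    score (Hungarian algorithm). Exact ties resolve deterministically, with
    sources preferred for earlier factors in the order dust, coal/biomass,
    vehicle, industrial, fuel oil.
    """
    p = f.shape[0]
    sources = list(LABEL_TIE_ORDER)
    score = np.zeros((p, len(sources)))
    for j, src in enumerate(sources):
        tracers = [t for t in TRACERS[src] if t in f.columns]
        if tracers:
            score[:, j] = f[tracers].mean(axis=1).to_numpy()
    # deterministic tie-break: tiny bonus for high-priority sources on early factors
    eps = 1e-12
    prio = np.arange(len(sources), 0, -1)[None, :] * np.arange(p, 0, -1)[:, None]
    rows, cols = linear_sum_assignment(-(score + eps * prio))
    labels = [""] * p
    for k, j in zip(rows, cols):
        labels[k] = sources[j]
    return labels


def source_contribution_shares(model: FactorModel) -> tuple[pd.DataFrame, pd.Series]:
    """Per-species and total-mass source shares implied by a fitted model.

    Per species j, source k's share is mean_t(g_tk) f_kj normalised over
    sources; total-mass shares weight by each source's reconstructed mass.
    Both sum to 1 (per species / overall).
    """
    gbar = model.G.mean(axis=0).to_numpy()             # p
    contrib = model.F.to_numpy() * gbar[:, None]       # p x m
    col_tot = contrib.sum(axis=0)
    if not (col_tot > 0).any():
        raise ValidationError("all-zero reconstruction; shares undefined")
    if (col_tot <= 0).any():
        raise ValidationError("a species has zero reconstructed mass; shares undefined")
    per_species = pd.DataFrame(
        (contrib / col_tot[None, :]).T, index=model.F.columns, columns=model.F.index
    )
    mass = contrib.sum(axis=1)
    total = pd.Series(mass / mass.sum(), index=model.F.index)
    return per_species, total


def match_factors_to_truth(
    f_hat: pd.DataFrame, f_true: pd.DataFrame
) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Optimally pair fitted factors with ground-truth profiles by cosine similarity.

    Returns the (fitted, true) index pairs and the matched cosine similarities.
    """
    a = f_hat.to_numpy()
    b = f_true[f_hat.columns].to_numpy()
    an = a / np.linalg.norm(a, axis=1, keepdims=True)
    bn = b / np.linalg.norm(b, axis=1, keepdims=True)
    cos = an @ bn.T
    rows, cols = linear_sum_assignment(-cos)
    pairs = [(f_hat.index[i], f_true.index[j]) for i, j in zip(rows, cols)]
    return pairs, cos[rows, cols]
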