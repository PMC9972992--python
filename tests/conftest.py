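"""Shared fixtures and independent oracles for the test suite.

The ODE oracle here transcribes the growth equations by hand and integrates
them with scipy directly, independently of the package's own dynamics
module, so that closed-form equilibria and classification can be checked
against an implementation-independent path.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import comres as cr


@pytest.fixture
def fig3a() -> cr.ModelParams:
    """Competition scenario: r=0.5, k=1, alpha=(0.8, 0.8), x=0.1."""
    return cr.ModelParams(
        r_p=0.5, r_c=0.5, k_p=1.0, k_c=1.0, alpha_pc=0.8, alpha_cp=0.8, x=0.1
    )


def oracle_rhs(p: cr.ModelParams, P: float, C: float) -> tuple[float, float]:
    """Hand-transcribed growth equations (kept independent of the package)."""
    dP = p.r_p * P * (1 - (P + p.alpha_pc * C) / p.k_p) - p.x * p.A * P
    dC = p.r_c * C * (1 - (C + p.alpha_cp * P) / p.k_c) - p.x * p.f * p.A * C
    return dP, dC


def ode_terminal(
    p: cr.ModelParams, P0: float, C0: float, horizon: float = 20000.0
) -> tuple[float, float]:
    """Long-horizon terminal state from a tight-tolerance scipy integration."""
    sol = solve_ivp(
        lambda t, y: oracle_rhs(p, y[0], y[1]),
        (0.0, horizon),
        [P0, C0],
        method="LSODA",
        rtol=1e-10,
        atol=1e-13,
    )
    assert sol.success
    return float(sol.y[0, -1]), float(sol.y[1, -1])


def random_params(rng: np.random.Generator) -> cr.ModelParams:
    """A random parameter set satisfying the model invariants."""
    return cr.ModelParams(
        r_p=rng.uniform(0.2, 1.0),
        r_c=rng.uniform(0.2, 1.0),
        k_p=rng.uniform(0.5, 1.5),
        k_c=rng.uniform(0.5, 1.5),
        alpha_pc=rng.uniform(-0.9, 0.9),
        alpha_cp=rng.uniform(-0.9, 0.9),
        x=rng.uniform(0.0, 0.3),
        f=rng.uniform(0.0, 2.0),
        A=rng.uniform(0.01, 0.99),
    )


def sample_clean_attractor(rng: np.random.Generator) -> tuple[cr.ModelParams, cr.EquilibriumState]:
    """Random valid parameters whose attractor is well away from bifurcations.

    Rejects sets where the attractor's leading eigenvalue is above -0.01 or
    where any other fixed point is within 0.01 of marginality, so that the
    ODE oracle converges on a practical horizon.
    """
    while True:
        p = random_params(rng)
        try:
            st = cr.classify_outcome(p)
        except cr.NoStableEquilibriumError:  # pragma: no cover - defensive
            continue
        if not st.stable or st.eigenvalues[0] > -0.01:
            continue
        others = [
            s
            for s in cr.all_equilibria(p)
            if abs(s.P_star - st.P_star) + abs(s.C_star - st.C_star) > 1e-6
        ]
        if any(abs(s.eigenvalues[0]) < 0.01 for s in others):
            continue
        return p, st


def sample_coexistence_params(
    rng: np.random.Generator, fd_step: float = 1e-6, min_gradient: float = 1e-3
) -> cr.ModelParams:
    """Random set with a strictly stable interior equilibrium, suited to
    central finite differencing in both A and f (both gradients bounded away
    from zero so relative error is well defined)."""
    while True:
        p = random_params(rng)
        st = cr.coexistence_equilibrium(p)
        if st is None or st.kind is not cr.Outcome.COEXISTENCE or not st.stable:
            continue
        if not (fd_step < p.A < 1 - fd_step and p.f > fd_step):
            continue
        try:
            ga, gf = cr.dPstar_dA(p), cr.dPstar_df(p)
        except cr.NotApplicableError:  # pragma: no cover
            continue
        if min(abs(ga), abs(gf)) < min_gradient:
            continue
        return p
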