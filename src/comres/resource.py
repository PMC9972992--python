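"""Resource-explicit robustness variant: two consumers on one nutrient.

A chemostat-style model with Monod (saturating) uptake replaces the
phenomenological Lotka-Volterra interaction terms:

    dP/dt = P (v_p R / (K_p + R) - d - x A)
    dC/dt = C (v_c R / (K_c + R) - d - x f A)
    dR/dt = s - d R - v_p R/(K_p + R) P / y_p - v_c R/(K_c + R) C / y_c

Both consumers draw on the same nutrient pool, so each inhibits the other
indirectly — the analogue of mutual inhibition (alpha_pc > 0, alpha_cp > 0)
in the baseline model.  The module exists to show that beneficial commensal
resistance is not an artifact of the Lotka-Volterra abstraction: a
drug-susceptible commensal (high f) yields competitive release of the
pathogen, a drug-resistant commensal (low f) yields enhanced suppression.

The default parameterization makes the two consumers demographically
identical (the two-strains-of-one-species reading), so that at A = 0 they
coexist neutrally and antibiotic exposure alone breaks the tie.  The
pathogen kill coefficient is small relative to the growth margin, mirroring
the partially resistant pathogen of the baseline scenarios.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .dynamics import CONVERGENCE_TOL, LadderResult, Trajectory, _clip_negative
from .errors import IntegrationError, ParameterError
from .params import ModelParams


@dataclasses.dataclass(frozen=True)
class ResourceParams:
    """Parameters of the one-nutrient chemostat competition model.

    ``v_*`` are maximal uptake/growth rates, ``K_*`` half-saturation
    constants, ``y_*`` yields (biomass per nutrient), ``s`` the nutrient
    supply rate, ``d`` the washout/turnover rate.  ``x``, ``f`` and ``A``
    have exactly the same semantics as in :class:`~comres.params.ModelParams`.
    """

    v_p: float = 1.0
    v_c: float = 1.0
    K_p: float = 0.5
    K_c: float = 0.5
    y_p: float = 1.0
    y_c: float = 1.0
    s: float = 1.0
    d: float = 0.2
    x: float = 0.1
    f: float = 1.0
    A: float = 0.0
    R0: float = 1.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            object.__setattr__(self, name, float(getattr(self, name)))
            if getattr(self, name) < 0.0:
                raise ParameterError(f"{name} must be >= 0 (got {getattr(self, name)})")
        if not 0.0 <= self.A <= 1.0:
            raise ParameterError(f"A must lie in [0, 1] (got {self.A})")

    def replace(self, **changes: float) -> "ResourceParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def resource_rhs(params: ResourceParams, P, C, R):
    """(dP/dt, dC/dt, dR/dt) of the chemostat model; accepts arrays."""
    p = params
    up = p.v_p * R / (p.K_p + R)
    uc = p.v_c * R / (p.K_c + R)
    dP = P * (up - p.d - p.x * p.A)
    dC = C * (uc - p.d - p.x * p.f * p.A)
    dR = p.s - p.d * R - up * P / p.y_p - uc * C / p.y_c
    return dP, dC, dR


def equilibrium_split(params: ResourceParams, horizon: float = 2000.0) -> tuple[float, float, float]:
    """No-antibiotic steady state with the two consumers at equal densities.

    Integrates the A = 0 system from an equal-density start; with the
    symmetric default parameters the equal split is preserved exactly, so
    this is the natural pre-exposure community state.
    """
    p0 = params.replace(A=0.0)
    sol = solve_ivp(
        lambda t, y: resource_rhs(p0, y[0], y[1], y[2]),
        (0.0, horizon),
        [1.0, 1.0, p0.R0],
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:
        raise IntegrationError(f"steady-state search failed: {sol.message}")
    P, C, R = sol.y[:, -1]
    return float(P), float(C), float(R)


def integrate_resource(
    params: ResourceParams,
    P0: float | None = None,
    C0: float | None = None,
    R0: float | None = None,
    horizon: float = 200.0,
    n_points: int = 400,
    rtol: float = 1e-8,
    atol: float = 1e-11,
) -> Trajectory:
    """Integrate the chemostat model; defaults start at the A=0 community state."""
    if P0 is None or C0 is None or R0 is None:
        eq_P, eq_C, eq_R = equilibrium_split(params)
        P0 = eq_P if P0 is None else P0
        C0 = eq_C if C0 is None else C0
        R0 = eq_R if R0 is None else R0
    if min(P0, C0, R0) < 0:
        raise ValueError("initial state must be non-negative")
    sol = solve_ivp(
        lambda t, y: resource_rhs(params, y[0], y[1], y[2]),
        (0.0, float(horizon)),
        [float(P0), float(C0), float(R0)],
        method="LSODA",
        t_eval=np.linspace(0.0, horizon, n_points),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"resource-model integration failed: {sol.message}")
    P, C, R = _clip_negative([sol.y[0], sol.y[1], sol.y[2]])
    rhs_end = resource_rhs(params, P[-1], C[-1], R[-1])
    residual = max(abs(float(v)) for v in rhs_end)
    return Trajectory(sol.t, P, C, params, residual < CONVERGENCE_TOL, residual, R=R)


def resource_ladder(
    params: ResourceParams,
    A_values: np.ndarray | None = None,
    P0: float | None = None,
    C0: float | None = None,
    R0: float | None = None,
    horizon: float = 200.0,
    n_points: int = 400,
) -> LadderResult:
    """One chemostat integration per exposure level, shared initial condition."""
    if A_values is None:
        A_values = np.linspace(0.0, 1.0, 6)
    if P0 is None or C0 is None or R0 is None:
        eq_P, eq_C, eq_R = equilibrium_split(params)
        P0 = eq_P if P0 is None else P0
        C0 = eq_C if C0 is None else C0
        R0 = eq_R if R0 is None else R0
    trajectories = [
        integrate_resource(
            params.replace(A=float(A)), P0, C0, R0, horizon=horizon, n_points=n_points
        )
        for A in A_values
    ]
    summary = pd.DataFrame(
        {
            "A": np.asarray(A_values, dtype=float),
            "P_end": [tr.P_end for tr in trajectories],
            "C_end": [tr.C_end for tr in trajectories],
            "R_end": [float(tr.R[-1]) for tr in trajectories],
            "converged": [tr.converged for tr in trajectories],
        }
    )
    return LadderResult(trajectories, summary)


def lv_analogue(params: ResourceParams, alpha: float = 0.95) -> ModelParams:
    """Qualitative Lotka-Volterra counterpart of a chemostat parameter set.

    Two consumers of a single nutrient overlap completely, which corresponds
    to the alpha_pc = alpha_cp -> 1 limit of the baseline model; ``alpha``
    truncates that limit to stay inside the validated |alpha| < 1 range.
    Effective growth rates are the net per-capita rates at nutrient
    saturation (v - d), carrying capacities are normalised to 1.  Intended
    for which-species-persist comparisons only, not quantitative mapping.
    """
    return ModelParams(
        r_p=params.v_p - params.d,
        r_c=params.v_c - params.d,
        k_p=1.0,
        k_c=1.0,
        alpha_pc=alpha,
        alpha_cp=alpha,
        x=params.x,
        f=params.f,
        A=params.A,
    )
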