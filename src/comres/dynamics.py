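"""Temporal ODE integration of the two-species model.

The default initial condition for two-species runs is the no-antibiotic
coexistence equilibrium, reflecting the modelled scenario: a chronic
polymicrobial community (or bystander microbiome) has settled before
antibiotic exposure begins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .equilibria import Outcome, classify_outcome, coexistence_equilibrium, growth_rhs
from .errors import IntegrationError, NotApplicableError
from .params import ModelParams

CONVERGENCE_TOL = 1e-8


@dataclass
class Trajectory:
    """Time series of densities from a single integration.

    ``converged`` means the terminal right-hand side is below
    ``CONVERGENCE_TOL`` in max-norm; ``residual`` stores that terminal value.
    ``R`` is populated by the resource-explicit model only.
    """

    t: np.ndarray
    P: np.ndarray
    C: np.ndarray
    params: object
    converged: bool
    residual: float
    R: np.ndarray | None = None
    P0: float | None = None
    C0: float | None = None

    @property
    def P_end(self) -> float:
        return float(self.P[-1])

    @property
    def C_end(self) -> float:
        return float(self.C[-1])

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy long format: (time, species, density, A)."""
        frames = [
            pd.DataFrame({"time": self.t, "species": "pathogen", "density": self.P}),
            pd.DataFrame({"time": self.t, "species": "commensal", "density": self.C}),
        ]
        if self.R is not None:
            frames.append(
                pd.DataFrame({"time": self.t, "species": "nutrient", "density": self.R})
            )
        df = pd.concat(frames, ignore_index=True)
        df["A"] = self.params.A
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.12g")


@dataclass
class LadderResult:
    """Trajectories across a ladder of antibiotic exposures plus a terminal summary."""

    trajectories: list[Trajectory]
    summary: pd.DataFrame


def _clip_negative(arrays: list[np.ndarray]) -> list[np.ndarray]:
    worst = min(float(a.min()) for a in arrays)
    if worst < -1e-9:
        warnings.warn(
            f"integrator produced density {worst:.3e} < 0; clipping to 0",
            RuntimeWarning,
            stacklevel=3,
        )
    return [np.clip(a, 0.0, None) for a in arrays]


def integrate(
    params: ModelParams,
    P0: float,
    C0: float,
    horizon: float = 200.0,
    n_points: int = 400,
    rtol: float = 1e-8,
    atol: float = 1e-11,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model from (P0, C0) over [0, horizon].

    Stores ``n_points`` evenly spaced samples.  Densities are non-negative in
    the stored output (tiny negative excursions from the adaptive solver are
    clipped with a warning).
    """
    if P0 < 0 or C0 < 0:
        raise ValueError("initial densities must be non-negative")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    sol = solve_ivp(
        lambda t, y: growth_rhs(params, y[0], y[1]),
        (0.0, float(horizon)),
        [float(P0), float(C0)],
        method=method,
        t_eval=np.linspace(0.0, horizon, n_points),
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    P, C = _clip_negative([sol.y[0], sol.y[1]])
    dP, dC = growth_rhs(params, P[-1], C[-1])
    residual = max(abs(float(dP)), abs(float(dC)))
    return Trajectory(
        sol.t, P, C, params, residual < CONVERGENCE_TOL, residual,
        P0=float(P0), C0=float(C0),
    )


def baseline_coexistence(params: ModelParams) -> tuple[float, float]:
    """No-antibiotic coexistence densities used as the default initial state."""
    state = coexistence_equilibrium(params.replace(A=0.0))
    if state is None or state.kind is not Outcome.COEXISTENCE:
        raise NotApplicableError(
            "no feasible A=0 coexistence equilibrium to use as initial condition"
        )
    return state.P_star, state.C_star


def exposure_ladder(
    params: ModelParams,
    A_values: np.ndarray | None = None,
    P0: float | None = None,
    C0: float | None = None,
    horizon: float = 200.0,
    n_points: int = 400,
) -> LadderResult:
    """One integration per antibiotic exposure level, shared initial condition.

    Defaults: 6 evenly spaced exposures in [0, 1]; initial condition at the
    no-antibiotic coexistence equilibrium (pass explicit ``P0``/``C0`` for
    e.g. a pathogen-alone run with ``C0=0``).
    """
    if A_values is None:
        A_values = np.linspace(0.0, 1.0, 6)
    if P0 is None or C0 is None:
        base_P, base_C = baseline_coexistence(params)
        P0 = base_P if P0 is None else P0
        C0 = base_C if C0 is None else C0
    trajectories = [
        integrate(params.replace(A=float(A)), P0, C0, horizon=horizon, n_points=n_points)
        for A in A_values
    ]
    summary = pd.DataFrame(
        {
            "A": np.asarray(A_values, dtype=float),
            "P_end": [tr.P_end for tr in trajectories],
            "C_end": [tr.C_end for tr in trajectories],
            "converged": [tr.converged for tr in trajectories],
        }
    )
    return LadderResult(trajectories, summary)


def attractor_agrees(trajectory: Trajectory, tol: float = 1e-4) -> bool:
    """Whether a converged trajectory's terminal state matches its attractor.

    Interior initial conditions are compared against the classified community
    attractor.  Starts on an absent-species boundary (P0 = 0 or C0 = 0) stay
    on that invariant subspace, so they are compared against the matching
    single-species equilibrium instead.
    """
    from .equilibria import boundary_equilibria

    p = trajectory.params
    if trajectory.C0 == 0.0 or trajectory.P0 == 0.0:
        extinction, pathogen_alone, commensal_alone = boundary_equilibria(p)
        if trajectory.P0 == 0.0 and trajectory.C0 == 0.0:
            st = extinction
        elif trajectory.C0 == 0.0:
            st = pathogen_alone
        else:
            st = commensal_alone
    else:
        st = classify_outcome(p)
    return (
        abs(trajectory.P_end - st.P_star) <= tol and abs(trajectory.C_end - st.C_star) <= tol
    )
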