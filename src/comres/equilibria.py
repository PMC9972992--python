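"""Closed-form equilibria and local stability for the two-species model.

Because antibiotic loss is linear in density, the perturbed system is again a
classic Lotka-Volterra competition model with *effective* growth rates
``r_p - x A`` and ``r_c - x f A`` and correspondingly shrunken carrying
capacities.  Under the |alpha| < 1 restriction there is therefore a unique
attractor for interior initial conditions: one of joint extinction, pathogen
dominance, commensal dominance, or interior coexistence.

Stability is classified numerically from the real parts of the Jacobian
eigenvalues at each fixed point (tolerance ``STABILITY_TOL``); fixed points
with a leading eigenvalue within tolerance of zero are reported as *marginal*
rather than silently stable, since parameter values exactly on bifurcation
lines are routinely evaluated when drawing threshold curves.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace as _dc_replace

import numpy as np

from .errors import NoStableEquilibriumError, SingularDenominatorError
from .params import FEASIBILITY_TOL, ModelParams

STABILITY_TOL = 1e-9
#: two states closer than this (max-norm) are treated as the same fixed point
_DEDUPE_TOL = 1e-8


class Outcome(str, enum.Enum):
    """Ecological outcome classes, named by the zero-pattern of (P*, C*)."""

    JOINT_EXTINCTION = "joint_extinction"
    PATHOGEN_DOMINANCE = "pathogen_dominance"
    COMMENSAL_DOMINANCE = "commensal_dominance"
    COEXISTENCE = "coexistence"


@dataclass(frozen=True)
class EquilibriumState:
    """A non-negative fixed point with its local stability classification."""

    P_star: float
    C_star: float
    kind: Outcome
    stable: bool
    marginal: bool
    eigenvalues: tuple[float, float]  # real parts, descending
    multistable: bool = False

    @property
    def state(self) -> tuple[float, float]:
        return (self.P_star, self.C_star)


def growth_rhs(params: ModelParams, P, C):
    """Right-hand side (dP/dt, dC/dt) of the model; accepts arrays."""
    dP = params.r_p * P * (1.0 - (P + params.alpha_pc * C) / params.k_p) - params.x * params.A * P
    dC = (
        params.r_c * C * (1.0 - (C + params.alpha_cp * P) / params.k_c)
        - params.x * params.f * params.A * C
    )
    return dP, dC


def jacobian(params: ModelParams, P: float, C: float) -> np.ndarray:
    """Jacobian matrix of the growth equations at densities (P, C)."""
    p = params
    j11 = p.r_p * (1.0 - (2.0 * P + p.alpha_pc * C) / p.k_p) - p.x * p.A
    j12 = -p.r_p * p.alpha_pc * P / p.k_p
    j21 = -p.r_c * p.alpha_cp * C / p.k_c
    j22 = p.r_c * (1.0 - (2.0 * C + p.alpha_cp * P) / p.k_c) - p.x * p.f * p.A
    return np.array([[j11, j12], [j21, j22]])


def _eig_real_parts(j11: float, j12: float, j21: float, j22: float) -> tuple[float, float]:
    tr = j11 + j22
    det = j11 * j22 - j12 * j21
    disc = tr * tr - 4.0 * det
    if disc >= 0.0:
        s = math.sqrt(disc)
        return ((tr + s) / 2.0, (tr - s) / 2.0)
    return (tr / 2.0, tr / 2.0)


def _kind_of(P: float, C: float) -> Outcome:
    p, c = P > FEASIBILITY_TOL, C > FEASIBILITY_TOL
    if p and c:
        return Outcome.COEXISTENCE
    if p:
        return Outcome.PATHOGEN_DOMINANCE
    if c:
        return Outcome.COMMENSAL_DOMINANCE
    return Outcome.JOINT_EXTINCTION


def _snap(v: float) -> float:
    return 0.0 if -FEASIBILITY_TOL <= v < 0.0 else v


def _make_state(params: ModelParams, P: float, C: float) -> EquilibriumState:
    j = jacobian(params, P, C)
    eig = _eig_real_parts(float(j[0, 0]), float(j[0, 1]), float(j[1, 0]), float(j[1, 1]))
    lead = eig[0]
    return EquilibriumState(
        P_star=float(P),
        C_star=float(C),
        kind=_kind_of(P, C),
        stable=bool(lead < -STABILITY_TOL),
        marginal=bool(abs(lead) <= STABILITY_TOL),
        eigenvalues=eig,
    )


def coexistence_point(params: ModelParams) -> tuple[float, float]:
    """Raw closed-form interior solution (P*, C*), feasible or not.

    P* = [r_c k_p (r_p - x A) - alpha_pc r_p k_c (r_c - x f A)]
         / [r_p r_c (1 - alpha_pc alpha_cp)]
    and symmetrically for C* (swap p <-> c and use the commensal loss x f A).
    """
    p = params
    den = p.r_p * p.r_c * (1.0 - p.alpha_pc * p.alpha_cp)
    if abs(den) < 1e-12:
        raise SingularDenominatorError(
            f"degenerate interior system: r_p r_c (1 - alpha_pc alpha_cp) = {den}"
        )
    loss_p = p.r_p - p.x * p.A
    loss_c = p.r_c - p.x * p.f * p.A
    P = (p.r_c * p.k_p * loss_p - p.alpha_pc * p.r_p * p.k_c * loss_c) / den
    C = (p.r_p * p.k_c * loss_c - p.alpha_cp * p.r_c * p.k_p * loss_p) / den
    return P, C


def coexistence_equilibrium(params: ModelParams) -> EquilibriumState | None:
    """Interior fixed point as an :class:`EquilibriumState`, or None if infeasible.

    Negative closed-form densities (beyond the feasibility tolerance) mean no
    interior equilibrium exists; values within the tolerance of zero are
    snapped to zero, in which case the state is classified by its zero
    pattern (a boundary state, reached when parameters sit on a transcritical
    bifurcation line).
    """
    P, C = coexistence_point(params)
    P, C = _snap(P), _snap(C)
    if P < 0.0 or C < 0.0:
        return None
    return _make_state(params, P, C)


def boundary_equilibria(params: ModelParams) -> list[EquilibriumState]:
    """Joint extinction and the two single-species fixed points.

    The single-species densities are ``k_p (1 - x A / r_p)`` and
    ``k_c (1 - x f A / r_c)``; if antibiotic loss exceeds the maximal growth
    rate the corresponding density is 0 (the state collapses onto joint
    extinction).  Stability of each state accounts for both own-species
    dynamics and the invasion growth rate of the absent species, via the
    Jacobian eigenvalues.
    """
    p = params
    P_alone = max(p.k_p * (1.0 - p.x * p.A / p.r_p), 0.0) if p.r_p > 0.0 else 0.0
    C_alone = max(p.k_c * (1.0 - p.x * p.f * p.A / p.r_c), 0.0) if p.r_c > 0.0 else 0.0
    return [
        _make_state(params, 0.0, 0.0),
        _make_state(params, P_alone, 0.0),
        _make_state(params, 0.0, C_alone),
    ]


def all_equilibria(params: ModelParams) -> list[EquilibriumState]:
    """All distinct feasible fixed points (interior first, then boundaries)."""
    states: list[EquilibriumState] = []
    interior = coexistence_equilibrium(params)
    if interior is not None:
        states.append(interior)
    for s in boundary_equilibria(params):
        if not any(
            abs(s.P_star - u.P_star) <= _DEDUPE_TOL and abs(s.C_star - u.C_star) <= _DEDUPE_TOL
            for u in states
        ):
            states.append(s)
    return states


def classify_outcome(params: ModelParams) -> EquilibriumState:
    """The stable feasible attractor reachable from interior initial conditions.

    Under |alpha| < 1 this attractor is unique.  If several fixed points are
    strictly stable (unreachable under the validated invariants, kept as a
    defensive branch) the most strongly stable one is returned with
    ``multistable=True``.  If no fixed point is strictly stable, a marginally
    stable one (leading eigenvalue within ``STABILITY_TOL`` of zero) is
    returned with ``marginal=True`` — this happens exactly on bifurcation
    lines.  Raises :class:`NoStableEquilibriumError` otherwise.
    """
    states = all_equilibria(params)
    stable = [s for s in states if s.stable]
    if len(stable) == 1:
        return stable[0]
    if stable:
        best = min(stable, key=lambda s: s.eigenvalues[0])
        return _dc_replace(best, multistable=True)
    marginal = [s for s in states if s.marginal]
    if marginal:
        return min(marginal, key=lambda s: s.eigenvalues[0])
    raise NoStableEquilibriumError(
        f"no stable feasible equilibrium found for {params}; "
        "check tolerances (this should be unreachable under |alpha| < 1)"
    )
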