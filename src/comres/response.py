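"""Gradient analysis of the coexistence equilibrium and 2-D parameter sweeps.

Two closed-form gradients of equilibrium pathogen density organise the whole
cost-benefit picture:

* ``dP*/dA = x (alpha_pc r_p k_c f - r_c k_p) / (r_p r_c (1 - alpha_pc alpha_cp))``
  — its sign defines *competitive release* (pathogen density grows with
  antibiotic exposure, dP*/dA > 0), which for inhibitory commensals
  (alpha_pc > 0) happens precisely above the critical susceptibility
  ``f* = r_c k_p / (r_p k_c alpha_pc)``.
* ``dP*/df = alpha_pc k_c x A / (r_c (1 - alpha_pc alpha_cp))`` — its sign
  defines *beneficial commensal resistance* (more resistant commensals mean
  less pathogen, dP*/df > 0), which under exposure (A > 0) reduces to
  ``alpha_pc > 0``: the commensal must inhibit the pathogen.

Both statements are interior-equilibrium results; the sweep routines mask the
gradients as not-applicable (NaN) wherever coexistence fails and report the
boundary outcome class instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .equilibria import Outcome, classify_outcome, coexistence_equilibrium
from .errors import NotApplicableError, ThresholdUndefinedError
from .params import ModelParams


def _dA_formula(p: ModelParams) -> float:
    return (
        p.x
        * (p.alpha_pc * p.r_p * p.k_c * p.f - p.r_c * p.k_p)
        / (p.r_p * p.r_c * (1.0 - p.alpha_pc * p.alpha_cp))
    )


def _df_formula(p: ModelParams) -> float:
    return p.alpha_pc * p.k_c * p.x * p.A / (p.r_c * (1.0 - p.alpha_pc * p.alpha_cp))


def _require_coexistence(params: ModelParams) -> None:
    state = coexistence_equilibrium(params)
    if state is None or state.kind is not Outcome.COEXISTENCE:
        raise NotApplicableError(
            "gradients of P* are defined on the interior coexistence branch "
            f"only; no feasible coexistence at {params}"
        )


def dPstar_dA(params: ModelParams) -> float:
    """Rate of change of equilibrium pathogen density with antibiotic exposure.

    Positive values are competitive release.  Raises
    :class:`NotApplicableError` outside the coexistence regime.
    """
    _require_coexistence(params)
    return _dA_formula(params)


def dPstar_df(params: ModelParams) -> float:
    """Rate of change of equilibrium pathogen density with commensal susceptibility.

    Positive values mean commensal resistance is beneficial (lowering f
    lowers P*).  Raises :class:`NotApplicableError` outside coexistence.
    """
    _require_coexistence(params)
    return _df_formula(params)


def release_threshold_f(params: ModelParams) -> float:
    """Critical commensal susceptibility f* = r_c k_p / (r_p k_c alpha_pc).

    Competitive release (dP*/dA > 0) occurs iff f > f*, subject to
    coexistence.  Undefined when the commensal does not inhibit the pathogen
    (alpha_pc <= 0): release is then impossible at any f.
    """
    p = params
    if p.alpha_pc <= 0.0:
        raise ThresholdUndefinedError(
            f"release threshold undefined for alpha_pc={p.alpha_pc} <= 0: "
            "increased antibiotic always suppresses the pathogen"
        )
    return p.r_c * p.k_p / (p.r_p * p.k_c * p.alpha_pc)


def beneficial_resistance_condition(params: ModelParams) -> bool:
    """Whether greater commensal resistance lowers equilibrium pathogen density.

    Evaluates the sign of dP*/df; with positive growth parameters and A > 0
    this is exactly ``alpha_pc > 0``.  At A = 0 susceptibility is inert and
    the condition is False.
    """
    return _df_formula(params) > 0.0


@dataclass
class ScanGrid:
    """Result of a 2-D parameter sweep.

    Cell ``[i, j]`` corresponds to ``axis1_values[i]``, ``axis2_values[j]``.
    ``dP_dA`` / ``dP_df`` are NaN where the interior coexistence branch is
    infeasible (the outcome column then names the boundary attractor).
    """

    axis1_name: str
    axis1_values: np.ndarray
    axis2_name: str
    axis2_values: np.ndarray
    P_star: np.ndarray
    C_star: np.ndarray
    outcome: np.ndarray  # array of Outcome value strings
    dP_dA: np.ndarray
    dP_df: np.ndarray
    base_params: ModelParams
    metadata: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table: one row per grid cell."""
        a1, a2 = np.meshgrid(self.axis1_values, self.axis2_values, indexing="ij")
        return pd.DataFrame(
            {
                self.axis1_name: a1.ravel(),
                self.axis2_name: a2.ravel(),
                "P_star": self.P_star.ravel(),
                "C_star": self.C_star.ravel(),
                "outcome": self.outcome.ravel(),
                "dP_dA": self.dP_dA.ravel(),
                "dP_df": self.dP_df.ravel(),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.12g")

    def value_at(self, v1: float, v2: float, attr: str = "dP_df") -> float:
        """Value of a cell located by its axis coordinates (nearest grid point)."""
        i = int(np.argmin(np.abs(self.axis1_values - v1)))
        j = int(np.argmin(np.abs(self.axis2_values - v2)))
        return getattr(self, attr)[i, j]


def _scan(
    base: ModelParams,
    axis1_name: str,
    axis1_values: np.ndarray,
    axis2_name: str,
    axis2_values: np.ndarray,
    metadata: dict,
) -> ScanGrid:
    n1, n2 = len(axis1_values), len(axis2_values)
    P = np.empty((n1, n2))
    C = np.empty((n1, n2))
    out = np.empty((n1, n2), dtype=object)
    dA = np.full((n1, n2), np.nan)
    df_ = np.full((n1, n2), np.nan)
    for i, v1 in enumerate(axis1_values):
        for j, v2 in enumerate(axis2_values):
            p = base.replace(**{axis1_name: float(v1), axis2_name: float(v2)})
            st = classify_outcome(p)
            P[i, j], C[i, j] = st.P_star, st.C_star
            out[i, j] = st.kind.value
            if st.kind is Outcome.COEXISTENCE:
                dA[i, j] = _dA_formula(p)
                df_[i, j] = _df_formula(p)
    return ScanGrid(
        axis1_name,
        np.asarray(axis1_values, dtype=float),
        axis2_name,
        np.asarray(axis2_values, dtype=float),
        P,
        C,
        out,
        dA,
        df_,
        base,
        metadata,
    )


def scan_Af(
    base: ModelParams,
    A_values: np.ndarray | None = None,
    f_values: np.ndarray | None = None,
    contour_increment: float = 0.03,
) -> ScanGrid:
    """Sweep antibiotic exposure (axis 1) against commensal susceptibility (axis 2).

    Defaults: 201 x 201 grid over A in [0, 1], f in [0, 2].  The contour
    increment is carried as plot metadata only.
    """
    if A_values is None:
        A_values = np.linspace(0.0, 1.0, 201)
    if f_values is None:
        f_values = np.linspace(0.0, 2.0, 201)
    return _scan(
        base, "A", A_values, "f", f_values, {"contour_increment": contour_increment}
    )


def scan_alpha(
    base: ModelParams,
    alpha_pc_values: np.ndarray | None = None,
    alpha_cp_values: np.ndarray | None = None,
) -> ScanGrid:
    """Sweep the two interaction coefficients (|alpha| < 1 on both axes).

    Default grid: -0.96 ... 0.96 in steps of 0.01 on each axis, which places
    the four canonical interaction scenarios (+-0.8, +-0.8) exactly on grid
    points.  The sign boundary of dP*/df sits on the alpha_pc = 0 line.
    """
    if alpha_pc_values is None:
        alpha_pc_values = np.linspace(-0.96, 0.96, 193)
    if alpha_cp_values is None:
        alpha_cp_values = np.linspace(-0.96, 0.96, 193)
    for vals, name in ((alpha_pc_values, "alpha_pc"), (alpha_cp_values, "alpha_cp")):
        if np.max(np.abs(vals)) >= 1.0:
            raise NotApplicableError(f"{name} axis must stay within |alpha| < 1")
    return _scan(base, "alpha_pc", alpha_pc_values, "alpha_cp", alpha_cp_values, {})
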