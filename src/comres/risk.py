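"""Cost-benefit optimization of commensal resistance via infection risk.

Total within-community infection risk at the ecological attractor is the sum
of three per-capita weighted terms,

    risk(f) = w_p P*(f) + w_c C*(f) + w_hb P*(f) C*(f),

where ``w_p`` and ``w_c`` weight infection risk from the pathogen and the
(opportunistically infectious) commensal, and ``w_hb`` combines the rate of
horizontal gene transfer with the risk posed by an HGT-resistant pathogen —
a static product term, maximal when both populations are abundant, zero
whenever either is extinct.  Lowering f (more commensal resistance) trades a
lower pathogen term against a higher commensal term, which is exactly the
resistance-optimization question.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd

from .equilibria import classify_outcome
from .errors import NotApplicableError, ParameterError
from .params import ModelParams


@dataclasses.dataclass(frozen=True)
class RiskWeights:
    """Static per-capita risk weights; ``w_h_beta = 0`` disables the HGT term."""

    w_p: float = 1.0
    w_c: float = 0.1
    w_h_beta: float = 0.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            object.__setattr__(self, name, float(getattr(self, name)))
            if getattr(self, name) < 0.0:
                raise ParameterError(f"{name} must be >= 0 (got {getattr(self, name)})")

    def replace(self, **changes: float) -> "RiskWeights":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class RiskProfile:
    """Per-class and total infection risk over a grid of susceptibilities f."""

    f_values: np.ndarray
    pathogen_risk: np.ndarray
    commensal_risk: np.ndarray
    hgt_risk: np.ndarray
    P_star: np.ndarray
    C_star: np.ndarray
    outcome: np.ndarray
    weights: RiskWeights
    base_params: ModelParams

    @property
    def total_risk(self) -> np.ndarray:
        return self.pathogen_risk + self.commensal_risk + self.hgt_risk

    def _tie_tol(self) -> float:
        return 1e-12 * max(1.0, float(np.max(np.abs(self.total_risk))))

    @property
    def argmin_f(self) -> float:
        """Minimizing f; ties broken toward larger f (least resistance needed)."""
        total = self.total_risk
        tied = np.where(total <= total.min() + self._tie_tol())[0]
        return float(self.f_values[tied[-1]])

    @property
    def ties(self) -> np.ndarray:
        """All grid f values attaining the minimal total risk (within tolerance)."""
        total = self.total_risk
        return self.f_values[total <= total.min() + self._tie_tol()]

    @property
    def interior_peak(self) -> float | None:
        """Location of an interior maximum of total risk, or None.

        An interior peak exists when the largest interior value exceeds both
        endpoint values by more than a prominence tolerance (a hump, not a
        monotone or plateaued profile; the tolerance absorbs float noise at
        bifurcation points, where the snapped closed form can sit a few ulp
        above the boundary value).
        """
        total = self.total_risk
        if len(total) < 3:
            return None
        tol = 1e-9 * max(1.0, float(np.max(np.abs(total))))
        i = 1 + int(np.argmax(total[1:-1]))
        if total[i] > total[0] + tol and total[i] > total[-1] + tol:
            return float(self.f_values[i])
        return None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "f": self.f_values,
                "pathogen_risk": self.pathogen_risk,
                "commensal_risk": self.commensal_risk,
                "hgt_risk": self.hgt_risk,
                "total_risk": self.total_risk,
                "P_star": self.P_star,
                "C_star": self.C_star,
                "outcome": self.outcome,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.12g")


class OptimalF(NamedTuple):
    f: float
    ties: np.ndarray


def risk_profile(
    base: ModelParams,
    weights: RiskWeights,
    f_values: np.ndarray | None = None,
    weight_fn: Callable[[float], RiskWeights] | None = None,
) -> RiskProfile:
    """Evaluate the three risk components over a grid of susceptibilities.

    For each f the stable attractor is found (boundary equilibria are used
    where coexistence fails) and risks are evaluated at its densities.
    Requires antibiotic exposure (``base.A > 0``): without exposure f is
    inert and the trade-off is undefined.  ``weight_fn``, if given, supplies
    f-dependent weights (e.g. resistance-strength-dependent virulence)
    overriding the static ``weights``.
    """
    if base.A <= 0.0:
        raise NotApplicableError("the risk trade-off is defined under exposure (A > 0)")
    if f_values is None:
        f_values = np.linspace(0.0, 3.0, 301)
    f_values = np.asarray(f_values, dtype=float)
    n = len(f_values)
    P = np.empty(n)
    C = np.empty(n)
    out = np.empty(n, dtype=object)
    rp = np.empty(n)
    rc = np.empty(n)
    rh = np.empty(n)
    for i, f in enumerate(f_values):
        st = classify_outcome(base.replace(f=float(f)))
        P[i], C[i] = st.P_star, st.C_star
        out[i] = st.kind.value
        w = weight_fn(float(f)) if weight_fn is not None else weights
        rp[i] = w.w_p * P[i]
        rc[i] = w.w_c * C[i]
        rh[i] = w.w_h_beta * P[i] * C[i]
    return RiskProfile(f_values, rp, rc, rh, P, C, out, weights, base)


def optimal_f(profile: RiskProfile) -> OptimalF:
    """Grid argmin of total risk with the tie set (ties broken toward larger f)."""
    return OptimalF(profile.argmin_f, profile.ties)
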