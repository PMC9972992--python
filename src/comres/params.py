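"""Parameter container for the antibiotic-perturbed two-species Lotka-Volterra model.

The model tracks a pathogen (density ``P``) and a commensal (density ``C``):

.. math::

    dP/dt = r_p P (1 - (P + \\alpha_{pc} C)/k_p) - x A P

    dC/dt = r_c C (1 - (C + \\alpha_{cp} P)/k_c) - x f A C

Interaction coefficients are signed: ``alpha_ij > 0`` means species *j*
inhibits species *i* (competition), ``alpha_ij < 0`` means facilitation.
Antibiotic exposure ``A`` scales the pathogen loss rate from 0 up to its
maximal clearance rate ``x``; the commensal's relative susceptibility ``f``
multiplies that loss rate (``f < 1``: commensal more resistant than the
pathogen, ``f > 1``: more susceptible).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

from .errors import ConfigError, ParameterError

#: Densities in [-FEASIBILITY_TOL, 0) are snapped to 0; more negative is infeasible.
FEASIBILITY_TOL = 1e-9


class CarryingCapacityWarning(UserWarning):
    """Carrying capacity outside the conventional rescaled range (0, 2]."""


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """Full parameter vector of the two-species model.

    Parameters
    ----------
    r_p, r_c
        Maximal per-capita growth rates (per unit time), >= 0.
    k_p, k_c
        Single-species carrying capacities (rescaled density). Must be > 0;
        values outside (0, 2] trigger :class:`CarryingCapacityWarning` only.
    alpha_pc
        Per-capita effect of the commensal on the pathogen, |alpha_pc| < 1.
    alpha_cp
        Per-capita effect of the pathogen on the commensal, |alpha_cp| < 1.
    x
        Maximal antibiotic clearance rate of the pathogen (per unit time).
    f
        Commensal susceptibility relative to the pathogen, >= 0.
    A
        Antibiotic perturbation level in [0, 1].
    """

    r_p: float = 0.5
    r_c: float = 0.5
    k_p: float = 1.0
    k_c: float = 1.0
    alpha_pc: float = 0.8
    alpha_cp: float = 0.8
    x: float = 0.1
    f: float = 1.0
    A: float = 0.0

    def __post_init__(self) -> None:
        for name in self.__dataclass_fields__:
            object.__setattr__(self, name, float(getattr(self, name)))
        if not abs(self.alpha_pc) < 1.0 or not abs(self.alpha_cp) < 1.0:
            raise ParameterError(
                "interaction coefficients must satisfy |alpha_ij| < 1 "
                f"(got alpha_pc={self.alpha_pc}, alpha_cp={self.alpha_cp}); "
                "strong interference competition is outside the model's scope"
            )
        for name in ("r_p", "r_c", "x", "f"):
            if getattr(self, name) < 0.0:
                raise ParameterError(f"{name} must be >= 0 (got {getattr(self, name)})")
        for name in ("k_p", "k_c"):
            if getattr(self, name) <= 0.0:
                raise ParameterError(f"{name} must be > 0 (got {getattr(self, name)})")
        if not 0.0 <= self.A <= 1.0:
            raise ParameterError(f"A must lie in [0, 1] (got {self.A})")
        for name in ("k_p", "k_c"):
            if getattr(self, name) > 2.0:
                warnings.warn(
                    f"{name}={getattr(self, name)} outside the conventional "
                    "rescaled range (0, 2]",
                    CarryingCapacityWarning,
                    stacklevel=2,
                )

    def replace(self, **changes: float) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParams":
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown parameter keys: {sorted(unknown)}")
        try:
            return cls(**data)
        except TypeError as exc:  # non-numeric values
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParams":
        """Load parameters from a JSON or TOML file keyed by field names."""
        data = load_config(path)
        if not data:
            raise ConfigError(f"{path} holds an empty configuration")
        return cls.from_dict(data)


def load_config(path: str | Path) -> dict:
    """Read a flat JSON or TOML mapping, dispatching on the file suffix."""
    path = Path(path)
    try:
        if path.suffix.lower() == ".toml":
            import tomllib

            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        else:
            with open(path, encoding="utf-8") as fh:
                data = json.load(fh)
    except (json.JSONDecodeError, ValueError) as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError(f"{path} must hold a mapping at top level")
    return data
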