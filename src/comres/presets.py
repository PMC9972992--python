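"""Named parameter presets for the canonical figure scenarios.

Every preset is validated on construction and records which figure legend
its payload transcribes.  The four interaction scenarios share the
demographic baseline r_p = r_c = 0.5, k_p = k_c = 1, x = 0.1 and differ in
the signs of (alpha_pc, alpha_cp):

    competition (0.8, 0.8) | commensal exploits pathogen (0.8, -0.8)
    pathogen exploits commensal (-0.8, 0.8) | mutualism (-0.8, -0.8)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams
from .resource import ResourceParams
from .risk import RiskWeights
from .spatial import SpatialConfig

_BASE = ModelParams(r_p=0.5, r_c=0.5, k_p=1.0, k_c=1.0, x=0.1)

_ALPHAS = {
    "A": (0.8, 0.8),
    "B": (0.8, -0.8),
    "C": (-0.8, 0.8),
    "D": (-0.8, -0.8),
}


@dataclass(frozen=True)
class Preset:
    """A named, validated payload plus the figure legend it transcribes."""

    name: str
    target: str  # scan | alpha-scan | simulate | resource | spatial | risk
    payload: dict = field(repr=False)
    provenance: str = ""


def _scan_preset(name: str, params: ModelParams, increment: float, provenance: str) -> Preset:
    return Preset(
        name=name,
        target="scan",
        payload={
            "params": params,
            "A_values": np.linspace(0.0, 1.0, 201),
            "f_values": np.linspace(0.0, 2.0, 201),
            "contour_increment": increment,
        },
        provenance=provenance,
    )


def _build_registry() -> dict[str, Preset]:
    reg: dict[str, Preset] = {}

    # (A, f) sweeps for the four interaction scenarios.
    for panel, (apc, acp) in _ALPHAS.items():
        inc = 0.06 if panel == "D" else 0.03
        reg[f"fig3{panel}"] = _scan_preset(
            f"fig3{panel}",
            _BASE.replace(alpha_pc=apc, alpha_cp=acp),
            inc,
            f"figure 3{panel} legend: r=0.5, k=1, x=0.1, alpha=({apc}, {acp})",
        )

    # Demographic-asymmetry variants (supplementary sweeps); competition panel.
    supp = {
        "figS1": dict(r_p=0.25, r_c=0.75, k_p=1.0, k_c=1.0),
        "figS2": dict(r_p=0.5, r_c=0.5, k_p=0.5, k_c=1.5),
        "figS3": dict(r_p=0.75, r_c=0.25, k_p=1.0, k_c=1.0),
        "figS4": dict(r_p=0.5, r_c=0.5, k_p=1.5, k_c=0.5),
    }
    notes = {
        "figS1": "commensal grows faster (r_c > r_p)",
        "figS2": "commensal has higher carrying capacity (k_c > k_p)",
        "figS3": "pathogen grows faster (r_p > r_c)",
        "figS4": "pathogen has higher carrying capacity (k_p > k_c)",
    }
    for name, over in supp.items():
        reg[name] = _scan_preset(
            name,
            _BASE.replace(alpha_pc=0.8, alpha_cp=0.8, **over),
            0.03,
            f"supplementary {name} legend: {notes[name]}, x=0.1, competition alpha=(0.8, 0.8)",
        )

    # Interaction-coefficient sweep of dP*/df at full exposure.
    reg["fig4"] = Preset(
        name="fig4",
        target="alpha-scan",
        payload={
            "params": _BASE.replace(alpha_pc=0.0, alpha_cp=0.0, A=1.0),
            "alpha_pc_values": np.linspace(-0.96, 0.96, 193),
            "alpha_cp_values": np.linspace(-0.96, 0.96, 193),
            "marked_points": dict(_ALPHAS),
        },
        provenance="figure 4 legend: r=0.5, k=1, x=0.1, A=1; marked points at (+-0.8, +-0.8)",
    )

    # Temporal dynamics ladders of the baseline model.
    ladder = np.linspace(0.0, 1.0, 6)
    reg["fig5A"] = Preset(
        name="fig5A",
        target="simulate",
        payload={
            "params": _BASE.replace(alpha_pc=0.8, alpha_cp=0.8, f=1.0),
            "A_values": ladder,
            "P0": 1.0,
            "C0": 0.0,
            "horizon": 200.0,
        },
        provenance="figure 5A legend: pathogen alone, P(0)=k_p=1, partial resistance x=0.1",
    )
    for panel, f in (("B", 2.0), ("C", 0.5)):
        reg[f"fig5{panel}"] = Preset(
            name=f"fig5{panel}",
            target="simulate",
            payload={
                "params": _BASE.replace(alpha_pc=0.8, alpha_cp=0.8, f=f),
                "A_values": ladder,
                "P0": None,  # no-antibiotic coexistence equilibrium
                "C0": None,
                "horizon": 200.0,
            },
            provenance=(
                f"figure 5{panel} legend: competition scenario with "
                f"{'susceptible' if f > 1 else 'resistant'} commensal (f={f})"
            ),
        )

    # Resource-explicit robustness scenarios.
    reg["fig5DEF"] = Preset(
        name="fig5DEF",
        target="resource",
        payload={
            "params": ResourceParams(),
            "scenarios": {
                "alone": {"f": 1.0, "C0": 0.0},
                "susceptible": {"f": 2.0, "C0": None},
                "resistant": {"f": 0.5, "C0": None},
            },
            "A_values": ladder,
            # transient window: long-run single-nutrient competition always
            # excludes one consumer, so release is a transient-phase signature
            "horizon": 60.0,
        },
        provenance="figure 5D-F: one-nutrient chemostat robustness variant (own parameterization)",
    )

    # Spatially extended robustness scenarios.
    reg["fig5GHI"] = Preset(
        name="fig5GHI",
        target="spatial",
        payload={
            "config": SpatialConfig(params=_BASE.replace(alpha_pc=0.8, alpha_cp=0.8)),
            "scenarios": {
                "alone": {"f": 1.0, "C0": 0.0},
                "susceptible": {"f": 2.0, "C0": None},
                "resistant": {"f": 0.5, "C0": None},
            },
            "horizon": 200.0,
        },
        provenance="figure 5G-I: reaction-diffusion variant with linear antibiotic gradient",
    )

    # Risk optimization at full exposure.
    reg["figS6"] = Preset(
        name="figS6",
        target="risk",
        payload={
            "params": _BASE.replace(alpha_pc=0.8, alpha_cp=0.8, A=1.0),
            "weights": RiskWeights(w_p=1.0, w_c=0.1, w_h_beta=0.0),
            "weights_hgt": RiskWeights(w_p=1.0, w_c=0.1, w_h_beta=5.0),
            "f_values": np.linspace(0.0, 3.0, 301),
        },
        provenance="supplementary figure S6 legend: A=1, w_p=1, w_c=0.1, w_h_beta=5",
    )
    return reg


_REGISTRY = _build_registry()


def list_presets() -> list[str]:
    return sorted(_REGISTRY)


def get_preset(name: str) -> Preset:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {list_presets()}") from None
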