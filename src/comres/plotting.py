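"""Figure regeneration: contour maps, gradient heat maps, dynamics, risk curves.

Best-effort visual matches of the canonical figure layouts; the CSV outputs
carry the quantitative surface, the figures are for inspection.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .dynamics import LadderResult
from .errors import ThresholdUndefinedError
from .response import ScanGrid, release_threshold_f
from .risk import RiskProfile


def plot_scan(scan: ScanGrid, path: str | Path, title: str = "") -> None:
    """Contour map of P* over the swept plane; dashed line at f* if defined."""
    fig, ax = plt.subplots(figsize=(5.2, 4.2))
    inc = scan.metadata.get("contour_increment", 0.03)
    P = np.ma.masked_invalid(scan.P_star)
    vmax = float(np.nanmax(scan.P_star))
    levels = np.arange(0.0, vmax + inc, inc)
    X, Y = np.meshgrid(scan.axis1_values, scan.axis2_values, indexing="ij")
    cf = ax.contourf(X, Y, P, levels=levels, cmap="viridis")
    dominated = scan.outcome == "pathogen_dominance"
    if dominated.any():
        ax.contourf(X, Y, dominated.astype(float), levels=[0.5, 1.5], colors=["#b2182b"])
    if scan.axis1_name == "A" and scan.axis2_name == "f":
        try:
            fstar = release_threshold_f(scan.base_params)
            if scan.axis2_values.min() <= fstar <= scan.axis2_values.max():
                ax.axhline(fstar, color="white", ls="--", lw=1.5)
        except ThresholdUndefinedError:
            pass
    fig.colorbar(cf, ax=ax, label="P*")
    ax.set_xlabel(scan.axis1_name)
    ax.set_ylabel(scan.axis2_name)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_alpha_scan(
    scan: ScanGrid, path: str | Path, marked_points: dict | None = None
) -> None:
    """Diverging heat map of dP*/df over the interaction-coefficient plane."""
    fig, ax = plt.subplots(figsize=(5.2, 4.2))
    lim = float(np.nanmax(np.abs(scan.dP_df)))
    pc = ax.pcolormesh(
        scan.axis1_values,
        scan.axis2_values,
        scan.dP_df.T,
        cmap="RdBu_r",
        vmin=-lim,
        vmax=lim,
        shading="nearest",
    )
    ax.axhline(0.0, color="k", ls="--", lw=0.8)
    ax.axvline(0.0, color="k", ls="--", lw=0.8)
    if marked_points:
        for label, (apc, acp) in marked_points.items():
            ax.plot(apc, acp, "ko", ms=4)
            ax.annotate(label, (apc, acp), textcoords="offset points", xytext=(4, 4))
    fig.colorbar(pc, ax=ax, label="dP*/df")
    ax.set_xlabel("alpha_pc")
    ax.set_ylabel("alpha_cp")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ladder(ladder: LadderResult, path: str | Path, title: str = "") -> None:
    """Pathogen density through time, one line per antibiotic exposure."""
    fig, ax = plt.subplots(figsize=(5.2, 3.6))
    cmap = plt.get_cmap("plasma")
    n = len(ladder.trajectories)
    for i, tr in enumerate(ladder.trajectories):
        ax.plot(tr.t, tr.P, color=cmap(i / max(n - 1, 1)), label=f"A={tr.params.A:g}")
    ax.set_xlabel("time")
    ax.set_ylabel("pathogen density")
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_risk(profiles: list[RiskProfile], path: str | Path) -> None:
    """Component (dashed) and total (solid) infection risk against f."""
    fig, axes = plt.subplots(1, len(profiles), figsize=(4.6 * len(profiles), 3.6), squeeze=False)
    for ax, prof in zip(axes[0], profiles):
        ax.plot(prof.f_values, prof.pathogen_risk, "r--", label="pathogen")
        ax.plot(prof.f_values, prof.commensal_risk, "b--", label="commensal")
        if prof.weights.w_h_beta > 0:
            ax.plot(prof.f_values, prof.hgt_risk, "--", color="purple", label="HGT")
        ax.plot(prof.f_values, prof.total_risk, "k-", label="total")
        ax.set_xlabel("commensal relative susceptibility f")
        ax.set_ylabel("infection risk")
        ax.set_title(f"w_h_beta = {prof.weights.w_h_beta:g}")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
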