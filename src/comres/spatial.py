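"""Two-dimensional reaction-diffusion extension with an antibiotic gradient.

The baseline growth equations act pointwise on fields P(x, y), C(x, y) with
added Fickian diffusion and a spatially varying antibiotic exposure field:

    dP/dt = lv_rhs_P(P, C; A(x, y)) + D_p lap(P)
    dC/dt = lv_rhs_C(P, C; A(x, y)) + D_c lap(C)

Discretization is a 5-point Laplacian on a uniform grid (method of lines,
same adaptive integrator family as the non-spatial module).  Boundaries are
no-flux by default (a closed host compartment); the antibiotic field is a
linear gradient along one axis by default.  Reported pathogen densities are
averaged across space.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp

from .dynamics import CONVERGENCE_TOL, Trajectory
from .errors import InstabilityError, ParameterError
from .params import ModelParams

_DIVERGENCE_LIMIT = 1e6


@dataclasses.dataclass(frozen=True)
class SpatialConfig:
    """Grid, diffusion, antibiotic-field and boundary configuration.

    ``params.A`` is ignored: exposure is supplied by the spatial field,
    a linear ramp from ``A_min`` to ``A_max`` along ``gradient_axis``.
    Diffusion defaults put the domain-crossing diffusion time within an
    order of magnitude of the demographic timescale 1/r, so spatial
    structure neither freezes nor instantly mixes away.
    """

    params: ModelParams = ModelParams()
    nx: int = 64
    ny: int = 64
    Lx: float = 1.0
    Ly: float = 1.0
    D_p: float = 1e-3
    D_c: float = 1e-3
    A_min: float = 0.0
    A_max: float = 1.0
    gradient_axis: str = "x"
    boundary: str = "no-flux"

    def __post_init__(self) -> None:
        if self.nx < 3 or self.ny < 3:
            raise ParameterError("grid dimensions must be >= 3")
        if self.D_p < 0 or self.D_c < 0:
            raise ParameterError("diffusion coefficients must be >= 0")
        if not (0.0 <= self.A_min <= self.A_max <= 1.0):
            raise ParameterError("need 0 <= A_min <= A_max <= 1")
        if self.gradient_axis not in ("x", "y"):
            raise ParameterError(f"gradient_axis must be 'x' or 'y', got {self.gradient_axis!r}")
        if self.boundary not in ("no-flux", "periodic"):
            raise ParameterError(f"boundary must be 'no-flux' or 'periodic', got {self.boundary!r}")

    def replace(self, **changes) -> "SpatialConfig":
        return dataclasses.replace(self, **changes)

    @property
    def dx(self) -> float:
        return self.Lx / (self.nx - 1)

    @property
    def dy(self) -> float:
        return self.Ly / (self.ny - 1)


def antibiotic_field(config: SpatialConfig) -> np.ndarray:
    """Exposure field A(x, y), shape (ny, nx); rows index y, columns x."""
    ramp_x = np.linspace(config.A_min, config.A_max, config.nx)
    ramp_y = np.linspace(config.A_min, config.A_max, config.ny)
    if config.gradient_axis == "x":
        return np.tile(ramp_x, (config.ny, 1))
    return np.tile(ramp_y[:, None], (1, config.nx))


def laplacian(field: np.ndarray, dx: float, dy: float, boundary: str = "no-flux") -> np.ndarray:
    """5-point Laplacian; no-flux via edge replication, periodic via wrap."""
    mode = "edge" if boundary == "no-flux" else "wrap"
    g = np.pad(field, 1, mode=mode)
    return (g[1:-1, 2:] - 2.0 * field + g[1:-1, :-2]) / (dx * dx) + (
        g[2:, 1:-1] - 2.0 * field + g[:-2, 1:-1]
    ) / (dy * dy)


@dataclasses.dataclass
class SpatialResult:
    """Space-time output: spatially averaged series plus field snapshots."""

    times: np.ndarray
    mean_P: np.ndarray
    mean_C: np.ndarray
    snapshot_times: np.ndarray
    P_snapshots: list[np.ndarray]
    C_snapshots: list[np.ndarray]
    A_field: np.ndarray
    config: SpatialConfig
    converged: bool
    residual: float

    @property
    def P_final(self) -> np.ndarray:
        return self.P_snapshots[-1]

    @property
    def C_final(self) -> np.ndarray:
        return self.C_snapshots[-1]

    @property
    def mean_trajectory(self) -> Trajectory:
        return Trajectory(
            self.times, self.mean_P, self.mean_C, self.config.params,
            self.converged, self.residual,
        )

    def save(self, outdir: str | Path) -> None:
        """Export snapshots as plain-text matrices plus a metadata JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for label, snaps in (("P", self.P_snapshots), ("C", self.C_snapshots)):
            for t, field in zip(self.snapshot_times, snaps):
                np.savetxt(outdir / f"{label}_t{t:g}.txt", field, fmt="%.10g")
        np.savetxt(outdir / "A_field.txt", self.A_field, fmt="%.10g")
        meta = dataclasses.asdict(self.config)
        meta["snapshot_times"] = [float(t) for t in self.snapshot_times]
        meta["converged"] = bool(self.converged)
        meta["residual"] = float(self.residual)
        (outdir / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def _reaction(params: ModelParams, P, C, A):
    dP = params.r_p * P * (1.0 - (P + params.alpha_pc * C) / params.k_p) - params.x * A * P
    dC = (
        params.r_c * C * (1.0 - (C + params.alpha_cp * P) / params.k_c)
        - params.x * params.f * A * C
    )
    return dP, dC


def integrate_spatial(
    config: SpatialConfig,
    P0: float | np.ndarray | None = None,
    C0: float | np.ndarray | None = None,
    horizon: float = 200.0,
    n_points: int = 200,
    n_snapshots: int = 5,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> SpatialResult:
    """Solve the reaction-diffusion system and report spatially averaged series.

    Scalar (or omitted) initial values are broadcast to uniform fields; the
    default is the no-antibiotic coexistence equilibrium of the non-spatial
    model.  Raises :class:`InstabilityError` if the fields diverge.
    """
    ny, nx = config.ny, config.nx
    A = antibiotic_field(config)
    if P0 is None or C0 is None:
        from .dynamics import baseline_coexistence

        bP, bC = baseline_coexistence(config.params)
        P0 = bP if P0 is None else P0
        C0 = bC if C0 is None else C0
    P0 = np.broadcast_to(np.asarray(P0, dtype=float), (ny, nx)).copy()
    C0 = np.broadcast_to(np.asarray(C0, dtype=float), (ny, nx)).copy()
    if P0.min() < 0 or C0.min() < 0:
        raise ValueError("initial fields must be non-negative")

    n = ny * nx
    p = config.params
    dx, dy, bc = config.dx, config.dy, config.boundary

    def rhs(t, y):
        P = y[:n].reshape(ny, nx)
        C = y[n:].reshape(ny, nx)
        dP, dC = _reaction(p, P, C, A)
        if config.D_p > 0.0:
            dP = dP + config.D_p * laplacian(P, dx, dy, bc)
        if config.D_c > 0.0:
            dC = dC + config.D_c * laplacian(C, dx, dy, bc)
        return np.concatenate([dP.ravel(), dC.ravel()])

    t_eval = np.linspace(0.0, float(horizon), n_points)
    sol = solve_ivp(
        rhs,
        (0.0, float(horizon)),
        np.concatenate([P0.ravel(), C0.ravel()]),
        method="RK45",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise InstabilityError(f"spatial integration failed: {sol.message}")
    if not np.all(np.isfinite(sol.y)) or np.abs(sol.y).max() > _DIVERGENCE_LIMIT:
        raise InstabilityError("spatial fields diverged (non-finite or exploding norm)")

    Pt = np.clip(sol.y[:n], 0.0, None)
    Ct = np.clip(sol.y[n:], 0.0, None)
    mean_P = Pt.mean(axis=0)
    mean_C = Ct.mean(axis=0)
    snap_idx = np.unique(np.linspace(0, n_points - 1, n_snapshots).astype(int))
    P_snaps = [Pt[:, i].reshape(ny, nx) for i in snap_idx]
    C_snaps = [Ct[:, i].reshape(ny, nx) for i in snap_idx]
    residual = float(np.abs(rhs(sol.t[-1], sol.y[:, -1])).max())
    return SpatialResult(
        times=sol.t,
        mean_P=mean_P,
        mean_C=mean_C,
        snapshot_times=sol.t[snap_idx],
        P_snapshots=P_snaps,
        C_snapshots=C_snaps,
        A_field=A,
        config=config,
        converged=residual < CONVERGENCE_TOL,
        residual=residual,
    )
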