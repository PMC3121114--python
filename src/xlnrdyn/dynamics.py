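"""Time-domain simulation of the regulon, with and without delayed feedback.

Without feedback (or with a zero delay) the 2n system is an ordinary ODE
and is handed to an adaptive Runge-Kutta integrator. With a positive
feedback delay ``tau`` it becomes a delay differential equation, integrated
by the method of steps: the horizon is cut into segments of length ``tau``;
inside each segment the delayed protein values z(t - tau) are read from the
dense interpolant of the already-integrated past, so each segment is again
an ordinary ODE. The pre-trigger history on [-tau, 0] is the basal steady
state (the network sits at rest until the D-xylose pulse at t = 0).
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model_core import (
    FeedbackSpec,
    InputSignal,
    RegulonModel,
    SystemState,
    dxylose,
    steady_state,
    system_rhs,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "SimulationError",
    "initial_state",
    "simulate",
    "relaxation_time",
    "empirical_relaxation_time",
    "delay_sensitivity",
]


class SimulationError(RuntimeError):
    """The integrator failed; the message carries the solver diagnostic."""


@dataclass(frozen=True)
class SimulationConfig:
    """Integration horizon, output sampling and solver tolerances.

    Defaults cover the tens-of-hours timescale on which the regulon's pulse
    response plays out: 50 h horizon sampled every 0.1 h, with tight
    adaptive-step tolerances so trajectories are reproducible to well below
    plotting resolution.
    """

    t_end: float = 50.0
    dt_out: float = 0.1
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    tau_grid: tuple[float, ...] = ()
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.t_end <= 0 or self.dt_out <= 0:
            raise ValueError("t_end and dt_out must be > 0")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValueError("tolerances must be > 0")

    @property
    def times(self) -> np.ndarray:
        return np.arange(0.0, self.t_end + 0.5 * self.dt_out, self.dt_out)


@dataclass
class Trajectory:
    """Simulated paths: times, mRNA matrix x, protein matrix z, input u."""

    times: np.ndarray
    x: np.ndarray  # shape (T, n)
    z: np.ndarray  # shape (T, n)
    u_values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.x.shape[1]

    def state_at(self, index: int) -> SystemState:
        return SystemState(x=self.x[index], z=self.z[index], t=float(self.times[index]))

    def to_frame(self) -> pd.DataFrame:
        n = self.n
        data = {"t": self.times, "u": self.u_values}
        for i in range(n):
            data[f"x{i + 1}"] = self.x[:, i]
        for i in range(n):
            data[f"z{i + 1}"] = self.z[:, i]
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        df = pd.read_csv(path)
        xcols = sorted((c for c in df.columns if c.startswith("x")), key=lambda c: int(c[1:]))
        zcols = sorted((c for c in df.columns if c.startswith("z")), key=lambda c: int(c[1:]))
        return cls(
            times=df["t"].to_numpy(),
            x=df[xcols].to_numpy(),
            z=df[zcols].to_numpy(),
            u_values=df["u"].to_numpy(),
        )


def initial_state(model: RegulonModel) -> SystemState:
    """Basal (pre-pulse) steady state: u = 0, no feedback drive.

    Starting here makes the t = 0 D-xylose pulse the only perturbation, so
    every response in the trajectory is attributable to the input.
    """
    return steady_state(model, u_const=0.0, spec=None)


def _clamp_negative(y: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    worst = y.min() if y.size else 0.0
    if worst < -tol:
        logger.warning("clamping negative concentrations (min %.3e) to zero", worst)
    return np.maximum(y, 0.0)


def simulate(
    model: RegulonModel,
    sig: InputSignal,
    spec: FeedbackSpec | None = None,
    cfg: SimulationConfig | None = None,
    y0: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the 2n system over [0, t_end] from the basal steady state.

    ``spec=None`` gives the open-loop regulon. With feedback and
    ``spec.tau > 0`` the delayed protein history is interpolated by the
    method of steps with constant pre-trigger history.
    """
    cfg = cfg or SimulationConfig()
    n = model.n
    if y0 is None:
        y0 = initial_state(model).as_vector()
    else:
        y0 = np.asarray(y0, dtype=float)

    t_out = cfg.times
    # a silenced drive (CreA present, or zero lumped synthesis) makes the
    # system exactly open loop; the delay of an identically-zero signal is
    # immaterial, so take the plain ODE path
    from .model_core import crea_gate

    silenced = spec is not None and (crea_gate(spec) == 0.0 or spec.k_ls == 0.0)
    ode_spec = None if silenced else spec
    tau = ode_spec.tau if ode_spec is not None else 0.0

    if ode_spec is None or tau == 0.0:
        rhs = lambda t, y: system_rhs(t, y, model, sig, ode_spec)
        sol = solve_ivp(
            rhs,
            (0.0, cfg.t_end),
            y0,
            method="RK45",
            t_eval=t_out,
            rtol=cfg.rel_tol,
            atol=cfg.abs_tol,
            dense_output=False,
        )
        if not sol.success:
            raise SimulationError(f"integration failed: {sol.message}")
        ys = sol.y.T
    else:
        ys = _simulate_dde(model, sig, spec, cfg, y0, t_out)

    ys = _clamp_negative(ys)
    u_vals = np.asarray(dxylose(t_out, sig), dtype=float)
    return Trajectory(
        times=t_out,
        x=ys[:, :n],
        z=ys[:, n:],
        u_values=u_vals,
        meta={"model": model, "input": sig, "feedback": spec, "config": cfg},
    )


def _simulate_dde(
    model: RegulonModel,
    sig: InputSignal,
    spec: FeedbackSpec,
    cfg: SimulationConfig,
    y0: np.ndarray,
    t_out: np.ndarray,
) -> np.ndarray:
    """Method-of-steps integration of the delayed system."""
    n = model.n
    tau = spec.tau
    segments: list = []  # (t_start, t_end, dense interpolant)
    starts: list[float] = []  # segment start times, for bisection lookup

    def history_z(t: float) -> np.ndarray:
        if t <= 0.0:
            return y0[n:]
        k = min(bisect.bisect_right(starts, t), len(segments)) - 1
        t0, t1, interp = segments[k]
        # t beyond the integrated range can only be roundoff past the edge
        return interp(min(t, t1))[n:]

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        return system_rhs(t, y, model, sig, spec, z_delayed=history_z(t - tau))

    t_start = 0.0
    y_start = y0
    while t_start < cfg.t_end - 1e-12:
        t_stop = min(t_start + tau, cfg.t_end)
        sol = solve_ivp(
            rhs,
            (t_start, t_stop),
            y_start,
            method="RK45",
            rtol=cfg.rel_tol,
            atol=cfg.abs_tol,
            dense_output=True,
        )
        if not sol.success:
            raise SimulationError(
                f"integration failed on [{t_start:.3f}, {t_stop:.3f}]: {sol.message}"
            )
        segments.append((t_start, t_stop, sol.sol))
        starts.append(t_start)
        y_start = sol.y[:, -1]
        t_start = t_stop

    ys = np.empty((t_out.size, 2 * n))
    for k, t in enumerate(t_out):
        if t <= 0.0:
            ys[k] = y0
            continue
        j = min(bisect.bisect_right(starts, t), len(segments)) - 1
        t0, t1, interp = segments[j]
        ys[k] = interp(min(t, t1))
    return ys


def relaxation_time(model: RegulonModel, gene_index: int) -> float:
    """Analytic mRNA relaxation time 1/k_d for gene ``gene_index`` (1-based).

    Returns ``inf`` when the degradation rate is zero (critically stable:
    the mRNA never relaxes).
    """
    if not 1 <= gene_index <= model.n:
        raise ValueError(f"gene_index must be in 1..{model.n}")
    k_d = model.genes[gene_index - 1].k_d
    return math.inf if k_d == 0 else 1.0 / k_d


def empirical_relaxation_time(
    model: RegulonModel,
    gene_index: int,
    u_level: float = 50.0,
    t_end: float = 40.0,
    dt_out: float = 0.005,
) -> float:
    """Relaxation time read off a simulation under sustained input.

    The network is held at its basal state, then a constant input of
    ``u_level`` is switched on; returns the time at which the gene's mRNA
    has closed all but 1/e of the gap to its new steady state, found by
    linear interpolation between output samples.
    """
    if not 1 <= gene_index <= model.n:
        raise ValueError(f"gene_index must be in 1..{model.n}")
    sig = InputSignal(u0=u_level * (1.0 + 1e-6), K=0.0, beta=1e-6)  # u(t) ~ u_level
    cfg = SimulationConfig(t_end=t_end, dt_out=dt_out)
    traj = simulate(model, sig, spec=None, cfg=cfg)
    xi = traj.x[:, gene_index - 1]
    x0 = xi[0]
    x_inf = steady_state(model, u_const=float(sig(0.0))).x[gene_index - 1]
    target = x0 + (1.0 - math.exp(-1.0)) * (x_inf - x0)
    crossed = np.nonzero(xi >= target)[0] if x_inf >= x0 else np.nonzero(xi <= target)[0]
    if crossed.size == 0:
        raise SimulationError("trajectory never reached the 1/e gap-closure level")
    k = crossed[0]
    if k == 0:
        return 0.0
    # linear interpolation between the bracketing samples
    frac = (target - xi[k - 1]) / (xi[k] - xi[k - 1])
    return float(traj.times[k - 1] + frac * dt_out)


def delay_sensitivity(
    model: RegulonModel,
    sig: InputSignal,
    spec: FeedbackSpec,
    cfg: SimulationConfig,
    tau_grid: Sequence[float],
) -> pd.DataFrame:
    """Peak metrics of every metabolite for each feedback delay in the grid.

    Returns a tidy frame with columns ``tau, variable, peak_value,
    peak_time, terminal_value`` — one row per (delay, state variable). The
    expected pattern for this regulon is profiles that nearly coincide
    across delays, with small differences concentrated at the peak and
    longer delays giving slightly lower peaks.
    """
    if len(tau_grid) == 0:
        raise ValueError("tau_grid must be nonempty")
    if any(t < 0 for t in tau_grid):
        raise ValueError("delays must be >= 0")
    rows = []
    for tau in tau_grid:
        traj = simulate(model, sig, spec.with_tau(float(tau)), cfg)
        for name, mat in (("x", traj.x), ("z", traj.z)):
            for i in range(model.n):
                series = mat[:, i]
                k = int(np.argmax(series))
                rows.append(
                    {
                        "tau": float(tau),
                        "variable": f"{name}{i + 1}",
                        "peak_value": float(series[k]),
                        "peak_time": float(traj.times[k]),
                        "terminal_value": float(series[-1]),
                    }
                )
    return pd.DataFrame(rows)
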