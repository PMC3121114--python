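"""Kinetic core of the XlnR regulon model.

The regulon is modeled as ``n`` genes: gene 1 is the master regulator
(*xlnR*), genes 2..n are its targets. Each gene contributes one mRNA state
``x_i`` and one protein state ``z_i``, giving a coupled 2n-dimensional ODE
system:

* transcription — the master gene is driven linearly by the external
  D-xylose signal ``u(t)``; target genes are activated by the master protein
  through a Hill function (Hill coefficient ``h = 1`` by default, XlnR binds
  as a monomer):

  .. math::

     \\dot x_1 = \\rho_1 + b_1 u(t) - k_{1d} x_1, \\qquad
     \\dot x_i = \\rho_i + k_{is}\\,\\psi^+(z_1, \\theta_i) - k_{id} x_i

* translation — linear synthesis and first-order decay:

  .. math::  \\dot z_i = r_i x_i - \\eta_i z_i

* optional delayed feedback — target proteins act back on the *xlnR* gene
  through a post-translational channel with delay ``tau``, gated by the
  carbon-catabolite repressor CreA; the drive is additive on
  :math:`\\dot x_1` (see :func:`feedback_drive`).

Units: time in hours, D-xylose in mM, mRNA/protein in arbitrary
concentration units; all rate constants are per hour.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "GeneKinetics",
    "RegulonModel",
    "InputSignal",
    "FeedbackSpec",
    "SystemState",
    "ConvergenceError",
    "hill_activation",
    "hill_repression",
    "dxylose",
    "crea_gate",
    "transcription_rates",
    "translation_rates",
    "feedback_drive",
    "steady_state",
    "promoter_activity",
    "model_to_dict",
    "model_from_dict",
    "save_config",
    "load_config",
]


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed to converge; carries the last residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneKinetics:
    """Kinetic parameters of one gene and its protein.

    Parameters
    ----------
    rho : float
        Basal (leaky) transcription rate, concentration/h.
    k_s : float
        Maximum synthesis rate of the Hill-activated term, concentration/h.
        Unused for the master gene.
    k_1 : float
        Effective affinity of the master protein for this gene's promoter;
        the Hill half-saturation constant is ``theta = 1/k_1`` (h = 1).
        Unused for the master gene.
    k_d : float
        First-order mRNA degradation rate, 1/h.
    r : float
        Specific translation rate, 1/h.
    eta : float
        First-order protein degradation rate, 1/h.
    b : float
        Input coupling coefficient (dimensionless); only the master gene is
        coupled to the D-xylose input in this regulon.
    """

    rho: float
    k_s: float = 0.0
    k_1: float = 0.0
    k_d: float = 1.0
    r: float = 1.0
    eta: float = 1.0
    b: float = 0.0

    def __post_init__(self) -> None:
        for name in ("rho", "k_s", "k_1", "k_d", "r", "eta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")

    @property
    def theta(self) -> float:
        """Half-saturation constant of the master protein on this promoter."""
        if self.k_1 <= 0:
            raise ValueError("theta undefined: k_1 must be > 0 for a target gene")
        return 1.0 / self.k_1


@dataclass(frozen=True)
class RegulonModel:
    """An ``n``-gene regulon: master gene first, targets after.

    ``genes[0]`` is the master *xlnR* gene; ``genes[1:]`` are targets whose
    promoters carry a binding site for the master protein.
    """

    genes: tuple[GeneKinetics, ...]
    h: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        if len(self.genes) < 1:
            raise ValueError("a regulon needs at least one gene")
        if self.h <= 0:
            raise ValueError("Hill coefficient h must be > 0")
        for g in self.genes[1:]:
            if g.k_1 <= 0:
                raise ValueError("target genes require k_1 > 0")

    @property
    def n(self) -> int:
        return len(self.genes)

    # vectorized parameter views, used by the rate functions and the Jacobian
    def _vec(self, name: str) -> np.ndarray:
        return np.array([getattr(g, name) for g in self.genes], dtype=float)

    @property
    def rho(self) -> np.ndarray:
        return self._vec("rho")

    @property
    def k_s(self) -> np.ndarray:
        return self._vec("k_s")

    @property
    def k_d(self) -> np.ndarray:
        return self._vec("k_d")

    @property
    def r(self) -> np.ndarray:
        return self._vec("r")

    @property
    def eta(self) -> np.ndarray:
        return self._vec("eta")

    @property
    def b(self) -> np.ndarray:
        return self._vec("b")

    @property
    def theta(self) -> np.ndarray:
        """Half-saturation constants; entry 0 (master) is NaN."""
        out = np.full(self.n, np.nan)
        for i, g in enumerate(self.genes[1:], start=1):
            out[i] = 1.0 / g.k_1
        return out


@dataclass(frozen=True)
class InputSignal:
    """Decaying D-xylose consumption signal u(t) = u0 / (beta + exp(K t)).

    ``beta`` defaults to 1e-6 so that u(0) is numerically the stated initial
    concentration; ``K`` sets the consumption speed (larger K, faster
    consumption). ``K = 0`` gives a sustained (constant) input.
    """

    u0: float = 50.0
    K: float = 0.3
    beta: float = 1e-6

    def __post_init__(self) -> None:
        if self.u0 < 0:
            raise ValueError("u0 must be >= 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")

    def __call__(self, t: float | np.ndarray) -> float | np.ndarray:
        return dxylose(t, self)


@dataclass(frozen=True)
class FeedbackSpec:
    """Delayed feedback of target proteins onto the *xlnR* gene.

    ``S1`` and ``S2`` hold 1-based gene indices into the protein vector:
    proteins in ``S1`` repress the master gene, proteins in ``S2`` activate
    it. The drive is delayed by ``tau`` hours and gated by CreA: in binary
    mode (default) the gate H is 0 when CreA is present and 1 when absent;
    in continuous mode H = 1/(1 + k_A * C_A).
    """

    S1: frozenset[int] = frozenset()
    S2: frozenset[int] = frozenset()
    k_RL: float = 1.0
    k_AL: float = 1.0
    k_ls: float = 1.0
    tau: float = 0.0
    creA_activity: float = 0.0
    k_A: float = 0.0
    creA_binary: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "S1", frozenset(int(i) for i in self.S1))
        object.__setattr__(self, "S2", frozenset(int(i) for i in self.S2))
        if self.S1 & self.S2:
            raise ValueError("S1 and S2 must be disjoint")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        for name in ("k_RL", "k_AL", "k_ls", "creA_activity", "k_A"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def validate_indices(self, n: int) -> None:
        for idx in self.S1 | self.S2:
            if not 1 <= idx <= n:
                raise ValueError(f"feedback index {idx} out of range 1..{n}")

    def with_tau(self, tau: float) -> "FeedbackSpec":
        return replace(self, tau=tau)


@dataclass
class SystemState:
    """mRNA vector ``x``, protein vector ``z`` and the time they refer to."""

    x: np.ndarray
    z: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.x.shape != self.z.shape or self.x.ndim != 1:
            raise ValueError("x and z must be 1-D arrays of equal length")

    @property
    def n(self) -> int:
        return self.x.size

    def as_vector(self) -> np.ndarray:
        """Concatenated state (x_1..x_n, z_1..z_n)."""
        return np.concatenate([self.x, self.z])

    @classmethod
    def from_vector(cls, y: np.ndarray, t: float = 0.0) -> "SystemState":
        y = np.asarray(y, dtype=float)
        n = y.size // 2
        return cls(x=y[:n], z=y[n:], t=t)


# ---------------------------------------------------------------------------
# elementary kinetics
# ---------------------------------------------------------------------------


def hill_activation(z: float, theta: float, h: float = 1.0) -> float:
    """Activating Hill function psi+(z, theta) = z^h / (theta^h + z^h).

    Equals 1/2 at ``z = theta`` (half-saturation) and increases
    monotonically from 0 to 1.
    """
    if theta <= 0 or h <= 0:
        raise ValueError("theta and h must be > 0")
    if z < 0:
        raise ValueError("z must be >= 0")
    if z == 0:
        return 0.0
    # evaluate via the ratio (z/theta)^h for scale robustness
    q = (z / theta) ** h
    return q / (1.0 + q)


def hill_repression(z: float, theta: float, h: float = 1.0) -> float:
    """Repressing Hill function psi-(z, theta) = 1 - psi+(z, theta)."""
    return 1.0 - hill_activation(z, theta, h)


def dxylose(t: float | np.ndarray, sig: InputSignal) -> float | np.ndarray:
    """D-xylose concentration u(t) = u0 / (beta + exp(K t)), mM."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = sig.u0 / (sig.beta + np.exp(sig.K * t))
    return float(out) if out.ndim == 0 else out


def crea_gate(spec: FeedbackSpec) -> float:
    """CreA gating factor H in [0, 1] applied to the feedback drive.

    Binary mode (the default): H = 0 when CreA is present
    (``creA_activity > 0``), H = 1 when absent. Continuous mode: the
    repressor Hill form H = 1 / (1 + k_A * C_A).
    """
    if spec.creA_binary:
        return 0.0 if spec.creA_activity > 0 else 1.0
    return 1.0 / (1.0 + spec.k_A * spec.creA_activity)


# ---------------------------------------------------------------------------
# system right-hand sides
# ---------------------------------------------------------------------------


def transcription_rates(
    state: SystemState, u: float, model: RegulonModel
) -> np.ndarray:
    """Open-loop mRNA rates dx/dt (feedback is added separately).

    Master gene: rho_1 + b_1*u - k_1d*x_1. Target gene i:
    rho_i + k_is * psi+(z_1, theta_i) - k_id * x_i.
    """
    if state.n != model.n:
        raise ValueError(f"state has {state.n} genes, model has {model.n}")
    if u < 0:
        raise ValueError("u must be >= 0")
    dx = np.empty(model.n)
    g0 = model.genes[0]
    dx[0] = g0.rho + g0.b * u - g0.k_d * state.x[0]
    z1 = state.z[0]
    for i, g in enumerate(model.genes[1:], start=1):
        dx[i] = g.rho + g.k_s * hill_activation(z1, g.theta, model.h) - g.k_d * state.x[i]
    return dx


def translation_rates(state: SystemState, model: RegulonModel) -> np.ndarray:
    """Protein rates dz/dt = r_i * x_i - eta_i * z_i (linear)."""
    if state.n != model.n:
        raise ValueError(f"state has {state.n} genes, model has {model.n}")
    return model.r * state.x - model.eta * state.z


def feedback_drive(z_delayed: np.ndarray, spec: FeedbackSpec) -> float:
    """Additive feedback rate on the master gene from delayed proteins.

    drive = H * k_ls * [ sum_{j in S1} 1/(1 + k_RL z_j)
                         + sum_{l in S2} k_AL z_l/(1 + k_AL z_l) ]

    Repressor terms start at 1 and fall with protein level; activator terms
    start at 0 and saturate at 1. The drive is bounded by
    H * k_ls * (|S1| + |S2|) and vanishes when CreA is present (H = 0) or
    k_ls = 0.
    """
    z_delayed = np.asarray(z_delayed, dtype=float)
    spec.validate_indices(z_delayed.size)
    H = crea_gate(spec)
    if H == 0.0 or spec.k_ls == 0.0:
        return 0.0
    total = 0.0
    for j in spec.S1:
        total += 1.0 / (1.0 + spec.k_RL * z_delayed[j - 1])
    for l in spec.S2:
        zl = spec.k_AL * z_delayed[l - 1]
        total += zl / (1.0 + zl)
    return H * spec.k_ls * total


def system_rhs(
    t: float,
    y: np.ndarray,
    model: RegulonModel,
    sig: InputSignal | None,
    spec: FeedbackSpec | None = None,
    z_delayed: np.ndarray | None = None,
    u_const: float | None = None,
) -> np.ndarray:
    """Full 2n right-hand side; helper shared by the integrator and solvers."""
    n = model.n
    state = SystemState(x=y[:n], z=y[n:], t=t)
    u = u_const if u_const is not None else (dxylose(max(t, 0.0), sig) if sig else 0.0)
    dx = transcription_rates(state, u, model)
    if spec is not None:
        zd = state.z if z_delayed is None else z_delayed
        dx[0] += feedback_drive(zd, spec)
    dz = translation_rates(state, model)
    return np.concatenate([dx, dz])


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------


def steady_state(
    model: RegulonModel,
    u_const: float = 0.0,
    spec: FeedbackSpec | None = None,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    damping: float = 0.5,
) -> SystemState:
    """Fixed point of the 2n system at constant input ``u_const``.

    At steady state the translation balance gives z_i* = r_i x_i* / eta_i
    exactly; the transcription balance then closes a scalar loop through the
    master protein (plus the feedback terms when ``spec`` is given), solved
    here by damped fixed-point iteration on the protein vector.

    Raises
    ------
    ConvergenceError
        If the max-norm update fails to drop below ``tol`` within
        ``max_iter`` iterations; the error carries the last residual.
    """
    if np.any(model.k_d <= 0) or np.any(model.eta <= 0):
        raise ValueError("steady state requires k_d > 0 and eta > 0 for all genes")
    n = model.n
    z = np.zeros(n)
    residual = math.inf
    for _ in range(max_iter):
        x = np.empty(n)
        g0 = model.genes[0]
        drive = feedback_drive(z, spec) if spec is not None else 0.0
        x[0] = (g0.rho + g0.b * u_const + drive) / g0.k_d
        z1 = max(z[0], 0.0)
        for i, g in enumerate(model.genes[1:], start=1):
            x[i] = (g.rho + g.k_s * hill_activation(z1, g.theta, model.h)) / g.k_d
        z_new = model.r * x / model.eta
        residual = float(np.max(np.abs(z_new - z)))
        z = (1.0 - damping) * z + damping * z_new
        if residual < tol:
            break
    else:
        raise ConvergenceError(
            f"steady-state iteration did not converge (residual {residual:.3e})",
            residual,
        )
    # close the translation balance exactly: z* = r x* / eta
    z = model.r * x / model.eta
    return SystemState(x=x, z=z, t=0.0)


# ---------------------------------------------------------------------------
# promoter occupancy
# ---------------------------------------------------------------------------


def promoter_activity(
    z_delayed: np.ndarray,
    spec: FeedbackSpec,
    competitive: bool = False,
) -> tuple[float, float, float]:
    """Promoter occupancy fractions (Gamma_A, Gamma_R, Gamma_A * Gamma_R).

    Gamma_A is the fraction of time the promoter is bound by activating
    feedback proteins, Gamma_R the fraction NOT blocked by repressing ones;
    their product is the combined activity under competitive binding.

    Default (separate binding sites): with lumped weights
    s_A = sum_{l in S2} k_AL z_l and s_R = sum_{j in S1} k_RL z_j,

        Gamma_A = s_A / (1 + s_A),   Gamma_R = 1 / (1 + s_R).

    ``competitive=True`` switches to a shared-denominator (single-site
    competition) variant: Gamma_A = s_A / (1 + s_A + s_R),
    Gamma_R = (1 + s_A) / (1 + s_A + s_R) (the site is not repressor-bound).
    """
    z_delayed = np.asarray(z_delayed, dtype=float)
    spec.validate_indices(z_delayed.size)
    if not spec.S2:
        raise ValueError("Gamma_A requested but the activator set S2 is empty")
    if not spec.S1:
        raise ValueError("Gamma_R requested but the repressor set S1 is empty")
    s_A = sum(spec.k_AL * z_delayed[l - 1] for l in spec.S2)
    s_R = sum(spec.k_RL * z_delayed[j - 1] for j in spec.S1)
    if competitive:
        denom = 1.0 + s_A + s_R
        gamma_a = s_A / denom
        gamma_r = (1.0 + s_A) / denom
    else:
        gamma_a = s_A / (1.0 + s_A)
        gamma_r = 1.0 / (1.0 + s_R)
    return gamma_a, gamma_r, gamma_a * gamma_r


# ---------------------------------------------------------------------------
# configuration serialization
# ---------------------------------------------------------------------------


def model_to_dict(
    model: RegulonModel,
    sig: InputSignal | None = None,
    spec: FeedbackSpec | None = None,
) -> dict:
    """Flat, YAML/JSON-friendly dictionary of all kinetic parameters."""
    d: dict = {
        "n": model.n,
        "h": model.h,
        "rho": [g.rho for g in model.genes],
        "k_s": [g.k_s for g in model.genes],
        "k_1": [g.k_1 for g in model.genes],
        "k_d": [g.k_d for g in model.genes],
        "r": [g.r for g in model.genes],
        "eta": [g.eta for g in model.genes],
        "b": [g.b for g in model.genes],
    }
    if sig is not None:
        d.update({"u0": sig.u0, "K": sig.K, "beta": sig.beta})
    if spec is not None:
        d.update(
            {
                "S1": sorted(spec.S1),
                "S2": sorted(spec.S2),
                "k_RL": spec.k_RL,
                "k_AL": spec.k_AL,
                "k_ls": spec.k_ls,
                "tau": spec.tau,
                "C_A": spec.creA_activity,
                "k_A": spec.k_A,
                "creA_binary": spec.creA_binary,
            }
        )
    return d


def model_from_dict(
    d: Mapping,
) -> tuple[RegulonModel, InputSignal | None, FeedbackSpec | None]:
    """Inverse of :func:`model_to_dict`."""
    n = int(d["n"])
    genes = tuple(
        GeneKinetics(
            rho=float(d["rho"][i]),
            k_s=float(d["k_s"][i]),
            k_1=float(d["k_1"][i]),
            k_d=float(d["k_d"][i]),
            r=float(d["r"][i]),
            eta=float(d["eta"][i]),
            b=float(d["b"][i]),
        )
        for i in range(n)
    )
    model = RegulonModel(genes=genes, h=float(d.get("h", 1.0)))
    sig = None
    if "u0" in d:
        sig = InputSignal(u0=float(d["u0"]), K=float(d["K"]), beta=float(d.get("beta", 1e-6)))
    spec = None
    if "S1" in d or "S2" in d:
        spec = FeedbackSpec(
            S1=frozenset(d.get("S1", ())),
            S2=frozenset(d.get("S2", ())),
            k_RL=float(d.get("k_RL", 1.0)),
            k_AL=float(d.get("k_AL", 1.0)),
            k_ls=float(d.get("k_ls", 1.0)),
            tau=float(d.get("tau", 0.0)),
            creA_activity=float(d.get("C_A", 0.0)),
            k_A=float(d.get("k_A", 0.0)),
            creA_binary=bool(d.get("creA_binary", True)),
        )
    return model, sig, spec


def save_config(path: str | Path, model: RegulonModel, sig=None, spec=None) -> None:
    """Write the parameter set to a YAML (``.yaml``/``.yml``) or JSON file."""
    path = Path(path)
    d = model_to_dict(model, sig, spec)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))


def load_config(path: str | Path):
    """Read a parameter file written by :func:`save_config`."""
    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return model_from_dict(d)
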