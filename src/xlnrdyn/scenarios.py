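"""Scenario generators: the canonical three-gene XlnR regulon and
randomized-but-plausible regulons for property testing.

The canonical scenario packages the reference kinetic parameterization of
the three-gene illustration (master *xlnR* gene plus two targets) together
with its D-xylose pulse; every number is stated literally so the scenario
is reproducible digit for digit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .model_core import (
    FeedbackSpec,
    GeneKinetics,
    InputSignal,
    RegulonModel,
    model_to_dict,
    save_config,
)

__all__ = [
    "Scenario",
    "canonical_scenario",
    "random_scenario",
    "degenerate_scenarios",
]


@dataclass(frozen=True)
class Scenario:
    """A complete run configuration: model, input signal, optional feedback."""

    model: RegulonModel
    input: InputSignal
    feedback: FeedbackSpec | None = None
    label: str = ""
    seed: int | None = None

    def to_dict(self) -> dict:
        d = model_to_dict(self.model, self.input, self.feedback)
        d["label"] = self.label
        if self.seed is not None:
            d["seed"] = self.seed
        return d

    def save(self, path: str | Path) -> None:
        save_config(path, self.model, self.input, self.feedback)


def canonical_scenario(with_feedback: bool = False) -> Scenario:
    """The canonical three-gene regulon driven by a 50 mM D-xylose pulse.

    Gene 1 is the master *xlnR* gene (b1 = 1, rho1 = 2e-3, k_1d = 0.5);
    genes 2 and 3 are targets with synthesis rates k_2s = 5, k_3s = 6 and
    promoter affinities k_21 = k_31 = 0.1 (half-saturation theta = 10). All
    translation rates are 0.5/h and all protein degradation rates 1/h. The
    input is u(t) = 50/(beta + exp(0.3 t)) mM.

    With ``with_feedback``, gene 3's protein activates and gene 2's protein
    represses the master gene (S2 = {3}, S1 = {2}), with lumped constants
    k_RL = k_AL = k_ls = 1, delay tau = 1 h, and CreA absent (binary gate
    open). Either role assignment is biologically admissible; this default
    is the one under which the activator dominates promoter occupancy and
    longer delays slightly lower the expression peaks — the behavior
    expected of the regulon — because gene 3's protein is the more abundant
    of the two (higher synthesis, slower mRNA decay).
    """
    genes = (
        GeneKinetics(rho=2e-3, k_d=0.5, r=0.5, eta=1.0, b=1.0),
        GeneKinetics(rho=2.5e-3, k_s=5.0, k_1=0.1, k_d=0.4, r=0.5, eta=1.0),
        GeneKinetics(rho=1e-3, k_s=6.0, k_1=0.1, k_d=0.3, r=0.5, eta=1.0),
    )
    model = RegulonModel(genes=genes, h=1.0)
    sig = InputSignal(u0=50.0, K=0.3, beta=1e-6)
    spec = None
    if with_feedback:
        spec = FeedbackSpec(
            S1=frozenset({2}),
            S2=frozenset({3}),
            k_RL=1.0,
            k_AL=1.0,
            k_ls=1.0,
            tau=1.0,
            creA_activity=0.0,
            creA_binary=True,
        )
    return Scenario(model=model, input=sig, feedback=spec, label="canonical-xlnr-3gene")


def random_scenario(
    seed: int,
    n: int = 3,
    ranges: dict[str, tuple[float, float]] | None = None,
    with_feedback: bool = False,
) -> Scenario:
    """A structurally valid random regulon, deterministic given ``seed``.

    Rates are drawn log-uniformly from ranges bracketing the canonical
    values by roughly an order of magnitude each way; basal transcription is
    kept far below the synthesis rates so basal mRNA levels stay low, as a
    leaky promoter should.
    """
    if n < 2:
        raise ValueError("random scenarios need n >= 2")
    defaults = {
        "rho": (1e-4, 1e-2),
        "k_s": (0.5, 50.0),
        "k_1": (0.01, 1.0),
        "k_d": (0.05, 5.0),
        "r": (0.05, 5.0),
        "eta": (0.1, 10.0),
        "u0": (5.0, 500.0),
        "K": (0.03, 3.0),
    }
    if ranges:
        for key, (lo, hi) in ranges.items():
            if key not in defaults:
                raise ValueError(f"unknown parameter range: {key}")
            if not (0 < lo <= hi):
                raise ValueError(f"invalid range for {key}: ({lo}, {hi})")
            defaults[key] = (lo, hi)
    rng = np.random.default_rng(seed)

    def draw(key: str) -> float:
        lo, hi = defaults[key]
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    genes = [
        GeneKinetics(rho=draw("rho"), k_d=draw("k_d"), r=draw("r"), eta=draw("eta"), b=1.0)
    ]
    for _ in range(n - 1):
        genes.append(
            GeneKinetics(
                rho=draw("rho"),
                k_s=draw("k_s"),
                k_1=draw("k_1"),
                k_d=draw("k_d"),
                r=draw("r"),
                eta=draw("eta"),
            )
        )
    model = RegulonModel(genes=tuple(genes), h=1.0)
    sig = InputSignal(u0=draw("u0"), K=draw("K"), beta=1e-6)
    spec = None
    if with_feedback:
        targets = list(range(2, n + 1))
        rng.shuffle(targets)
        half = len(targets) // 2
        spec = FeedbackSpec(
            S1=frozenset(targets[:half]),
            S2=frozenset(targets[half:]),
            k_RL=1.0,
            k_AL=1.0,
            k_ls=float(rng.uniform(0.5, 5.0)),
            tau=float(rng.uniform(0.0, 5.0)),
        )
    return Scenario(
        model=model, input=sig, feedback=spec, label=f"random-n{n}-seed{seed}", seed=seed
    )


def degenerate_scenarios() -> dict[str, Scenario]:
    """Named edge cases exercising critical stability and silenced drives.

    ``zero_kd``: one mRNA degradation rate is zero, so the spectrum has a
    zero eigenvalue (critically stable). ``zero_basal``: no leaky
    transcription. ``zero_input``: nothing perturbs the basal state.
    ``zero_delay``: feedback without delay. ``crea_present``: binary CreA
    gate closed, silencing the feedback drive entirely.
    """
    base = canonical_scenario()
    fb = canonical_scenario(with_feedback=True)
    genes = list(base.model.genes)

    zero_kd_genes = [genes[0], replace(genes[1], k_d=0.0), genes[2]]
    zero_basal_genes = [replace(g, rho=0.0) for g in genes]

    cases = {
        "zero_kd": Scenario(
            model=RegulonModel(genes=tuple(zero_kd_genes)),
            input=base.input,
            label="degenerate-zero-kd",
        ),
        "zero_basal": Scenario(
            model=RegulonModel(genes=tuple(zero_basal_genes)),
            input=base.input,
            label="degenerate-zero-basal",
        ),
        "zero_input": Scenario(
            model=base.model,
            input=InputSignal(u0=0.0, K=0.3, beta=1e-6),
            label="degenerate-zero-input",
        ),
        "zero_delay": Scenario(
            model=fb.model,
            input=fb.input,
            feedback=fb.feedback.with_tau(0.0),
            label="degenerate-zero-delay",
        ),
        "crea_present": Scenario(
            model=fb.model,
            input=fb.input,
            feedback=FeedbackSpec(
                S1=fb.feedback.S1,
                S2=fb.feedback.S2,
                k_RL=fb.feedback.k_RL,
                k_AL=fb.feedback.k_AL,
                k_ls=fb.feedback.k_ls,
                tau=fb.feedback.tau,
                creA_activity=1.0,
                creA_binary=True,
            ),
            label="degenerate-crea-present",
        ),
    }
    return cases
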