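# xlnrdyn

Dynamics and stability analysis of the D-xylose-induced **XlnR regulon** of
*Aspergillus niger*, for systems biologists studying how a master
transcriptional activator and its target genes respond to a sugar pulse —
and how feedback from target proteins reshapes that response.

The regulon is modeled as 2n coupled ODEs: per gene, mRNA `x_i` with
Hill-function transcription and first-order decay, and protein `z_i` with
linear translation and decay. Gene 1 (*xlnR*) is driven by the decaying
D-xylose signal `u(t) = u0/(β + e^{Kt})`; target genes are activated by the
XlnR protein through `ψ⁺(z₁, θ) = z₁/(θ + z₁)` (monomeric binding, Hill
coefficient 1). Optional delayed feedback of target proteins on the master
gene — repressing (set `S1`) or activating (`S2`), delayed by `τ`, gated by
the CreA carbon-catabolite repressor — is added to the master-gene
equation. The package provides:

* **simulation** of the pulse response, with the delay handled by the
  method of steps (`xlnrdyn.simulate`);
* **stability analysis**: analytic Jacobians, the open-loop spectrum
  (exactly the negated degradation rates), closed-form eigenvalues for
  master-protein autoregulation
  `λ₅,₆ = ½[−(η₁+k₁d) ± √((η₁−k₁d)² + 4r₁ω₁)]`, and stability/oscillation
  index scans over feedback gains with bisection-refined thresholds
  (`xlnrdyn.scan_feedback_gain`);
* **promoter occupancy** fractions Γ_A, Γ_R and their product under
  competing feedback regulators;
* **scenarios**: the canonical three-gene reference parameterization plus
  seeded random regulons for property testing;
* a **CLI** (`xlnrdyn simulate|scan|promoter|report`) writing CSV/JSON
  (optionally PNG plots) with full provenance records.

## Worked example

```python
import numpy as np
from xlnrdyn import (canonical_scenario, simulate, SimulationConfig,
                     relaxation_time, empirical_relaxation_time,
                     omega1_conditions, steady_state, scan_feedback_gain)

sc = canonical_scenario(with_feedback=True)
cfg = SimulationConfig(t_end=50.0, dt_out=0.1)

open_run = simulate(sc.model, sc.input, None, cfg)
fb_run = simulate(sc.model, sc.input, sc.feedback, cfg)
print(f"master mRNA peak, open loop : {open_run.x[:, 0].max():.2f}")
print(f"master mRNA peak, feedback  : {fb_run.x[:, 0].max():.2f}")
print(f"relaxation time 1/k_1d      : {relaxation_time(sc.model, 1):.1f} h")
print(f"empirical (1/e) estimate    : {empirical_relaxation_time(sc.model, 1):.2f} h")

osc, stab = omega1_conditions(sc.model)
print(f"omega_1 stability threshold : {stab:.3f}")
print(f"omega_1 oscillation bound   : {osc:.3f}")

ss = steady_state(sc.model, u_const=sc.input.u0)
res = scan_feedback_gain(sc.model, (1, 5), np.linspace(-1000, 0, 201), ss)
print(f"(1,5) stability crossing    : {res.thresholds['stability'][0]:.1f}")
```

prints

```
master mRNA peak, open loop : 46.47
master mRNA peak, feedback  : 47.95
relaxation time 1/k_1d      : 2.0 h
empirical (1/e) estimate    : 2.00 h
omega_1 stability threshold : 1.000
omega_1 oscillation bound   : -0.125
(1,5) stability crossing    : -271.9
```

Reading: the 50 mM D-xylose pulse drives the master mRNA from its basal
level (0.004) to a peak near 46, decaying back as the sugar is consumed;
the delayed feedback loop (CreA absent) raises that peak and the late-time
levels. The master mRNA relaxes on the `1/k_1d = 2 h` timescale, and the
simulation-based 1/e estimator recovers exactly that. Positive
autoregulation of the *xlnR* gene destabilizes the regulon once the
feedback gain `ω₁` exceeds `η₁k₁d/r₁ = 1`; negative `ω₁` is always stable,
oscillatory (damped) below −0.125. Feedback through a *target* protein
(Jacobian cell (1,5)) destabilizes only at strongly negative gains — near
−272 when the Jacobian is evaluated at the sustained-input steady state;
this threshold moves with the chosen operating point, which is why every
scan records it.

The same analyses from the shell:

```sh
xlnrdyn simulate --scenario canonical-feedback --tau 1 --tau 5 --outdir out
xlnrdyn scan --position 1,4 --outdir out
xlnrdyn promoter --k-ls 1 --k-ls 5 --outdir out
xlnrdyn report --outdir out
```

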