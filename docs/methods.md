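# Methods

## The model

`xlnrdyn` models the XlnR regulon of *Aspergillus niger* as an `n`-gene
transcription–translation system. Gene 1 is the master regulator *xlnR*;
genes 2..n are target genes (xylanolytic/cellulolytic enzymes) whose
promoters carry a binding site for the XlnR protein. Each gene contributes
an mRNA concentration `x_i(t)` and a protein concentration `z_i(t)`,
giving 2n coupled ODEs:

    dx_1/dt = rho_1 + b_1 u(t) - k_1d x_1            (master gene)
    dx_i/dt = rho_i + k_is psi+(z_1, theta_i) - k_id x_i,  i >= 2
    dz_i/dt = r_i x_i - eta_i z_i                     (translation)

with the activating Hill function `psi+(z, theta) = z^h / (theta^h + z^h)`
and its complement `psi- = 1 - psi+`. The Hill coefficient defaults to
`h = 1` because XlnR is thought to bind DNA as a monomer; promoter
affinities are parameterized as `k_i1 = 1/theta_i`. The D-xylose trigger is
the decaying consumption signal

    u(t) = u0 / (beta + exp(K t)),

a pulse that starts at (numerically) `u0` and is consumed at rate `K`.
Larger `K` means faster consumption and a shorter induction window.

### Delayed feedback and the CreA gate

Target proteins can act back on the *xlnR* gene through a delayed
post-translational channel. The drive is additive on `dx_1/dt`:

    drive(t) = H * k_ls * [ sum_{j in S1} 1/(1 + k_RL z_j(t - tau))
                          + sum_{l in S2} k_AL z_l(t - tau)/(1 + k_AL z_l(t - tau)) ]

`S1` indexes repressing proteins (their term starts at 1 and falls as the
protein accumulates), `S2` activating ones (starts at 0, saturates at 1),
`k_ls` is a lumped synthesis strength, and `tau` the channel delay in
hours. `H` is the CreA carbon-catabolite-repression gate: binary by default
(`H = 0` CreA present, `H = 1` absent — CreA blocks the promoter
outright), with a continuous alternative `H = 1/(1 + k_A C_A)` for graded
repressor activity. A silenced drive (`H = 0` or `k_ls = 0`) reduces the
system to the open loop exactly, and the simulator takes the plain-ODE path
in that case so gated runs and open-loop runs are bit-identical.

Several functional forms here (the target-gene transcription term, the
feedback drive, the promoter activities below) are canonical
Hill/mass-action reconstructions chosen from the standard repertoire; each
sits behind a single function so an alternative form is a one-function
change.

### Promoter occupancy

Promoter activity under competing feedback regulators is summarized by
occupancy fractions built from the lumped weights
`s_A = sum_{S2} k_AL z_l` and `s_R = sum_{S1} k_RL z_j`:

    Gamma_A = s_A / (1 + s_A)      (activator-bound fraction)
    Gamma_R = 1 / (1 + s_R)        (fraction not blocked by repressor)

with the product `Gamma_A * Gamma_R` as the combined activity. A
shared-denominator variant (`competitive=True`), in which activator and
repressor compete for a single site, is provided behind a flag; the
separate-site product form is the default.

## Canonical scenario

The packaged three-gene scenario uses: `b1 = 1`, `rho = (2e-3, 2.5e-3,
1e-3)`, `k_d = (0.5, 0.4, 0.3)` 1/h, `k_s = (5, 6)` and `k_1 = 0.1`
(theta = 10) for the targets, `r = 0.5` 1/h and `eta = 1` 1/h for all
genes, input `u0 = 50 mM`, `K = 0.3` 1/h. Feedback runs add `k_RL = k_AL =
k_ls = 1`, `tau = 1 h`, CreA absent. `beta = 1e-6` (the input-signal
offset is otherwise unconstrained; this makes `u(0)` equal the stated
initial concentration to six digits).

Which target protein activates and which represses the master gene is not
biologically determined here; the package's default makes gene 3's protein
the activator and gene 2's the repressor (`S2 = {3}`, `S1 = {2}`). Gene 3's
protein is the more abundant of the two (higher synthesis rate, slower
mRNA decay), and under this assignment the regulon shows the expected
behavior: the activator occupies more promoter sites than the repressor
blocks through the active window, and longer feedback delays give slightly
lower expression peaks. The opposite assignment reverses both effects; the
role sets are plain configuration fields.

## Numerics

* **Integration.** `scipy.integrate.solve_ivp` (RK45, `rtol = 1e-8`,
  `atol = 1e-10`), output sampled every 0.1 h over a 50 h default horizon —
  the timescale on which the pulse response plays out. With `tau > 0` the
  delay system is integrated by the method of steps: segments of length
  `tau`, delayed protein values read from the dense interpolant of the
  already-integrated past (binary-searched over segments), constant
  pre-trigger history equal to the basal steady state. Halving tolerances
  moves trajectories by less than 1e-4 relative (tested).
* **Steady states.** Damped fixed-point iteration on the protein vector
  (damping 0.5, max-norm tolerance 1e-10, cap 10,000 iterations); the
  translation balance `z* = r x* / eta` is closed exactly afterwards. The
  open-loop fixed point is a scalar contraction through `psi+`;
  non-convergence raises an error carrying the residual.
* **Negative concentrations.** Stiff transients near zero basal levels can
  undershoot by roundoff; output values are clamped to zero with a logged
  warning rather than aborting.
* **Relaxation time.** Analytically `1/k_d` per gene (infinite when
  `k_d = 0`, the critically stable case). The empirical estimator switches
  on a sustained input, simulates at 0.005 h sampling, and interpolates the
  time at which the mRNA closes all but `1/e` of the gap to its new steady
  state; it agrees with `1/k_d` to well under 15% for the master gene.

## Stability analysis

The Jacobian of the 2n system, ordered `(x, z)`, is assembled in closed
form; its open-loop spectrum is exactly the negated degradation rates
`{-k_id} ∪ {-eta_i}` — the open loop is globally stable, cannot oscillate,
and its trace equals the eigenvalue sum. Feedback adds entries in row 1's
protein columns; the scans treat the entry at cell `(1, n+i)` as a free
gain `omega_i`, decoupled from the mechanistic `k_RL`/`k_AL` derivatives
(both representations are available from `jacobian_analytic`).

For master-protein autoregulation (cell `(1, n+1)`) the perturbed pair is

    lambda_{5,6} = [-(eta_1 + k_1d) ± sqrt((eta_1 - k_1d)^2 + 4 r_1 omega_1)]/2

giving the closed-form thresholds: oscillation (complex pair) iff
`omega_1 < -(eta_1 - k_1d)^2/(4 r_1)`, stability iff
`omega_1 < eta_1 k_1d / r_1`. Complex pairs have fixed real part
`-(eta_1 + k_1d)/2 < 0`, so negative feedback on this cell is always
stable (damped oscillation at most), and the stability loss at
`omega_1 = eta_1 k_1d / r_1` happens through a **real zero eigenvalue**,
not a finite-frequency pair — `bifurcation_report` states both facts
rather than labeling the crossing a Hopf point.

**Scans.** `scan_feedback_gain` sweeps one gain over a grid (default 2001
points on (-1000, 1000)), computes the spectrum at each point, derives ±1
stability/oscillation indices (tolerance `1e-9 * max(1, ||J||)`, the
eigensolver noise floor; spectra within it are flagged critical and mapped
to stable), and refines every index sign change by bisection to 1e-6. The
refinement bisects the raw eigenvalue signs so the located flip is not
offset by the index noise floor.

**Evaluation point.** The Jacobian of the nonlinear system must be
evaluated somewhere. The default operating point for scans is the steady
state under sustained input `u = u0` with no feedback drive — the fully
responsive window of the regulon. This choice matters: the crossing for
the target-protein cells `(1, n+2)`, `(1, n+3)` scales roughly with
`(theta + z_1*)^2` through the promoter-activation derivative, so a
different operating point moves those thresholds substantially (at the
canonical point they sit near -272 and -186; at the basal point they are
two orders of magnitude smaller). The evaluation point is therefore an
explicit argument, recorded in every `ScanResult` and in the threshold
JSON the CLI writes. The delay `tau` is not part of the eigenvalue
analysis (the Jacobian is delay-free; delay-aware stability would need
transcendental characteristic equations, out of scope).

## Synthetic scenarios

`random_scenario(seed, n)` draws rates log-uniformly from ranges bracketing
the canonical values by roughly an order of magnitude (degradation
0.05–5 /h, synthesis 0.5–50, affinity 0.01–1, translation 0.05–5 /h,
protein decay 0.1–10 /h, input 5–500 mM, consumption 0.03–3 /h), keeping
basal rates far below synthesis rates so basal mRNA stays leaky-low.
These scenarios emulate the structure of the study system — one master
activator, Hill-regulated targets, first-order decay — not real expression
data: there is no measurement noise, no cell-to-cell variability, no
resource competition, and no parameter correlations. Passing property
tests on them demonstrates the analytic structure (Jacobian correctness,
spectrum identities, threshold recovery) across the plausible parameter
range, not predictive accuracy for *A. niger* cultures.
`degenerate_scenarios()` packages the edge cases: a zero mRNA-degradation
rate (zero eigenvalue, critical stability), zero basal rates (all-zero
rest state), zero input (nothing perturbs the system), zero delay, and
CreA present (feedback silenced).

## Problem sizes

The test suite and the acceptance script run the three-gene canonical
system throughout (6 ODEs); property suites use 50 seeded random
three-gene regulons with 2 random evaluation states each for the
finite-difference Jacobian check, and bisection-refined scans on 41-point
grids for threshold recovery. These sizes characterize the method fully —
every analytic identity checked is dimension-independent — and keep the
whole suite in seconds.

## Known limitations

* The delay enters simulation only; stability analysis linearizes the
  delay-free system.
* Promoter-activity forms are standard reconstructions (see above); only
  their qualitative contracts (bounds, monotonicity, role of `k_ls`) are
  asserted.
* No parameter estimation, no SBML import/export, no stochastic
  (chemical-master-equation) simulation; the model is deterministic and
  noise-free by design.
* Target-protein feedback thresholds are operating-point-dependent;
  reported numbers are meaningful only together with the evaluation point,
  which the package always records alongside them.
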