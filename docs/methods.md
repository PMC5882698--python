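# Methods

## The single-variant model

`phagewave` simulates a lytic phage–bacteria system in a well-mixed aquatic
environment.  The single-variant (three-population) model tracks susceptible
bacteria `S(t)`, infected bacteria `I(t)` and free phage `P(t)`:

    dS/dt = alpha*S*(1 - (S + I)/C) - k*S*P
    dI/dt = k*S*P - lam*I
    dP/dt = b*lam*I - k*S*P - mu*P

Assumptions: logistic host growth (rate `alpha`, carrying capacity `C`,
shared between susceptible and infected cells), bilinear (mass-action)
infection `k*S*P`, no reproduction of infected cells, lysis at rate `lam`
releasing `b` virions on average, first-order phage decay `mu`, and loss of
one free virion per adsorption.  Default parameters (units: day⁻¹ except
`C` in cells·ml⁻¹, `k` in ml·cell⁻¹·day⁻¹, `b` dimensionless):

| parameter | default | meaning |
|-----------|---------|---------|
| `alpha`   | 1.5     | bacterial per-capita growth rate |
| `C`       | 100     | carrying capacity |
| `k`       | 0.002 (at `r = 1`) | infection rate constant |
| `lam`     | 3       | lysis rate (mean latent period 1/3 day) |
| `b`       | 149.254 | burst size |
| `mu`      | 20      | free-phage decay rate |

The basic reproduction number `R0 = (b - 1) k C / mu` organizes the phase
portrait: the phage-free state `Ef = (C, 0, 0)` is stable for `R0 <= 1`;
at `R0 = 1` a saddle–node bifurcation creates the coexistence state
`E+ = (C/R0, alpha*C/(lam*R0 + alpha) * (R0-1)/R0, lam*R0*I+/(k*C))`,
which loses stability in a supercritical Hopf bifurcation as `R0` grows
(the paradox of enrichment).  `hopf_threshold` locates the critical
parameter value numerically: it samples the spectral abscissa of the exact
Jacobian at `E+` along one parameter axis, brackets the sign change and
bisects (`scipy.optimize.brentq`).  With the defaults above the threshold
along `k` is `k* ≈ 0.01353` (`R0* ≈ 10.03`).  No analytic expression for
the threshold is asserted; the scan reports a numerical crossing and makes
no claim about the criticality type.

## The evolution model

To model evolution, phage variants are arranged along a dimensionless
phenotype coordinate `r` in a truncated interval `(0, r_end]`.  A fitness
landscape assigns each variant its traits `k(r), lam(r), mu(r), b(r)`; the
variant fitness is `R0(r) = (b(r)-1) C k(r) / mu(r)`.  The shipped presets
use the linear landscape `k(r) = xi*r` with the other traits constant
(`baseline`: `xi = 0.002`; `enriched`: `xi = 0.02`), so fitness grows
linearly along `r`.  Mutation is modelled as diffusion of the infected
density in phenotype space with a small constant dispersion coefficient
`q = 1e-6 day⁻¹`:

    dS/dt   = alpha*S*(1 - (S + Int[i])/C) - S*Int[k(r) p]
    di/dt   = k(r) p S - lam(r) i + q * d²i/dr²
    dp/dt   = -k(r) p S - mu(r) p + b(r) lam(r) i

No explicit law of evolution is imposed: random mutation (diffusion) plus
competition for the shared susceptible pool produce a pulse-shaped
travelling wave moving toward higher `R0(r)`.

Initial condition: `S(0) = C`, `i ≡ 0`, and a Gaussian phage pulse centred
at `r = 1` (default width 0.05, total mass 1 virion·ml⁻¹, renormalized on
the grid to the requested integral).  The pulse parameters are not critical
for late-time behaviour — they shift the early transient by a few days —
but they are configurable and recorded in the run manifest.

## Discretization

* Uniform grid on `(0, r_end]`, node `j` at `j*dr`, defaults `r_end = 20`,
  `n = 4000` (`dr = 0.005`).  All phenotype integrals use the composite
  trapezoid rule on this grid (second order, matching the Laplacian).
* The Laplacian is the central second difference.  Two boundary closures
  exist.  The `robin` closure implements the condition
  `q * d(field)/dn = field` with the *outward* normal at both ends via
  first-order ghost-node elimination.  At the right end this orientation
  pumps mass into the boundary node at rate `~1/dr` (the continuum problem
  has a boundary-layer mode growing at rate `~1/q`), so it is usable only
  while the solution is identically zero near the boundary; in long runs
  round-off seeds the unstable mode and the run overflows.  The presets
  therefore default to the `no-flux` (homogeneous Neumann) closure, which
  is indistinguishable from the Robin one in the interior while the wave
  stays away from the walls — a condition the simulator monitors (a warning
  fires when >0.1% of any field's mass sits in the outermost 5% of the
  grid).  With `q = 0` the operator degenerates to the zero map and the
  model decouples into independent single-variant systems, which is used as
  an exact reduction oracle in the tests.

## Time integration

Method-of-lines produces a stiff ODE system of dimension `2n + 1`.  The
state is interleaved `[i_1, p_1, ..., i_n, p_n, S]` so the Jacobian is
banded (bandwidth 2) in the field block plus one dense border row/column
for `S` — an arrowhead matrix.  The integrator (`phagewave._stepper`) is
the one-step, L-stable TR-BDF2 pair (trapezoidal stage to `t + gamma*h`,
`gamma = 2 - sqrt(2)`, then a BDF2 stage; both stages share the iteration
matrix `M = I - (gamma/2) h J`).  Newton systems are solved in O(n) by a
banded LU (`LAPACK dgbtrf/dgbtrs`) of the field block plus a scalar Schur
complement for the border (bordering method).  The embedded third-order
error estimate is filtered through `M⁻¹` so stiff components do not force
spurious rejections; factorizations are reused while the step size stays
within 30% of the factored one.  Output snapshots are cubic-Hermite
interpolants of the accepted steps, so the output cadence never constrains
the step size.  Default tolerances: `rtol = 1e-6`, `atol = 1e-9`; runs are
bit-reproducible for a fixed configuration (no randomness anywhere in the
pipeline).

Two measures keep the deep oscillatory regime integrable:

* **Positivity projection.**  After each accepted step the state is clipped
  to the non-negative cone.  Non-negativity is an invariant of the exact
  flow, but in the enriched regime the fields pass through troughs many
  orders of magnitude below any affordable absolute tolerance; without the
  projection, sign-indefinite solver noise seeded in a trough is amplified
  exponentially by the next outbreak and the run blows up.  Clipping only
  on output is not sufficient.
* **Susceptible floor.**  `S = 0` is an absorbing state of the logistic
  term that the exact flow never reaches (the true minima `~exp(-Int[k P])`
  merely drop below solver resolution), so after projection `S` is kept at
  one `atol` (1e-9 cells·ml⁻¹) rather than allowed to stick at zero, which
  would extinguish the host population permanently and with it the cycles.

The trough densities themselves bottom out near the solver's noise floor;
this is a property of *any* linear-scale integration of this regime, and it
means the phase of the late cycles (not their existence, amplitude scale,
or period trend) depends on tolerances.  The late-time quasi-species means
are insensitive to it: tightening `atol` from 1e-9 to 1e-14 moves the
enriched 1000-day mean `k` by under 2%.

## What the endpoint numbers do and do not mean

The travelling wave advances through its exponential leading edge.  With
`q = 1e-6` the edge decays on a scale `~sqrt(q/sigma)` (of order 1e-3 in
`r`), well below any affordable grid spacing, so the *numerical* wave speed
retains a resolution dependence: on the default grid the baseline run's
1000-day mean `k` is 0.0094, dropping toward ≈0.0072 under repeated grid
doubling (n = 16000), i.e. the default-grid speed is a property of the
discretized system rather than a converged property of the continuum PDE.
All qualitative observables — monotone wave advance, monotone decline of
`S`, the stable-vs-oscillatory dichotomy, growing oscillation periods — are
robust across every grid and tolerance we tested; the quantitative endpoint
means should be read with this caveat.  The grid-refinement test documents
the actual sensitivity rather than assuming convergence.

## Observables

* Totals `I(t) = Int[i]`, `P(t) = Int[p]` by composite trapezoid.
* Quasi-species means of `k(r)` or `R0(r)`, weighted by the infected field
  by default (`p`-weighting available; the two agree closely because the
  phage distribution is slaved to the infected one).
* Wave position: centroid of the infected field by default (stable under
  oscillations); `argmax` with parabolic sub-node refinement as an
  alternative.  Speed by central finite differences.
* Oscillation detection: peaks of the linearly detrended series with
  minimum prominence 5% of the series range (ignores solver ripple).
  *Sustained* means the last half of the record still contains ≥3 peaks
  whose median prominence is at least half the record's median — this
  separates self-sustained cycles from decaying transients while tolerating
  the genuine amplitude modulation of the deep predator–prey cycles (late
  peak heights vary by a factor ~2 in a multi-cycle envelope).  Peak-based
  measurements need the scalar series sampled at ~1-day cadence: the S
  recovery spikes are only 1–2 days wide while the default snapshot cadence
  for file output is 5 days.

## Degenerate inputs and numerical edges

* `b <= 1` (no net phage production) is a warning, not an error; `R0 <= 0`.
* `R0 = 1` exactly: `E+` is reported absent (it coincides with `Ef`).
* Grids with fewer than 16 nodes are rejected; `q < 0` is rejected.
* A zero-mass weighting field makes quasi-species means undefined (error).
* The argmax wave position clamps its parabolic offset to one node.
* Initial pulses truncated by the domain (>1% of Gaussian mass) warn.

## Known limitations

* One phenotype dimension only; only `k(r)` varies in the shipped presets,
  although all four trait functions are supported (and can be tabulated).
* No bacterial evolution or co-evolution; no extinction thresholds (the
  deep cycles would realistically extinguish one or both populations).
* The outward-normal Robin boundary closure is provided for completeness
  but is unusable for long runs (see above); the default is reflecting ends plus a
  wall-contact warning.
* Endpoint trait means on affordable grids carry the resolution dependence
  described above.
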