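# Methods

## Model

`betadisp` integrates a non-stationary electrodiffusion equation for a
dimensionless electric potential field ψ(x, y, t) on a rectangular grid:

    ∂ψ/∂t = ∇²ψ − κ² sinh ψ + w(x) s(t)

The equation interpolates between the stationary Poisson–Boltzmann equation
(left side set to zero) and the classical diffusion equation (κ = 0). The
screening parameter κ is an inverse Debye-length-like constant: it bundles
the mobile-charge density, permittivity and temperature of the medium into
one number, and larger κ means the external field is screened over a
shorter distance. κ is treated as a free input; mapping it to a physical
electrolyte is a calibration task outside this package, for which two
reporting-time scale factors (length per grid cell, seconds per numerical
time unit) are exposed in the run configuration. They never enter the
stepper.

The forcing is separable. The spatial weight w(i) = 1 − ln(1+i)/ln(nx)
(clamped to [0, 1]) is maximal at the left edge and decays logarithmically
to zero at the right edge — a smoothed electrode footprint chosen over a
Dirac delta for numerical convergence. The temporal part is harmonic,
s(t) = A sin(2πft), with f the drive frequency in cycles per numerical
time unit. All frequencies inside the engine are numerical; output labels
use "Hz" with the time-scale factor recorded alongside so the labelling is
reversible.

Boundaries are zero-flux (Neumann) on all four sides, realized by
first-order ghost mirroring: the stencil value outside the border equals
the adjacent border value. This makes the discrete Laplacian sum to zero
over the domain exactly (up to rounding), which is the conservation
property the tests check to 1e−10.

A constant-charge normalization subtracts the domain mean of ψ after every
step. "Constant charge" is ambiguous at the discrete level; zero spatial
mean of ψ is the simplest condition consistent with it (the linearized
charge density is proportional to sinh ψ ≈ ψ), it is idempotent, and it
alters the dynamics only by removing the spatially uniform mode.
Alternatives (conserving Σ sinh ψ, or per-sub-domain conservation for
structured domains) were considered and not implemented; `mode="none"` is
available for experiments.

## Numerics

* **Time integration** is explicit Euler. The stability bound for the 2D
  five-point diffusion stencil is dt ≤ h²/4; the default dt is 20% of that
  (0.05 for h = 1), and exceeding the bound is a hard error raised before
  any stepping. The acceptance-scale sweeps run at dt = 0.2 (80% of the
  bound): the modes that carry the response have rates ~(π/L)² ≪ 1/dt, so
  the Euler amplitude error stays well below the 2% oracle tolerance
  (measured ≲ 0.3% at 50 steps per period, the worst case probed).
* **Blow-up guard**: if |ψ| exceeds 30 anywhere the stepper raises a
  stability error naming dt and max|ψ|. sinh overflows double precision
  only near 710, but the model is meaningless long before that.
* **Initial conditions** are IID uniform on [−0.05, +0.05], drawn from a
  seeded generator. A single root seed deterministically derives one child
  seed per sweep frequency (`numpy` SeedSequence spawning), so any sweep is
  bit-reproducible from its configuration, and κ-families share identical
  initial fields point for point.

## Response measurement

The simulated "EIS response" at one frequency is the steady-state
oscillation amplitude of the mean of ψ over the right-edge column (the
side opposite the forcing; the mean is robust to ny parity, unlike a
corner sample). The protocol is:

1. **Transient window** (discarded): the longer of `transient_periods`
   drive periods (default 5, minimum 2), `settle_multiple` × (L/π)² time
   units (default 10 — ten times the slowest diffusive relaxation time of
   the domain, L = nx·h), and 200·dt. The settle floor matters at high
   frequency, where a few drive periods are far shorter than the domain's
   own relaxation: without it the random initial field has not decayed and
   leaks into the measurement.
2. **Measurement window**: `measure_periods` drive periods (default 4,
   minimum 2), recorded every step.
3. **Amplitude estimator**: single-bin Fourier projection of the demeaned
   edge signal onto exp(−i2πft) over the largest whole number of periods
   that fits at the end of the window. Exact for a pure tone, insensitive
   to constant offsets, and with spectral leakage controlled by the
   integer-period window; preferred over (max−min)/2, which is
   noise-sensitive. The sampling precondition f·dt < 0.5 is enforced.

Each frequency starts from a fresh initial field rather than continuing
from the previous frequency, so sweep results are independent of sweep
order.

## The linearized frequency-domain oracle

For small fields, sinh ψ ≈ ψ and the model becomes linear; the
steady-state response then solves the complex stationary system
(i2πf + κ² − ∇²)Ψ = A·w(x) on the same Neumann discretization. The
package solves this directly (sparse Kronecker-sum Laplacian + sparse LU),
with no time stepping, and compares the modulus of the right-edge mean of
Ψ with the simulated amplitude. Under zero-mean normalization the
dynamics lives in the zero-mean subspace, which is invariant under the
operator, so the oracle equivalently demeans the forcing (w − w̄); with
normalization off it uses w as is. Because the only nonlinearity is
κ²(sinh ψ − ψ) and the sweeps use κ ≤ 0.005, agreement holds even where ψ
reaches order one; measured disagreement is ≤ 0.3% over three decades of
frequency, against a 2% tolerance. This is the strongest correctness check
in the repository: the two routes share only the spatial stencil.

## Dispersion (knee) detection

The dispersion frequency is defined operationally: the plateau level is
the mean modulus of the first `plateau_points` (default 3) lowest
frequencies; the knee is the lowest frequency whose modulus deviates from
the plateau by more than `rel_tolerance` (default 5%) of it, refined by
interpolating the deviation linearly in log10(f) between the bracketing
points. If the plateau points themselves vary beyond tolerance the
detector refuses (no-plateau error); if nothing departs within the span it
returns a clearly distinguished not-found sentinel. The same rule applies
to simulated and measured spectra. A mirrored high-frequency-plateau mode
exists but is off by default, matching β-dispersion phenomenology where
the departure is sought upward from the low-frequency plateau. Note the 5%
rule places the knee somewhat below the relaxation frequency 1/(2πτ) of a
single-relaxation spectrum (where the drop is already ~30%); the detector
is therefore validated to within a factor of 2 of 1/(2πτ), and its value
is in *comparing* knees across parameter settings, where the bias cancels.

## Synthetic data

Two generators stand in for measured data:

* `synth_debye_spectrum` produces single-relaxation impedance spectra
  Z(f) = R∞ + ΔR/(1 + i2πfτ) with optional seeded multiplicative Gaussian
  noise on the modulus, in the same tabular format a potentiostat FRA
  export would take. It emulates the shape and noise character of a real
  β-dispersion knee but none of the multi-dispersion structure, electrode
  polarization, or drift of real tissue spectra — passing tests on it
  shows the detector and I/O work, not that real cucumber spectra would
  yield a particular τβ. The test default R∞ = 400 Ω, ΔR = 100 Ω, places
  the 5%-departure knee within a factor 2 of 1/(2πτ).
* The simulator itself generates the "theoretical spectra": response
  amplitude against drive frequency for families of κ (amplitude falls
  with κ at every frequency) and of domain length (knee frequency falls
  like ~1/L², the diffusive time scaling; measured knee ratios are 4.00
  and 4.00 across the 25→50→100 doublings).

## Problem sizes used

Unit tests run on grids ≤ 10×6 with ≤ 6 frequencies. The end-to-end checks
use the reference 50×20 domain for the κ family (κ ∈ {0.001…0.005}, 8
frequencies spanning 1e−4…1e−2 cycles/unit), nx ∈ {25, 50, 100} at ny = 20
for the domain family (7 frequencies per curve, scaled by (50/nx)² so each
size resolves its own plateau), and a 25×10 grid over 3 decades for the
oracle comparison — with dt = 0.2 and 2-period transient/measure windows
(the settle floor dominating the transient). These are the package's
chosen desk-scale settings; the properties checked (monotonicity,
equivalence, conservation) do not depend on them.

## Known limitations

* Explicit Euler only; no implicit or higher-order integrators, so very
  fine grids force small dt.
* No mesoscopic internal structure (impermeable sub-domains, membranes,
  surface effects); the domain is a single homogeneous cell.
* The knee definition is a convention; absolute knee values shift with
  `rel_tolerance` and the sweep's frequency resolution, while trends
  across κ or L are robust.
* No equivalent-circuit fitting (Cole–Cole, CPE, Warburg) and no
  α-dispersion mechanism: the Debye generator is a fixture, not a model.
* Physical units enter only through the two reporting-time scale factors;
  no temperature-dependent transport laws are modelled.
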