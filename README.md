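# betadisp

Electrodiffusive simulation of cell polarization and the β-dispersion of
impedance spectra.

## The problem

Electric impedance spectroscopy (EIS) of biological tissue shows step-wise
"dispersions": frequency bands where the impedance modulus departs from a
plateau. The β dispersion, typically at kHz frequencies, is attributed to
cell-scale polarization — mobile ions redistributing across a cell in
response to the applied field, a process that takes a characteristic time
τβ and therefore cannot follow drives much faster than 1/τβ. Equivalent
circuits fit such spectra but do not explain them. `betadisp` is for
researchers who want a first-principles, mechanistic counterpart: a
minimal electrodiffusion model whose simulated frequency response
reproduces the β-dispersion phenomenology and whose parameters (screening
length, domain size) map onto measurable cell properties.

## The model

The dimensionless potential ψ(x, y, t) on a 2D rectangular domain evolves
as

    ∂ψ/∂t = ∇²ψ − κ² sinh ψ + w(x)·A sin(2πft)

with zero-flux (Neumann) boundaries and a zero-mean (constant-charge)
normalization each step. κ is an inverse Debye-length-like screening
parameter; w(x) is a logarithmically decaying forcing footprint peaking at
the left edge; the response is the steady-state oscillation amplitude of ψ
averaged over the right edge. Sweeping f yields a low-pass "spectrum":

* increasing κ lowers the amplitude at every frequency (stronger screening
  → higher impedance);
* increasing the domain length L moves the dispersion knee down in
  frequency like ~1/L² (diffusive polarization time ∝ L²).

Around the simulator sit the standard EIS utilities: logarithmic
measurement grids (10 points/decade from 100 mHz to 500 kHz gives the
classic 67-point sweep), Bode-diagram assembly, dispersion-knee detection,
a synthetic single-relaxation (Debye) spectrum generator for fixtures, and
the type-B uncertainty combination u = √(Δx²/3 + Δxe²/3).

Integration is explicit Euler (dt ≤ h²/4 enforced); a linearized
frequency-domain solve of the same discretization serves as an independent
correctness oracle, with time-domain/frequency-domain agreement better
than 0.3% at small forcing. See `docs/methods.md` for the full numerical
account.

## Worked example

Simulate a small frequency sweep from the shipped config
(`examples/quick.yaml`: 10×6 grid, κ = 0.01, A = 0.01, three frequencies):

```sh
$ betadisp simulate --config examples/quick.yaml --out quick_sweep.csv
$ cat quick_sweep.csv
frequency,amplitude
0.001,0.038038225912388028
0.002,0.037806134917875739
0.0040000000000000001,0.036917455924957411
```

The three numbers are steady-state right-edge response amplitudes
(dimensionless potential units) at drive frequencies of 0.001–0.004
cycles per time unit: essentially flat, because all three sit on the
low-frequency plateau of this small domain. A `.meta.yaml` sidecar records
the full configuration and seed; rerunning the config reproduces the file
byte for byte.

Generate a synthetic Debye spectrum with τ = 45 µs (relaxation frequency
1/2πτ ≈ 3.5 kHz) on the 67-point grid and locate its knee:

```sh
$ betadisp synth --tau 4.5e-5 --fmin 0.1 --fmax 500000 --out debye.csv
$ betadisp analyze debye.csv --bode-out bode.csv
debye: knee_frequency=2143.53 Hz plateau=500 tol=0.05
```

The detected knee — where the modulus first leaves the 500 Ω plateau by
more than 5% — sits at 2.1 kHz, below the 3.5 kHz relaxation frequency as
a 5%-departure criterion must, and within the factor-2 band the detector
is validated to. `bode.csv` holds the plot-ready long-format Bode table.

The κ and domain-size families behind the theoretical spectra are one
command each: `betadisp sweep-kappa` and `betadisp sweep-domain`.

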