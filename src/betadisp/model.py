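"""Electrodiffusive polarization model on a 2D rectangular grid.

The evolving quantity is a dimensionless electric potential field
``psi(x, y, t)`` obeying a non-stationary Poisson--Boltzmann-type
electrodiffusion equation

    d psi / dt = laplacian(psi) - kappa**2 * sinh(psi) + w(x) * s(t)

with zero-flux (Neumann) boundaries on all four sides. ``kappa`` is an
inverse screening length: its inverse plays the role of a Debye length, so
larger ``kappa`` means stronger ionic screening and weaker field
penetration. The forcing is separable: a fixed spatial weight ``w(x)`` that
peaks at the left edge and decays logarithmically along the domain (a
smoothed stand-in for an electrode contact), times a harmonic drive
``s(t) = A sin(2 pi f t)`` representing the applied external field.

Time integration is explicit Euler with the standard 5-point Laplacian;
ghost points outside the border take the value of the adjacent border cell
(first-order mirror), which realizes the zero-flux condition. An optional
charge normalization subtracts the domain mean of ``psi`` after every step,
pinning the (linearized) net charge density to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DimensionError, InvalidGridError, StabilityError

__all__ = [
    "GridSpec",
    "ModelParams",
    "FieldState",
    "ForcingSpec",
    "make_weight_profile",
    "forcing_value",
    "laplacian_neumann",
    "normalize_charge",
    "euler_step",
    "init_field",
    "stability_limit",
    "default_dt",
    "PSI_BLOWUP_GUARD",
    "INIT_NOISE_HALF_RANGE",
]

#: Above this |psi| the model is physically meaningless and sinh is on its
#: way to double-precision overflow; the stepper aborts rather than
#: propagating inf.
PSI_BLOWUP_GUARD = 30.0

#: Half-range of the uniform IID initial noise on psi.
INIT_NOISE_HALF_RANGE = 0.05


@dataclass(frozen=True)
class GridSpec:
    """Rectangular computational domain: ``nx`` by ``ny`` cells, spacing ``h``."""

    nx: int
    ny: int
    h: float = 1.0

    def __post_init__(self):
        if self.nx < 3 or self.ny < 3:
            raise InvalidGridError(
                f"grid must be at least 3x3, got {self.nx}x{self.ny}"
            )
        if not self.h > 0:
            raise InvalidGridError(f"grid spacing must be positive, got {self.h}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nx, self.ny)

    @property
    def length(self) -> float:
        """Horizontal extent ``nx * h`` in numerical length units."""
        return self.nx * self.h


def stability_limit(grid: GridSpec) -> float:
    """Largest stable explicit-Euler time step for 2D diffusion: ``h**2 / 4``."""
    return grid.h**2 / 4.0


def default_dt(grid: GridSpec) -> float:
    """Default time step: 20% of the stability limit."""
    return 0.2 * stability_limit(grid)


@dataclass(frozen=True)
class ModelParams:
    """Parameters fixed over one simulation run.

    kappa
        Inverse screening length (>= 0) in inverse numerical length units.
    amplitude
        Dimensionless forcing amplitude ``A``.
    dt
        Time step in numerical time units; must respect ``h**2 / 4``.
    normalization
        ``"zero-mean"`` subtracts the domain mean of psi after every step
        (constant-charge condition); ``"none"`` disables it.
    """

    kappa: float
    amplitude: float
    dt: float
    normalization: str = "zero-mean"

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.normalization not in ("zero-mean", "none"):
            raise ValueError(
                f"normalization must be 'zero-mean' or 'none', "
                f"got {self.normalization!r}"
            )

    def validate_for_grid(self, grid: GridSpec) -> None:
        limit = stability_limit(grid)
        if self.dt > limit * (1 + 1e-12):
            raise ValueError(
                f"dt={self.dt:g} exceeds the explicit-Euler stability bound "
                f"h^2/4={limit:g}"
            )


@dataclass
class FieldState:
    """The potential field ``psi`` of shape ``(nx, ny)`` at elapsed time ``t``."""

    psi: np.ndarray
    t: float = 0.0

    def __post_init__(self):
        self.psi = np.asarray(self.psi, dtype=float)
        if self.psi.ndim != 2:
            raise DimensionError(f"psi must be 2D, got ndim={self.psi.ndim}")


@dataclass(frozen=True)
class ForcingSpec:
    """Separable forcing ``w(x) * A sin(2 pi f t)``.

    ``weight`` is a 1D profile of length nx, broadcast along y; it must peak
    at the left edge with values in [0, 1]. ``frequency`` is in cycles per
    numerical time unit.
    """

    frequency: float
    amplitude: float
    weight: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "weight", np.asarray(self.weight, dtype=float))
        if self.frequency < 0:
            raise ValueError(f"frequency must be >= 0, got {self.frequency}")
        w = self.weight
        if w.ndim != 1:
            raise DimensionError("weight must be a 1D profile")
        if w.size and (w.min() < -1e-12 or w.max() > 1 + 1e-12):
            raise ValueError("weight entries must lie in [0, 1]")
        if w.size and w[0] < w.max() - 1e-12:
            raise ValueError("weight must attain its maximum at the left edge")


def make_weight_profile(grid: GridSpec) -> np.ndarray:
    """Spatial forcing weight: 1 at the left edge, logarithmic decay to 0.

    Concrete form ``w(i) = 1 - ln(1 + i) / ln(nx)`` for ``i = 0 .. nx-1``,
    clamped to [0, 1]: maximal at the left boundary, strictly decreasing,
    and exactly zero at the right boundary. This is the smoothed electrode
    footprint used in place of a Dirac delta at x = 0.
    """
    if grid.nx < 3:  # pragma: no cover - GridSpec already enforces this
        raise InvalidGridError(f"nx must be >= 3, got {grid.nx}")
    i = np.arange(grid.nx, dtype=float)
    w = 1.0 - np.log1p(i) / np.log(grid.nx)
    return np.clip(w, 0.0, 1.0)


def forcing_value(t: float, spec: ForcingSpec) -> float:
    """Harmonic drive ``s(t) = A sin(2 pi f t)`` at time ``t``."""
    return spec.amplitude * np.sin(2.0 * np.pi * spec.frequency * t)


def laplacian_neumann(state: FieldState | np.ndarray, grid: GridSpec) -> np.ndarray:
    """5-point Laplacian with zero-flux boundaries via first-order ghost mirror.

    Ghost points outside the border are set equal to the adjacent border
    value, so boundary differences vanish and the discrete Laplacian sums to
    zero over the domain (discrete divergence theorem).
    """
    psi = state.psi if isinstance(state, FieldState) else np.asarray(state, float)
    if psi.shape != grid.shape:
        raise DimensionError(
            f"field shape {psi.shape} does not match grid {grid.shape}"
        )
    p = np.pad(psi, 1, mode="edge")
    lap = (
        p[2:, 1:-1] + p[:-2, 1:-1] + p[1:-1, 2:] + p[1:-1, :-2] - 4.0 * psi
    ) / grid.h**2
    return lap


def normalize_charge(state: FieldState, mode: str = "zero-mean") -> FieldState:
    """Apply the constant-charge normalization.

    ``zero-mean`` subtracts the domain mean of psi from every cell, which
    pins the linearized net charge density (proportional to sinh psi ~ psi)
    to zero; ``none`` is the identity. Idempotent in both modes.
    """
    if mode == "none":
        return state
    if mode != "zero-mean":
        raise ValueError(f"unknown normalization mode {mode!r}")
    return replace(state, psi=state.psi - state.psi.mean())


def euler_step(
    state: FieldState,
    grid: GridSpec,
    params: ModelParams,
    forcing: ForcingSpec,
) -> FieldState:
    """Advance psi by one explicit-Euler step of the electrodiffusion equation.

    ``psi <- psi + dt * (lap(psi) - kappa^2 sinh(psi) + w(x) s(t))`` followed
    by the charge normalization if enabled; ``t <- t + dt``. Raises
    :class:`StabilityError` if the field leaves the trusted range
    (non-finite, or ``|psi| > 30``).
    """
    params.validate_for_grid(grid)
    if forcing.weight.shape[0] != grid.nx:
        raise DimensionError(
            f"weight length {forcing.weight.shape[0]} does not match nx={grid.nx}"
        )
    psi = state.psi
    if psi.shape != grid.shape:
        raise DimensionError(
            f"field shape {psi.shape} does not match grid {grid.shape}"
        )
    lap = laplacian_neumann(psi, grid)
    s = forcing_value(state.t, forcing)
    rhs = lap - params.kappa**2 * np.sinh(psi) + forcing.weight[:, None] * s
    new_psi = psi + params.dt * rhs
    max_abs = float(np.max(np.abs(new_psi))) if new_psi.size else 0.0
    if not np.isfinite(new_psi).all() or max_abs > PSI_BLOWUP_GUARD:
        raise StabilityError(params.dt, max_abs)
    out = FieldState(psi=new_psi, t=state.t + params.dt)
    if params.normalization == "zero-mean":
        out = normalize_charge(out, "zero-mean")
    return out


def init_field(
    grid: GridSpec, seed: int | np.random.SeedSequence | np.random.Generator
) -> FieldState:
    """IID uniform initial condition on [-0.05, +0.05], reproducible by seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    psi = rng.uniform(-INIT_NOISE_HALF_RANGE, INIT_NOISE_HALF_RANGE, size=grid.shape)
    return FieldState(psi=psi, t=0.0)
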