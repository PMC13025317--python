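"""EIS spectrum utilities: frequency grids, Bode data, dispersion knees.

This module works on measured-or-synthetic impedance spectra — triplets of
frequency (Hz), impedance modulus, and phase (degrees) — and on simulated
response curves alike. Its central operation is locating the dispersion
("knee" or departure-point) frequency: the frequency at which the modulus
first departs from its low-frequency plateau. The inverse of that frequency
is the characteristic full-polarization time of the system (tau_beta for
the cell-scale beta dispersion of tissue).

The knee rule is deliberately simple and is applied identically to
simulated and measured curves: estimate the plateau from the first few
low-frequency points, then find the lowest frequency whose modulus deviates
from the plateau by more than a relative tolerance (default 5%), refined by
log-linear interpolation between the bracketing points.

A single-relaxation (Debye) spectrum generator provides synthetic test
fixtures in potentiostat-export form; it is a fixture, not a model — no
equivalent-circuit fitting is done anywhere in this package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    LogDomainError,
    NoPlateauError,
    SpectrumFormatError,
)

__all__ = [
    "Spectrum",
    "DispersionEstimate",
    "log_frequency_grid",
    "detect_dispersion_frequency",
    "bode_assemble",
    "synth_debye_spectrum",
    "type_b_uncertainty",
    "read_spectrum",
    "write_spectrum",
]

#: Column names of the tabular spectrum text format.
SPECTRUM_COLUMNS = ("freq_Hz", "Zmod_ohm", "Zphase_deg")


@dataclass(frozen=True)
class Spectrum:
    """One impedance spectrum: frequency (Hz), modulus, phase (degrees).

    The modulus may be an impedance magnitude in ohms or a dimensionless
    response amplitude; the analysis operations only assume positivity.
    Phase follows the capacitive-negative convention in (-180, 180].
    """

    frequency: np.ndarray
    modulus: np.ndarray
    phase: np.ndarray
    label: str = ""

    def __post_init__(self):
        for name in ("frequency", "modulus", "phase"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float)
            )
        f, m, p = self.frequency, self.modulus, self.phase
        if not (f.shape == m.shape == p.shape) or f.ndim != 1:
            raise SpectrumFormatError("frequency/modulus/phase must be equal-length 1D")
        if f.size and (np.any(f <= 0) or np.any(np.diff(f) <= 0)):
            raise SpectrumFormatError(
                "frequencies must be positive and strictly increasing"
            )

    def __len__(self) -> int:
        return self.frequency.size


@dataclass(frozen=True)
class DispersionEstimate:
    """Detected dispersion knee: where the modulus leaves its plateau.

    ``knee_frequency`` is None when the spectrum never departs from the
    plateau within its span (the knee-not-found sentinel); ``found``
    distinguishes that case from a real estimate.
    """

    knee_frequency: float | None
    plateau_level: float
    rel_tolerance: float

    def __post_init__(self):
        if not 0 < self.rel_tolerance < 1:
            raise ValueError("rel_tolerance must lie in (0, 1)")

    @property
    def found(self) -> bool:
        return self.knee_frequency is not None


def log_frequency_grid(
    fmin: float, fmax: float, points_per_decade: int
) -> np.ndarray:
    """Logarithmic measurement grid: equal spacing within each decade.

    ``f_i = fmin * 10**(i / ppd)`` for ``i = 0 .. floor(ppd * log10(fmax/fmin))``.
    The first point is exactly fmin; the last does not exceed fmax. The
    standard potentiostat sweep from 100 mHz to 500 kHz at 10 points per
    decade yields 67 points.
    """
    if fmin <= 0:
        raise ValueError(f"fmin must be > 0, got {fmin}")
    if fmax < fmin:
        raise ValueError(f"fmax={fmax} must be >= fmin={fmin}")
    if points_per_decade < 1:
        raise ValueError("points_per_decade must be >= 1")
    n_max = math.floor(points_per_decade * math.log10(fmax / fmin) + 1e-9)
    i = np.arange(n_max + 1)
    f = fmin * 10.0 ** (i / points_per_decade)
    f[0] = fmin
    return f


def detect_dispersion_frequency(
    spectrum: Spectrum,
    rel_tolerance: float = 0.05,
    plateau_points: int = 3,
    side: str = "low",
) -> DispersionEstimate:
    """Locate the frequency where the modulus departs from its plateau.

    The plateau level is the mean modulus over the first ``plateau_points``
    points (lowest frequencies for ``side="low"``; a mirrored
    high-frequency-plateau mode ``side="high"`` is provided for completeness
    and off by default). The knee is the lowest frequency whose modulus
    deviates from the plateau by more than ``rel_tolerance * plateau``,
    refined by interpolating the deviation linearly in log10(f) between the
    bracketing points.

    Raises :class:`NoPlateauError` if the plateau points themselves already
    vary beyond tolerance; returns a not-found sentinel if the spectrum
    never departs within its span.
    """
    if side not in ("low", "high"):
        raise ValueError(f"side must be 'low' or 'high', got {side!r}")
    if len(spectrum) < 5:
        raise SpectrumFormatError("need at least 5 points to detect a knee")
    if plateau_points < 2 or plateau_points >= len(spectrum):
        raise ValueError("plateau_points must be in [2, len(spectrum))")

    freq = spectrum.frequency
    mod = spectrum.modulus
    if side == "high":
        freq = freq[::-1]
        mod = mod[::-1]

    k = plateau_points
    plateau = float(mod[:k].mean())
    if plateau <= 0:
        raise LogDomainError("plateau level must be positive")
    dev = np.abs(mod - plateau) / plateau
    if np.any(dev[:k] > rel_tolerance):
        raise NoPlateauError(
            f"first {k} points vary beyond rel_tolerance={rel_tolerance:g}: "
            f"no plateau to depart from"
        )
    beyond = np.nonzero(dev > rel_tolerance)[0]
    if beyond.size == 0:
        return DispersionEstimate(None, plateau, rel_tolerance)
    j = int(beyond[0])
    # log-linear interpolation of the deviation between points j-1 and j
    d0, d1 = dev[j - 1], dev[j]
    lf0, lf1 = math.log10(freq[j - 1]), math.log10(freq[j])
    frac = (rel_tolerance - d0) / (d1 - d0)
    knee = 10.0 ** (lf0 + frac * (lf1 - lf0))
    return DispersionEstimate(float(knee), plateau, rel_tolerance)


def bode_assemble(spectra: list[Spectrum]) -> pd.DataFrame:
    """Long-format Bode diagram table for a set of spectra.

    Columns ``curve_label, log10_f, log10_Zmod, phase_deg`` — the two Bode
    panels (log modulus and phase against log frequency) in one plot-ready
    table, curve order preserved. Phase is kept linear: phases near zero
    make a logarithmic phase axis ill-defined.
    """
    if len(spectra) == 0:
        raise EmptyInputError("no spectra to assemble")
    frames = []
    for idx, s in enumerate(spectra):
        bad = np.nonzero(s.modulus <= 0)[0]
        if bad.size:
            raise LogDomainError(
                f"spectrum {s.label!r}: non-positive modulus at point {bad[0]} "
                f"(f={s.frequency[bad[0]]:g} Hz)"
            )
        frames.append(
            pd.DataFrame(
                {
                    "curve_label": s.label or f"curve{idx}",
                    "log10_f": np.log10(s.frequency),
                    "log10_Zmod": np.log10(s.modulus),
                    "phase_deg": s.phase,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def synth_debye_spectrum(
    r_inf: float,
    delta_r: float,
    tau: float,
    frequencies: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
    label: str = "synthetic-debye",
) -> Spectrum:
    """Single-relaxation synthetic impedance spectrum (test fixture).

    ``Z(f) = r_inf + delta_r / (1 + i 2 pi f tau)`` — the Debye form with
    high-frequency resistance ``r_inf``, relaxation strength ``delta_r`` and
    time constant ``tau``. Multiplicative Gaussian noise of relative
    standard deviation ``noise_sd`` is applied to the modulus (seeded).
    The characteristic frequency is ``1 / (2 pi tau)``.
    """
    if r_inf <= 0:
        raise ValueError("r_inf must be > 0")
    if delta_r < 0:
        raise ValueError("delta_r must be >= 0")
    if tau <= 0:
        raise ValueError("tau must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    f = np.asarray(frequencies, dtype=float)
    z = r_inf + delta_r / (1.0 + 2j * np.pi * f * tau)
    modulus = np.abs(z)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        modulus = modulus * (1.0 + noise_sd * rng.standard_normal(f.shape))
    phase = np.degrees(np.angle(z))
    return Spectrum(frequency=f, modulus=modulus, phase=phase, label=label)


def type_b_uncertainty(delta_cal: float, delta_exp: float) -> float:
    """Type-B combined uncertainty of two uniform-distribution error bounds.

    ``u = sqrt(delta_cal**2 / 3 + delta_exp**2 / 3)`` — each bound is
    treated as the half-width of a uniform distribution (variance
    ``delta**2 / 3``) and the two are combined in quadrature. For a 1 degC
    thermometer graduation and a 0.5 degC reading uncertainty this gives
    0.65 degC (reported at two decimals).
    """
    if delta_cal < 0 or delta_exp < 0:
        raise ValueError("uncertainty components must be non-negative")
    return math.sqrt(delta_cal**2 / 3.0 + delta_exp**2 / 3.0)


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write a spectrum as comma-separated text: freq_Hz, Zmod_ohm, Zphase_deg."""
    df = pd.DataFrame(
        {
            "freq_Hz": spectrum.frequency,
            "Zmod_ohm": spectrum.modulus,
            "Zphase_deg": spectrum.phase,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_spectrum(
    path: str | Path, label: str | None = None, decimal_comma: bool = False
) -> Spectrum:
    """Read a tabular spectrum file.

    ``decimal_comma=True`` switches to the semicolon-separated,
    decimal-comma dialect some potentiostat FRA exports use.
    """
    path = Path(path)
    kwargs: dict = {"float_precision": "round_trip"}
    if decimal_comma:
        kwargs.update(sep=";", decimal=",")
    try:
        df = pd.read_csv(path, **kwargs)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise SpectrumFormatError(f"{path}: cannot parse spectrum table: {exc}")
    missing = [c for c in SPECTRUM_COLUMNS if c not in df.columns]
    if missing:
        raise SpectrumFormatError(f"{path}: missing columns {missing}")
    if df[list(SPECTRUM_COLUMNS)].isna().any().any():
        idx = int(df[list(SPECTRUM_COLUMNS)].isna().any(axis=1).idxmax())
        raise SpectrumFormatError(f"{path}: non-numeric or NaN entry at row {idx}")
    return Spectrum(
        frequency=df["freq_Hz"].to_numpy(),
        modulus=df["Zmod_ohm"].to_numpy(),
        phase=df["Zphase_deg"].to_numpy(),
        label=label if label is not None else path.stem,
    )
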