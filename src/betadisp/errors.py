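"""Exception hierarchy.

Every error raised on a user-facing path derives from :class:`BetadispError`
so the command-line layer can map any failure to a one-line message and a
nonzero exit status.
"""


class BetadispError(Exception):
    """Base class for all errors raised by betadisp."""


class InvalidGridError(BetadispError, ValueError):
    """Grid specification violates its constraints (nx/ny too small, h <= 0)."""


class DimensionError(BetadispError, ValueError):
    """A field's shape does not match the grid it is used with."""


class StabilityError(BetadispError, RuntimeError):
    """The explicit time integration blew up (non-finite or runaway field).

    Carries the time step and the largest ``|psi|`` reached so the cause
    (too-large dt versus genuinely stiff parameters) can be diagnosed.
    """

    def __init__(self, dt: float, max_abs_psi: float):
        self.dt = dt
        self.max_abs_psi = max_abs_psi
        super().__init__(
            f"time integration unstable: dt={dt:g}, max|psi|={max_abs_psi:g} "
            f"(reduce dt or the forcing amplitude)"
        )


class EmptyInputError(BetadispError, ValueError):
    """An operation received an empty sequence where data was required."""


class InsufficientWindowError(BetadispError, ValueError):
    """The analysed time window covers fewer than two drive periods."""


class SamplingError(BetadispError, ValueError):
    """The drive frequency is too high for the sampling interval (f*dt >= 0.5)."""


class NoPlateauError(BetadispError, ValueError):
    """A spectrum has no low-frequency plateau, so no knee can be defined."""


class LogDomainError(BetadispError, ValueError):
    """A non-positive modulus cannot be placed on a logarithmic axis."""


class ConfigError(BetadispError, ValueError):
    """A run configuration is missing, unparseable, or violates a constraint."""


class FormatVersionError(BetadispError, ValueError):
    """A serialized file was written by an incompatible format version."""


class SpectrumFormatError(BetadispError, ValueError):
    """A spectrum or sweep file violates the tabular format contract."""
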