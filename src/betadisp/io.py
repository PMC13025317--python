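"""Serialization of sweep results.

A sweep is stored as two plain-text files: a comma-separated table of
(frequency, amplitude) pairs, and a YAML sidecar ``<path>.meta.yaml``
holding the full run configuration, seed, protocol and a format version —
enough to regenerate the run bit-identically. Floats are written at full
round-trip precision (%.17g), so read(write(x)) reproduces x exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import FormatVersionError, SpectrumFormatError
from .model import GridSpec, ModelParams
from .sweep import ResponsePoint, SweepProtocol, SweepResult

__all__ = ["write_sweep", "read_sweep", "sidecar_path", "FORMAT_VERSION"]

FORMAT_VERSION = 1


def sidecar_path(path: str | Path) -> Path:
    return Path(str(path) + ".meta.yaml")


def write_sweep(result: SweepResult, path: str | Path, extra_meta: dict | None = None) -> None:
    """Write the (frequency, amplitude) table plus its metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        {"frequency": result.frequencies, "amplitude": result.amplitudes}
    )
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "format_version": FORMAT_VERSION,
        "grid": {"nx": result.grid.nx, "ny": result.grid.ny, "h": result.grid.h},
        "model": {
            "kappa": result.params.kappa,
            "amplitude": result.params.amplitude,
            "dt": result.params.dt,
            "normalization": result.params.normalization,
        },
        "protocol": {
            "transient_periods": result.protocol.transient_periods,
            "measure_periods": result.protocol.measure_periods,
            "settle_multiple": result.protocol.settle_multiple,
            "seed": result.protocol.seed,
        },
    }
    if extra_meta:
        meta.update(extra_meta)
    sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))


def read_sweep(path: str | Path) -> SweepResult:
    """Read a sweep table and its sidecar back into a SweepResult.

    Rejects NaN amplitudes (naming the offending point) and sidecars
    written by an incompatible format version.
    """
    path = Path(path)
    side = sidecar_path(path)
    if not side.exists():
        raise SpectrumFormatError(f"missing metadata sidecar: {side}")
    meta = yaml.safe_load(side.read_text())
    version = meta.get("format_version")
    if version != FORMAT_VERSION:
        raise FormatVersionError(
            f"{side}: format_version {version} is incompatible "
            f"(expected {FORMAT_VERSION})"
        )
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("frequency", "amplitude"):
        if col not in df.columns:
            raise SpectrumFormatError(f"{path}: missing column {col!r}")
    bad = np.nonzero(~np.isfinite(df["amplitude"].to_numpy()))[0]
    if bad.size:
        raise SpectrumFormatError(
            f"{path}: non-finite amplitude at point {bad[0]}"
        )
    grid = GridSpec(**meta["grid"])
    params = ModelParams(**meta["model"])
    protocol = SweepProtocol(**meta["protocol"])
    points = tuple(
        ResponsePoint(frequency=f, amplitude=a)
        for f, a in zip(df["frequency"], df["amplitude"])
    )
    return SweepResult(points=points, params=params, grid=grid, protocol=protocol)
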