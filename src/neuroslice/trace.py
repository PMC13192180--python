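"""Uniformly sampled voltage traces and their on-disk formats.

A :class:`Trace` is the common currency of the electrophysiology modules:
a finite, uniformly sampled voltage signal in millivolts with an explicit
sampling rate (Hz) and time origin (s).  Two plain-text-friendly formats
are supported: two-column delimited text (time_s, voltage_mV) and a raw
float32 binary with a small JSON sidecar carrying the sampling metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Trace", "read_trace", "write_trace"]


@dataclass(frozen=True)
class Trace:
    """A uniformly sampled voltage signal.

    Parameters
    ----------
    samples : ndarray
        Voltage in mV; finite values only.
    fs : float
        Sampling rate in Hz, > 0.
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 2:
            raise ValueError("trace must be a 1-D array with at least 2 samples")
        if not np.all(np.isfinite(samples)):
            raise ValueError("trace contains NaN or Inf")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace duration in seconds (n samples at fs)."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    def scaled(self, factor: float) -> "Trace":
        """Return a copy with voltage multiplied by ``factor``."""
        return Trace(self.samples * factor, self.fs, self.t0)


def write_trace(trace: Trace, path: str | Path, fmt: str = "text") -> None:
    """Write a trace to disk.

    ``fmt='text'`` writes two-column delimited text (time_s, voltage_mV);
    ``fmt='binary'`` writes raw little-endian float32 samples to ``path``
    and a JSON sidecar ``<path>.json`` with fs, t0 and units.
    """
    path = Path(path)
    if fmt == "text":
        np.savetxt(
            path,
            np.column_stack([trace.times, trace.samples]),
            fmt="%.9g",
            delimiter="\t",
            header="time_s\tvoltage_mV",
        )
    elif fmt == "binary":
        trace.samples.astype("<f4").tofile(path)
        sidecar = {"fs_hz": trace.fs, "t0_s": trace.t0, "units": "mV", "dtype": "<f4"}
        Path(str(path) + ".json").write_text(json.dumps(sidecar))
    else:
        raise ValueError(f"unknown trace format: {fmt!r}")


def read_trace(path: str | Path) -> Trace:
    """Read a trace written by :func:`write_trace`.

    The format is inferred: if ``<path>.json`` exists the file is read as
    float32 binary, otherwise as two-column delimited text.
    """
    path = Path(path)
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        samples = np.fromfile(path, dtype=meta.get("dtype", "<f4")).astype(float)
        return Trace(samples, fs=float(meta["fs_hz"]), t0=float(meta.get("t0_s", 0.0)))
    data = np.loadtxt(path, delimiter="\t", comments="#")
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (time_s, voltage_mV)")
    t, v = data[:, 0], data[:, 1]
    dt = np.diff(t)
    if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError(f"{path}: time column is not uniformly sampled")
    return Trace(v, fs=1.0 / dt[0], t0=float(t[0]))
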