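"""Shared containers for assay time series.

A :class:`Trace` is the package's unit of raw data for every plate-reader and
stopped-flow style assay: a sampled (time, signal) series plus a metadata
dictionary carrying assay conditions (nucleotide concentrations, temperature,
chase time, ...). Metadata keys are free-form strings; analysis modules
document the keys they consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class Trace:
    """A uniformly or explicitly sampled (time, signal) series.

    Parameters
    ----------
    time : ndarray
        Sample times in seconds, strictly increasing.
    signal : ndarray
        Signal values (absorbance, fluorescence, nm, ...), same length as
        ``time``.
    meta : dict
        Assay-specific metadata (units, concentrations, temperature).
    """

    time: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal must have the same shape")
        if self.time.ndim != 1:
            raise ValueError("Trace requires 1-D arrays")
        if len(self.time) >= 2 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def dt(self) -> float:
        """Median sampling interval in seconds."""
        return float(np.median(np.diff(self.time)))

    def to_csv(self, path: str | Path) -> None:
        """Write as two-column CSV with ``# key: value`` metadata header."""
        path = Path(path)
        with path.open("w") as fh:
            for key, value in self.meta.items():
                fh.write(f"# {key}: {value}\n")
            fh.write("time,signal\n")
            for t, y in zip(self.time, self.signal):
                fh.write(f"{t:.10g},{y:.10g}\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trace":
        """Read a trace written by :meth:`to_csv`."""
        path = Path(path)
        meta: dict = {}
        rows: list[tuple[float, float]] = []
        with path.open() as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, value = line[1:].partition(":")
                    meta[key.strip()] = _coerce(value.strip())
                elif line.lower().startswith("time"):
                    continue
                else:
                    a, b = line.split(",")
                    rows.append((float(a), float(b)))
        arr = np.asarray(rows, dtype=float)
        return cls(time=arr[:, 0], signal=arr[:, 1], meta=meta)


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    return value
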