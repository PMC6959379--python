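"""Shared spectrum container and two-column plain-text I/O.

A :class:`Spectrum` is the common currency between the NEXAFS stage
(photon energy in eV) and the FTIR stage (wavenumber in cm^-1): an
ordered axis, one intensity per axis point, and free-form metadata
(sample id, soil horizon, treatment, edge, ...).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

AXIS_ENERGY_EV = "energy_eV"
AXIS_WAVENUMBER_CM1 = "wavenumber_cm1"
_AXIS_KINDS = (AXIS_ENERGY_EV, AXIS_WAVENUMBER_CM1)

#: Minimum number of grid points for a spectrum to be meaningful.
MIN_POINTS = 16


@dataclass
class Spectrum:
    """An ordered axis/intensity pair with an axis kind and metadata.

    Parameters
    ----------
    axis :
        Strictly increasing positions (eV or cm^-1), length >= 16.
    intensity :
        One finite intensity value per axis point.
    axis_kind :
        ``"energy_eV"`` or ``"wavenumber_cm1"``.
    meta :
        Free-form labels (sample id, edge, horizon, treatment, flags).
    """

    axis: np.ndarray
    intensity: np.ndarray
    axis_kind: str = AXIS_ENERGY_EV
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("axis and intensity must be one-dimensional")
        if self.axis.shape != self.intensity.shape:
            raise ValueError(
                f"axis ({self.axis.size}) and intensity ({self.intensity.size}) "
                "must have equal length"
            )
        if self.axis.size < MIN_POINTS:
            raise ValueError(f"spectrum needs at least {MIN_POINTS} points")
        if not np.all(np.isfinite(self.axis)) or not np.all(np.isfinite(self.intensity)):
            raise ValueError("non-finite values in spectrum")
        if not np.all(np.diff(self.axis) > 0):
            raise ValueError("axis must be strictly increasing")
        if self.axis_kind not in _AXIS_KINDS:
            raise ValueError(f"unknown axis_kind {self.axis_kind!r}")

    # -- convenience -------------------------------------------------

    def with_intensity(self, intensity: np.ndarray, **meta_updates) -> "Spectrum":
        """Return a copy with a new intensity array (axis shared)."""
        meta = dict(self.meta)
        meta.update(meta_updates)
        return Spectrum(self.axis.copy(), np.asarray(intensity, float),
                        self.axis_kind, meta)

    def window(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of axis points inside [lo, hi]."""
        return (self.axis >= lo) & (self.axis <= hi)

    @property
    def n_points(self) -> int:
        return int(self.axis.size)


def read_spectrum(path: str | Path, axis_kind: str = AXIS_ENERGY_EV,
                  **meta) -> Spectrum:
    """Read a two-column delimited text spectrum.

    Lines beginning with ``#`` are comments; the delimiter may be
    whitespace, comma or tab.
    """
    text = Path(path).read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise ValueError(f"{path}: expected two columns, got {line!r}")
        rows.append((float(parts[0]), float(parts[1])))
    if not rows:
        raise ValueError(f"{path}: no data rows")
    arr = np.asarray(rows, dtype=float)
    order = np.argsort(arr[:, 0])
    meta.setdefault("source", str(path))
    return Spectrum(arr[order, 0], arr[order, 1], axis_kind, meta)


def write_spectrum(s: Spectrum, path: str | Path) -> None:
    """Write a spectrum as two-column text with a small comment header."""
    buf = io.StringIO()
    buf.write(f"# axis_kind: {s.axis_kind}\n")
    for key in ("sample_id", "edge", "horizon", "treatment"):
        if key in s.meta:
            buf.write(f"# {key}: {s.meta[key]}\n")
    for x, y in zip(s.axis, s.intensity):
        buf.write(f"{x:.6g}\t{y:.10g}\n")
    Path(path).write_text(buf.getvalue())
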