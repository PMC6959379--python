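"""FTIR fingerprinting: area normalization, band integrals and PCA.

Diffuse-reflectance infrared spectra of dissolved organic matter are
compared through six diagnostic vibrational regions (carbohydrate C-O,
phenolic C-O, nitrate/ammonium N-O/N-H, aliphatic O-H/C-H, aromatic C-C
and carbonyl C=O).  Spectra are normalized to unit total area before any
comparison, band areas are trapezoidal integrals over each region, and
sample fingerprints (band tables, whole spectra, or NEXAFS pi*
abundance tables) are ordinated with a covariance PCA (centering only,
no variance scaling).

Two of the literature regions overlap (1380-1400 sits inside
1350-1450 cm^-1); band areas are integrated independently and must not
be summed across bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .spectrum import Spectrum


@dataclass(frozen=True)
class BandDefinition:
    """A named wavenumber interval [lo, hi] in cm^-1."""

    label: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.label!r}: lo must be < hi")


#: The six diagnostic regions.  The aromatic band is a point assignment
#: (1510 cm^-1) realized as a 20 cm^-1 interval around it.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("carbohydrates (C-O/C-O-C)", 970.0, 1150.0),
    BandDefinition("phenolics (C-O)", 1150.0, 1250.0),
    BandDefinition("nitrate/ammonium (N-O/N-H)", 1380.0, 1400.0),
    BandDefinition("aliphatics (O-H/C-H)", 1350.0, 1450.0),
    BandDefinition("aromatics (C-C)", 1500.0, 1520.0),
    BandDefinition("carbonyl (C=O)", 1620.0, 1800.0),
)

FTIR_RANGE = (900.0, 1850.0)


def _interval_integral(s: Spectrum, lo: float, hi: float) -> float:
    """Trapezoidal integral over [lo, hi] with interpolated endpoints."""
    if lo < s.axis[0] or hi > s.axis[-1]:
        raise ValueError(
            f"interval [{lo}, {hi}] outside spectrum axis "
            f"[{s.axis[0]}, {s.axis[-1]}]"
        )
    inner = s.axis[(s.axis > lo) & (s.axis < hi)]
    xs = np.concatenate(([lo], inner, [hi]))
    ys = np.interp(xs, s.axis, s.intensity)
    return float(np.trapezoid(ys, xs))


def area_normalize(s: Spectrum,
                   range: tuple[float, float] | None = None) -> Spectrum:
    """Scale a spectrum so its trapezoidal integral over ``range`` is 1.

    ``range`` defaults to the full axis.  Idempotent and invariant under
    positive rescaling of the input.
    """
    lo, hi = range if range is not None else (s.axis[0], s.axis[-1])
    total = _interval_integral(s, lo, hi)
    if total <= 0:
        raise ValueError(f"total area {total:.3g} over [{lo}, {hi}] is not positive")
    return s.with_intensity(s.intensity / total, area_normalized=(lo, hi))


def band_table(s: Spectrum,
               bands: tuple[BandDefinition, ...] = DEFAULT_BANDS) -> dict[str, float]:
    """Trapezoidal integral of an (area-normalized) spectrum per band.

    Overlapping bands are integrated independently; the values are not a
    partition of the total area and must not be summed.
    """
    table: dict[str, float] = {}
    for band in bands:
        try:
            table[band.label] = _interval_integral(s, band.lo, band.hi)
        except ValueError as err:
            raise ValueError(f"band {band.label!r}: {err}") from None
    return table


@dataclass
class PcaResult:
    """Covariance PCA of a sample x variable matrix.

    ``scores @ loadings.T + center`` reconstructs the input;
    ``degenerate`` flags a constant input matrix (zero total variance).
    """

    scores: np.ndarray                 # samples x components
    loadings: np.ndarray               # variables x components
    explained_variance_pct: np.ndarray
    center: np.ndarray                 # variable means
    degenerate: bool = False
    meta: dict = field(default_factory=dict)


def pca_fingerprint(X, n_components: int | None = None) -> PcaResult:
    """Column-centered (covariance) PCA with a deterministic sign convention.

    No variance scaling is applied — spectra are expected to be
    area-normalized already.  For each component the loading of largest
    magnitude is made positive so scores are reproducible across runs
    and sample orderings (up to overall sign).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs a 2-D matrix with >= 2 samples and >= 2 variables")
    if not np.all(np.isfinite(X)):
        raise ValueError("PCA input contains missing or non-finite values")
    n, p = X.shape
    center = X.mean(axis=0)
    k_max = min(n - 1, p)
    k = k_max if n_components is None else min(n_components, k_max)

    if np.allclose(X - center, 0.0):
        return PcaResult(
            scores=np.zeros((n, k)), loadings=np.zeros((p, k)),
            explained_variance_pct=np.zeros(k), center=center, degenerate=True,
        )

    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # variables x components
    # Deterministic signs: largest-magnitude loading positive per component.
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    return PcaResult(
        scores=scores,
        loadings=loadings,
        explained_variance_pct=pca.explained_variance_ratio_ * 100.0,
        center=center,
    )
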