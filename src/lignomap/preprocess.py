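"""Trimming, resampling, and range selection.

Master (macro) and slave (micro) instruments must live on one shared axis
before calibration transfer.  The shared axis is the *common grid*: 2800
evenly spaced points from 675 to 4000 cm^-1 inclusive, matching the micro
instrument's acquisition range.  Within that axis, modelling uses the
*effective range* 881-3581 cm^-1, which excludes the noisy edges of the
spectrum.

Resampling uses a natural cubic spline and never extrapolates: FTIR noise
dominates at the range edges, so values outside the source span are refused
rather than invented.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

from .spectra_io import (
    GridMismatchError,
    Hypercube,
    SpectraIOError,
    SpectralDataset,
    Spectrum,
    WavenumberGrid,
)

#: Shared master/slave transfer axis: [lo, hi] cm^-1 and point count.
COMMON_LO = 675.0
COMMON_HI = 4000.0
COMMON_N = 2800

#: Modelling range after discarding the noisy spectral edges, cm^-1.
EFFECTIVE_RANGE = (881.0, 3581.0)


class EmptyRangeError(SpectraIOError):
    """A trim interval contains no grid points."""


class ExtrapolationError(SpectraIOError):
    """A resampling target extends beyond the source grid span."""


def common_grid() -> WavenumberGrid:
    """The 2800-point evenly spaced grid on 675-4000 cm^-1 (inclusive)."""
    return WavenumberGrid(np.linspace(COMMON_LO, COMMON_HI, COMMON_N))


def trim(s: Spectrum, lo: float, hi: float) -> Spectrum:
    """Retain exactly the grid points with lo <= wavenumber <= hi (closed)."""
    if lo >= hi:
        raise SpectraIOError("trim needs lo < hi")
    mask = (s.grid.values >= lo) & (s.grid.values <= hi)
    if mask.sum() < 2:  # a usable spectrum needs at least two points
        raise EmptyRangeError(f"fewer than two grid points in [{lo}, {hi}]")
    return Spectrum(WavenumberGrid(s.grid.values[mask]), s.intensity[mask], mode=s.mode)


def trim_dataset(ds: SpectralDataset, lo: float, hi: float) -> SpectralDataset:
    """Dataset analogue of :func:`trim`; X columns dropped consistently."""
    if lo >= hi:
        raise SpectraIOError("trim needs lo < hi")
    mask = (ds.grid.values >= lo) & (ds.grid.values <= hi)
    if mask.sum() < 2:
        raise EmptyRangeError(f"fewer than two grid points in [{lo}, {hi}]")
    return ds.subset_bands(np.flatnonzero(mask))


def effective_range(ds: SpectralDataset) -> SpectralDataset:
    """Restrict a dataset to the 881-3581 cm^-1 effective modelling range."""
    return trim_dataset(ds, *EFFECTIVE_RANGE)


def effective_indices(grid: WavenumberGrid) -> np.ndarray:
    """Indices of ``grid`` falling inside the effective range (closed)."""
    lo, hi = EFFECTIVE_RANGE
    return np.flatnonzero((grid.values >= lo) & (grid.values <= hi))


def resample(s: Spectrum, target: WavenumberGrid) -> Spectrum:
    """Natural cubic spline through the source points, evaluated on ``target``.

    Raises :class:`ExtrapolationError` if the target extends beyond the
    source span.
    """
    src_lo, src_hi = s.grid.span
    tgt_lo, tgt_hi = target.span
    if tgt_lo < src_lo - 1e-9 or tgt_hi > src_hi + 1e-9:
        raise ExtrapolationError(
            f"target [{tgt_lo}, {tgt_hi}] outside source span [{src_lo}, {src_hi}]"
        )
    spline = CubicSpline(s.grid.values, s.intensity, bc_type="natural")
    return Spectrum(target, spline(target.values), mode=s.mode)


def resample_matrix(X: np.ndarray, source: WavenumberGrid,
                    target: WavenumberGrid) -> np.ndarray:
    """Row-wise :func:`resample` for an n x p intensity matrix."""
    src_lo, src_hi = source.span
    tgt_lo, tgt_hi = target.span
    if tgt_lo < src_lo - 1e-9 or tgt_hi > src_hi + 1e-9:
        raise ExtrapolationError("target outside source span")
    spline = CubicSpline(source.values, np.asarray(X, dtype=float),
                         bc_type="natural", axis=1)
    return spline(target.values)


def resample_hypercube(cube: Hypercube, target: WavenumberGrid) -> Hypercube:
    r, c, p = cube.data.shape
    flat = resample_matrix(cube.data.reshape(r * c, p), cube.grid, target)
    return Hypercube(flat.reshape(r, c, len(target)), target,
                     pixel_size=cube.pixel_size, mode=cube.mode)


def mean_std_profile(spectra: list[Spectrum]) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and population STD over spectra sharing one grid."""
    if not spectra:
        raise SpectraIOError("need at least one spectrum")
    grid = spectra[0].grid
    for s in spectra[1:]:
        if s.grid != grid:
            raise GridMismatchError("spectra are not on one shared grid")
    block = np.stack([s.intensity for s in spectra])
    return block.mean(axis=0), block.std(axis=0)
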