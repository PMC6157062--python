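"""Direct standardization (DS) between the macro (master) and micro (slave)
FTIR instruments.

DS solves ``X_master = X_slave @ E + B`` on a small set of representative
standard pairs measured on both instruments.  Here the standards are site
means: on the master side the mean macro spectrum of each growth site's
samples, on the slave side the mean over all pixels of that site's tissue
hypercube.  Both sides are mean-centred, E is the minimal-norm least-squares
solution via a truncated-SVD pseudoinverse, and B absorbs the means
(``B = mean_master - mean_slave @ E``).

With only three representative pairs the centred system has rank at most
two, so E is a heavily rank-deficient projection: spectral variation outside
the span of the site differences cannot survive the transfer.  The
minimal-norm solution is the canonical resolution -- it reproduces the
standards exactly and maps everything orthogonal to them to the master mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import resample_hypercube
from .spectra_io import (
    GridMismatchError,
    Hypercube,
    SpectraIOError,
    SpectralDataset,
    Spectrum,
    WavenumberGrid,
)


@dataclass
class RepresentativeSet:
    """Paired master/slave standard spectra, one row per group (site)."""

    master_reps: np.ndarray
    slave_reps: np.ndarray
    labels: list[str]
    grid: WavenumberGrid

    def __post_init__(self) -> None:
        self.master_reps = np.atleast_2d(np.asarray(self.master_reps, dtype=float))
        self.slave_reps = np.atleast_2d(np.asarray(self.slave_reps, dtype=float))
        if self.master_reps.shape != self.slave_reps.shape:
            raise SpectraIOError("master/slave representative shapes differ")
        if self.master_reps.shape[0] != len(self.labels):
            raise SpectraIOError("label count != representative count")
        if self.master_reps.shape[1] != len(self.grid):
            raise GridMismatchError("representative width != grid length")


@dataclass
class TransferModel:
    """Fitted DS map: x_corrected = x_slave @ E + B."""

    E: np.ndarray
    B: np.ndarray
    grid: WavenumberGrid
    n_reps: int
    svd_tol: float


class MissingGroupError(SpectraIOError):
    pass


def make_representatives(master_ds: SpectralDataset,
                         slave_cubes: dict[str, Hypercube],
                         group_by: str = "site") -> RepresentativeSet:
    """Site-mean standards: master = group mean spectrum, slave = cube pixel mean.

    Slave cubes not already on the master grid are spline-resampled onto it.
    """
    labels = sorted(slave_cubes)
    master_reps = []
    slave_reps = []
    for lab in labels:
        rows = [i for i, m in enumerate(master_ds.meta)
                if getattr(m, group_by) == lab]
        if not rows:
            raise MissingGroupError(f"no master samples with {group_by}={lab!r}")
        master_reps.append(master_ds.X[rows].mean(axis=0))
        cube = slave_cubes[lab]
        if cube.grid != master_ds.grid:
            cube = resample_hypercube(cube, master_ds.grid)
        slave_reps.append(cube.pixel_matrix().mean(axis=0))
    return RepresentativeSet(np.array(master_reps), np.array(slave_reps),
                             labels, master_ds.grid)


def ds_fit(reps: RepresentativeSet, svd_tol: float = 1e-8) -> TransferModel:
    """Fit the DS transfer matrix on representative pairs.

    Singular values below ``svd_tol`` times the largest are dropped, so the
    solution interpolates the standards without amplifying numerical noise.
    """
    Xm = reps.master_reps
    Xs = reps.slave_reps
    if not (np.isfinite(Xm).all() and np.isfinite(Xs).all()):
        raise ValueError("non-finite values in representative spectra")
    mm = Xm.mean(axis=0)
    ms = Xs.mean(axis=0)
    Xs_c = Xs - ms
    Xm_c = Xm - mm
    # minimal-norm solution of Xs_c @ E = Xm_c via economy SVD
    U, s, Vt = np.linalg.svd(Xs_c, full_matrices=False)
    if s.size and s[0] > 0:
        keep = s > svd_tol * s[0]
    else:
        keep = np.zeros_like(s, dtype=bool)
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    E = Vt.T @ ((U.T @ Xm_c) / s[:, None]) if s.size else np.zeros(
        (Xs.shape[1], Xs.shape[1]))
    B = mm - ms @ E
    return TransferModel(E=E, B=B, grid=reps.grid, n_reps=Xm.shape[0],
                         svd_tol=svd_tol)


def ds_apply(x: Spectrum | Hypercube | np.ndarray, tm: TransferModel):
    """Apply ``x @ E + B``; hypercubes are mapped pixelwise, shape preserved."""
    if isinstance(x, Spectrum):
        if x.grid != tm.grid:
            raise GridMismatchError("spectrum grid != transfer grid")
        return Spectrum(x.grid, x.intensity @ tm.E + tm.B, mode=x.mode)
    if isinstance(x, Hypercube):
        if x.grid != tm.grid:
            raise GridMismatchError("hypercube grid != transfer grid")
        r, c, p = x.data.shape
        flat = x.pixel_matrix() @ tm.E + tm.B
        return Hypercube(flat.reshape(r, c, p), x.grid,
                         pixel_size=x.pixel_size, mode=x.mode)
    X = np.atleast_2d(np.asarray(x, dtype=float))
    if X.shape[1] != len(tm.grid):
        raise GridMismatchError("matrix width != transfer grid length")
    return X @ tm.E + tm.B


def save_transfer(tm: TransferModel, path: str) -> None:
    """Persist the transfer model as a compressed npz container."""
    np.savez_compressed(path, E=tm.E, B=tm.B, grid=tm.grid.values,
                        n_reps=tm.n_reps, svd_tol=tm.svd_tol)


def load_transfer(path: str) -> TransferModel:
    with np.load(path) as z:
        return TransferModel(E=z["E"], B=z["B"],
                             grid=WavenumberGrid(z["grid"]),
                             n_reps=int(z["n_reps"]), svd_tol=float(z["svd_tol"]))
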