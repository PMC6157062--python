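"""Core domain types and file I/O for FTIR spectra, datasets, and hypercubes.

Conventions
-----------
* Wavenumber grids are stored strictly ascending in cm^-1.  Descending order,
  which spectroscopists prefer for plotting, is a rendering concern only.
* All quantitative modelling operates on absorbance (Beer-Lambert linearity);
  instruments record transmittance, conversion happens at load time.
* Hypercubes are exchanged as ENVI header/binary pairs; pixel (0, 0) is the
  top-left corner and pixels are stored row-major.

File formats
------------
Spectra: two-column CSV ``wavenumber_cm-1,intensity``.
Datasets: wide CSV -- metadata columns (``site,age,part,replicate``), the
three reference columns ``y_cellulose,y_hemicellulose,y_lignin`` (mass
fractions), then one intensity column per grid point named by wavenumber.
Hypercubes: ENVI ``.hdr`` text header plus raw binary block.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

COMPONENTS = ("cellulose", "hemicellulose", "lignin")

MODE_TRANSMITTANCE = "transmittance"
MODE_ABSORBANCE = "absorbance"


class SpectraIOError(ValueError):
    """Base class for domain/file errors raised by this package."""


class DuplicateGridError(SpectraIOError):
    """A wavenumber occurs more than once in a grid."""


class CorruptContainerError(SpectraIOError):
    """Hypercube header and binary block disagree."""


class GridMismatchError(SpectraIOError):
    """Two objects that must share a wavenumber grid do not."""


class DomainError(SpectraIOError):
    """Input values outside the mathematical domain of an operation."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly increasing wavenumber axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise SpectraIOError("grid needs at least two wavenumbers")
        if np.any(v <= 0):
            raise SpectraIOError("wavenumbers must be positive")
        d = np.diff(v)
        if np.any(d == 0):
            raise DuplicateGridError("duplicate wavenumbers in grid")
        if np.any(d < 0):
            raise SpectraIOError("grid must be strictly increasing")

    def __len__(self) -> int:
        return self.values.size

    @property
    def spacing(self) -> float:
        """Nominal step in cm^-1 (median of successive differences)."""
        return float(np.median(np.diff(self.values)))

    @property
    def span(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])

    def nearest_index(self, wavenumber: float) -> int:
        """Index of the grid point nearest ``wavenumber``; ties to lower index."""
        i = int(np.argmin(np.abs(self.values - wavenumber)))
        return i

    def __eq__(self, other: object) -> bool:  # value semantics
        if not isinstance(other, WavenumberGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(
            np.array_equal(self.values, other.values)
        )

    def __hash__(self) -> int:
        return hash((self.values.size, float(self.values[0]), float(self.values[-1])))


@dataclass
class Spectrum:
    """One intensity vector on a wavenumber grid."""

    grid: WavenumberGrid
    intensity: np.ndarray
    mode: str = MODE_ABSORBANCE

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (len(self.grid),):
            raise SpectraIOError(
                f"intensity length {self.intensity.size} != grid length {len(self.grid)}"
            )
        if self.mode not in (MODE_TRANSMITTANCE, MODE_ABSORBANCE):
            raise SpectraIOError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class SampleMeta:
    """Provenance of one macro sample: growth site, culm age, culm part, replicate."""

    site: str
    age: int
    part: str
    replicate: int

    def __post_init__(self) -> None:
        if not self.site or not self.part:
            raise SpectraIOError("site and part must be non-empty")
        if self.replicate < 1:
            raise SpectraIOError("replicate must be >= 1")


@dataclass
class SpectralDataset:
    """Sample x wavenumber matrix with reference mass fractions and metadata.

    ``Y`` columns follow :data:`COMPONENTS` order (cellulose, hemicellulose,
    lignin); entries are unitless mass fractions in [0, 1] whose row sums stay
    below 1 -- the remainder is the non-lignocellulosic residue.
    """

    X: np.ndarray
    Y: np.ndarray
    meta: list[SampleMeta]
    grid: WavenumberGrid
    mode: str = MODE_ABSORBANCE

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        n = self.X.shape[0]
        if self.Y.shape != (n, 3):
            raise SpectraIOError("Y must be n x 3 (cellulose, hemicellulose, lignin)")
        if len(self.meta) != n:
            raise SpectraIOError("meta length must match number of rows")
        if self.X.shape[1] != len(self.grid):
            raise GridMismatchError("X column count != grid length")
        if np.any(self.Y < 0) or np.any(self.Y > 1):
            raise DomainError("mass fractions must lie in [0, 1]")
        if np.any(self.Y.sum(axis=1) >= 1):
            raise DomainError("component mass fractions must sum to < 1 per sample")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def y(self, component: str) -> np.ndarray:
        """Reference vector for one component by name."""
        return self.Y[:, COMPONENTS.index(component)]

    def subset_bands(self, idx: np.ndarray) -> "SpectralDataset":
        """Restrict to a subset of grid indices (ascending order enforced)."""
        idx = np.sort(np.asarray(idx, dtype=int))
        return SpectralDataset(
            X=self.X[:, idx],
            Y=self.Y.copy(),
            meta=list(self.meta),
            grid=WavenumberGrid(self.grid.values[idx]),
            mode=self.mode,
        )


@dataclass
class Hypercube:
    """rows x cols x wavenumber block of pixel spectra from a tissue section."""

    data: np.ndarray
    grid: WavenumberGrid
    pixel_size: float  # um per pixel edge
    mode: str = MODE_ABSORBANCE

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise SpectraIOError("hypercube data must be rows x cols x bands")
        if self.data.shape[2] != len(self.grid):
            raise GridMismatchError("band count != grid length")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise SpectraIOError("hypercube must have at least one pixel")
        if self.pixel_size <= 0:
            raise SpectraIOError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_pixels(self) -> int:
        return self.data.shape[0] * self.data.shape[1]

    def pixel_matrix(self) -> np.ndarray:
        """Flatten to (rows*cols) x p, row-major pixel order."""
        r, c, p = self.data.shape
        return self.data.reshape(r * c, p)


# ---------------------------------------------------------------------------
# Spectrum CSV I/O
# ---------------------------------------------------------------------------


def read_spectrum(path: str | os.PathLike, mode_hint: str = MODE_ABSORBANCE) -> Spectrum:
    """Read a two-column wavenumber/intensity table; any row order accepted.

    The returned spectrum is sorted to ascending wavenumber with intensities
    permuted accordingly.
    """
    try:
        tab = pd.read_csv(path, comment="#")
        if tab.shape[1] < 2:
            raise SpectraIOError(f"{path}: expected two columns")
        wn = tab.iloc[:, 0].to_numpy(dtype=float)
        inten = tab.iloc[:, 1].to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise SpectraIOError(f"{path}: non-numeric rows") from exc
    if np.unique(wn).size != wn.size:
        raise DuplicateGridError(f"{path}: duplicated wavenumbers")
    order = np.argsort(wn, kind="stable")
    return Spectrum(WavenumberGrid(wn[order]), inten[order], mode=mode_hint)


def write_spectrum(s: Spectrum, path: str | os.PathLike) -> None:
    """Write a spectrum as two-column CSV at full double precision."""
    pd.DataFrame(
        {"wavenumber_cm-1": s.grid.values, "intensity": s.intensity}
    ).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Dataset wide-CSV I/O
# ---------------------------------------------------------------------------

_META_COLS = ("site", "age", "part", "replicate")
_Y_COLS = tuple(f"y_{c}" for c in COMPONENTS)


def write_dataset(ds: SpectralDataset, path: str | os.PathLike) -> None:
    """Write one row per sample: meta, reference fractions, intensities."""
    cols: dict[str, object] = {
        "site": [m.site for m in ds.meta],
        "age": [m.age for m in ds.meta],
        "part": [m.part for m in ds.meta],
        "replicate": [m.replicate for m in ds.meta],
    }
    for j, c in enumerate(_Y_COLS):
        cols[c] = ds.Y[:, j]
    frame = pd.DataFrame(cols)
    spec = pd.DataFrame(ds.X, columns=[f"{v:.6f}" for v in ds.grid.values])
    pd.concat([frame, spec], axis=1).to_csv(path, index=False, float_format="%.17g")


def read_dataset(path: str | os.PathLike, mode: str = MODE_ABSORBANCE) -> SpectralDataset:
    tab = pd.read_csv(path)
    missing = [c for c in _META_COLS + _Y_COLS if c not in tab.columns]
    if missing:
        raise SpectraIOError(f"{path}: missing columns {missing}")
    meta = [
        SampleMeta(str(r.site), int(r.age), str(r.part), int(r.replicate))
        for r in tab.itertuples()
    ]
    Y = tab.loc[:, list(_Y_COLS)].to_numpy(dtype=float)
    spec_cols = [c for c in tab.columns if c not in _META_COLS + _Y_COLS]
    grid = WavenumberGrid(np.array([float(c) for c in spec_cols]))
    X = tab.loc[:, spec_cols].to_numpy(dtype=float)
    return SpectralDataset(X=X, Y=Y, meta=meta, grid=grid, mode=mode)


# ---------------------------------------------------------------------------
# ENVI hypercube I/O
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {4: np.dtype("<f4"), 5: np.dtype("<f8")}
_ENVI_CODES = {np.dtype("float32"): 4, np.dtype("float64"): 5}


def _parse_envi_header(text: str) -> dict[str, str]:
    if not text.lstrip().startswith("ENVI"):
        raise CorruptContainerError("missing ENVI magic line")
    body = text.lstrip()[4:]
    # join { ... } groups onto one line
    body = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), body)
    fields: dict[str, str] = {}
    for line in body.splitlines():
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def read_hypercube(path: str | os.PathLike) -> Hypercube:
    """Read an ENVI ``.hdr``/binary pair written by :func:`write_hypercube`.

    ``path`` may point at either member of the pair.
    """
    path = str(path)
    hdr_path = path if path.endswith(".hdr") else path + ".hdr"
    if not os.path.exists(hdr_path):
        base, _ = os.path.splitext(path)
        hdr_path = base + ".hdr"
    with open(hdr_path) as fh:
        fields = _parse_envi_header(fh.read())
    try:
        rows = int(fields["lines"])
        cols = int(fields["samples"])
        bands = int(fields["bands"])
        code = int(fields["data type"])
        interleave = fields.get("interleave", "bip").lower()
    except KeyError as exc:
        raise CorruptContainerError(f"header missing field {exc}") from exc
    if code not in _ENVI_DTYPES:
        raise CorruptContainerError(f"unsupported ENVI data type {code}")
    wl_text = fields.get("wavelength", "")
    wl = np.array(
        [float(t) for t in wl_text.strip("{} ").replace(",", " ").split()], dtype=float
    )
    if wl.size != bands:
        raise CorruptContainerError("wavelength list length != bands")
    dat_path = os.path.splitext(hdr_path)[0] + ".dat"
    raw = np.fromfile(dat_path, dtype=_ENVI_DTYPES[code])
    if raw.size != rows * cols * bands:
        raise CorruptContainerError(
            f"block has {raw.size} values, header implies {rows * cols * bands}"
        )
    if interleave == "bip":
        data = raw.reshape(rows, cols, bands)
    elif interleave == "bil":
        data = raw.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bsq":
        data = raw.reshape(bands, rows, cols).transpose(1, 2, 0)
    else:
        raise CorruptContainerError(f"unknown interleave {interleave!r}")
    pixel_size = float(fields.get("pixel size", "10"))
    mode = fields.get("sample mode", MODE_ABSORBANCE)
    return Hypercube(np.ascontiguousarray(data, dtype=float), WavenumberGrid(wl),
                     pixel_size=pixel_size, mode=mode)


def write_hypercube(cube: Hypercube, path: str | os.PathLike) -> None:
    """Write an ENVI pair ``<path>.hdr`` + ``<path>.dat`` (BIP, float64)."""
    base = str(path)
    if base.endswith(".hdr") or base.endswith(".dat"):
        base = os.path.splitext(base)[0]
    rows, cols, bands = cube.data.shape
    wl = ", ".join(f"{v:.6f}" for v in cube.grid.values)
    header = (
        "ENVI\n"
        "description = {lignomap hypercube}\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 5\n"
        "interleave = bip\n"
        "byte order = 0\n"
        f"pixel size = {cube.pixel_size:.6f}\n"
        f"sample mode = {cube.mode}\n"
        f"wavelength = {{ {wl} }}\n"
    )
    with open(base + ".hdr", "w") as fh:
        fh.write(header)
    np.ascontiguousarray(cube.data, dtype="<f8").tofile(base + ".dat")


# ---------------------------------------------------------------------------
# Mode conversion
# ---------------------------------------------------------------------------


def to_absorbance(s: Spectrum) -> Spectrum:
    """Convert transmittance to absorbance, A = -log10(T); no-op on absorbance."""
    if s.mode == MODE_ABSORBANCE:
        return s
    if np.any(s.intensity <= 0):
        raise DomainError("transmittance must be positive to take -log10")
    return Spectrum(s.grid, -np.log10(s.intensity), mode=MODE_ABSORBANCE)


def to_transmittance(s: Spectrum) -> Spectrum:
    """Inverse of :func:`to_absorbance`: T = 10**(-A)."""
    if s.mode == MODE_TRANSMITTANCE:
        return s
    return Spectrum(s.grid, np.power(10.0, -s.intensity), mode=MODE_TRANSMITTANCE)
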