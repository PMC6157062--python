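"""Pixelwise concentration maps and single-band intensity maps.

A concentration map applies a macro-calibrated PLS1 model to every pixel
spectrum of a (transfer-corrected) hypercube.  Out-of-gamut predictions
(mass fractions below 0 or above 1) are reported through a validity mask and
an out-of-range fraction, never clipped -- silently clipping would hide a
failed transfer.

Single-band maps reproduce the classical semi-quantitative alternative: the
absorbance image at one assignment wavenumber (e.g. 1157 cm^-1 for the
carbohydrate C-O-C stretch, 1504 cm^-1 for the lignin aromatic skeleton,
1734 cm^-1 for the ester C=O).  Band lookup is nearest-neighbour with a
tolerance of two grid steps, ties resolved to the lower index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .plsr import PLSRModel
from .spectra_io import GridMismatchError, Hypercube, SpectraIOError
from .transfer import TransferModel, ds_apply


@dataclass
class ConcentrationMap:
    values: np.ndarray  # rows x cols mass fractions
    component: str
    pixel_size: float
    valid: np.ndarray = field(default=None)  # in-gamut mask
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = (self.values >= 0) & (self.values <= 1)

    @property
    def out_of_range_fraction(self) -> float:
        return float(1.0 - self.valid.mean())


def predict_map(cube: Hypercube, model: PLSRModel,
                tm: TransferModel | None = None) -> ConcentrationMap:
    """Transfer each pixel spectrum (if ``tm`` given), then predict with ``model``.

    The model may be calibrated on a band subset of the cube grid: its
    ``band_idx`` selects those columns after transfer.
    """
    corrected = ds_apply(cube, tm) if tm is not None else cube
    P = corrected.pixel_matrix()
    if model.band_idx is not None:
        if np.max(model.band_idx) >= P.shape[1]:
            raise GridMismatchError("model band indices exceed cube grid")
        P = P[:, model.band_idx]
    elif model.coef.size != P.shape[1]:
        raise GridMismatchError(
            f"model expects {model.coef.size} bands, cube has {P.shape[1]}")
    rows, cols, _ = cube.data.shape
    vals = model.predict(P).reshape(rows, cols)
    cmap = ConcentrationMap(
        values=vals, component=model.component or "unknown",
        pixel_size=cube.pixel_size,
        provenance={
            "transferred": tm is not None,
            "n_lv": model.n_lv,
        },
    )
    cmap.provenance["out_of_range_fraction"] = cmap.out_of_range_fraction
    return cmap


def single_band_map(cube: Hypercube, wavenumber: float,
                    tol_steps: float = 2.0) -> np.ndarray:
    """Per-pixel absorbance at the grid point nearest ``wavenumber``."""
    lo, hi = cube.grid.span
    step = cube.grid.spacing
    if wavenumber < lo - tol_steps * step or wavenumber > hi + tol_steps * step:
        raise SpectraIOError(f"wavenumber {wavenumber} outside grid span")
    i = cube.grid.nearest_index(wavenumber)
    if abs(cube.grid.values[i] - wavenumber) > tol_steps * step:
        raise SpectraIOError(
            f"no grid point within {tol_steps} steps of {wavenumber} cm^-1")
    return cube.data[:, :, i].copy()


def render(cmap: ConcentrationMap, out_prefix: str,
           palette: str = "viridis",
           vmin: float | None = None, vmax: float | None = None) -> dict:
    """Write ``<prefix>.png`` (pseudo-colour) and ``<prefix>.csv`` (numeric map).

    Colour bounds default to the (min, max) of the map and are returned so a
    legend can be reconstructed.
    """
    import matplotlib
    matplotlib.use("Agg")
    from matplotlib import colormaps, colors

    v = cmap.values
    if v.size == 0 or not np.isfinite(v).all():
        raise ValueError("map must be non-empty and finite")
    lo = float(v.min()) if vmin is None else vmin
    hi = float(v.max()) if vmax is None else vmax
    norm = colors.Normalize(vmin=lo, vmax=hi if hi > lo else lo + 1e-12)
    rgba = colormaps[palette](norm(v))
    from matplotlib.image import imsave
    imsave(out_prefix + ".png", rgba)
    np.savetxt(out_prefix + ".csv", v, delimiter=",", fmt="%.12g")
    return {"png": out_prefix + ".png", "csv": out_prefix + ".csv",
            "vmin": lo, "vmax": hi, "palette": palette,
            "component": cmap.component}
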