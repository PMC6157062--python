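"""Synthetic macro spectra, slave-instrument distortion, and tissue hypercubes.

Every stage of the pipeline is exercised on generated data with known ground
truth, because the calibration problem (180 bamboo powder samples, three
tissue sections) has no public counterpart.  The generators emulate:

* a full-factorial sampling design -- 3 growth sites x 5 ages x 4 culm parts
  x 3 replicates = 180 samples, with component mass fractions drawn from
  truncated normals around the cohort statistics (cellulose 0.446 +/- 0.029,
  hemicellulose 0.237 +/- 0.025, lignin 0.204 +/- 0.019) plus small zero-sum
  site/age/part effects whose signs follow the field observations (1-year
  culms richer in cellulose, nodes richer in hemicellulose and lignin, ...);
* Beer-Lambert mixture spectra: each component is a sum of Gaussian bands at
  literature assignment positions, with the overlaps that make single-band
  imaging ambiguous built in deliberately (shared carbohydrate bands at
  1157/1369/1415/1430/1457, the 1610 band shared by all three, and 1734
  contributed by hemicellulose and weakly by lignin); a fourth featureless
  "residue" spectrum carries the non-lignocellulosic mass;
* a slave-instrument response (coarser resolution via Gaussian broadening,
  wavenumber registration shift, gain/offset/path-length scaling, extra
  noise) linking the macro master to the micro slave;
* 21 x 21-pixel tissue sections at 10 um/pixel: a central fiber strand
  (cellulose- and lignin-rich) embedded in parenchyma, with a smooth
  transition band and nearly uniform hemicellulose.  Per-site strand area
  fractions and hemicellulose offsets are consistent between the macro
  design and the cubes, which is what makes 3-standard direct
  standardization a well-posed transfer on this data.

All generators are seed-deterministic and return ground truth sufficient to
score every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter1d

from .spectra_io import (
    COMPONENTS,
    Hypercube,
    SampleMeta,
    SpectraIOError,
    SpectralDataset,
    WavenumberGrid,
)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class SpecError(SpectraIOError):
    pass


# ---------------------------------------------------------------------------
# Pure component spectra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComponentSpectrumSpec:
    """Gaussian band list for one pure component: (center cm^-1, height, FWHM)."""

    component: str
    peaks: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        for c, h, w in self.peaks:
            if not (675.0 <= c <= 4000.0):
                raise SpecError(f"peak center {c} outside 675-4000 cm^-1")
            if h <= 0 or w <= 0:
                raise SpecError("peak heights and widths must be positive")


# Fingerprint bands default to 12 cm^-1 FWHM; the O-H envelope near 3449 is
# broad (180 cm^-1) and C-H near 2946 intermediate, shaped to resemble real
# lignocellulose absorbance profiles.
DEFAULT_COMPONENT_SPECS: tuple[ComponentSpectrumSpec, ...] = (
    ComponentSpectrumSpec("cellulose", (
        (1060.0, 0.90, 45.0),   # C-O backbone
        (1157.0, 0.60, 14.0),   # C-O-C asym stretch (shared with hemicellulose)
        (1369.0, 0.35, 12.0),
        (1373.0, 0.30, 12.0),
        (1415.0, 0.30, 12.0),
        (1425.0, 0.30, 12.0),
        (1430.0, 0.25, 12.0),
        (1457.0, 0.30, 12.0),
        (1508.0, 0.25, 12.0),   # aromatic skeleton
        (1605.0, 0.30, 14.0),
        (1610.0, 0.20, 12.0),   # shared by all three components
        (2946.0, 0.35, 60.0),   # C-H stretch
        (3449.0, 0.80, 180.0),  # O-H stretch
    )),
    ComponentSpectrumSpec("hemicellulose", (
        (1045.0, 0.80, 45.0),
        (1157.0, 0.50, 14.0),
        (1369.0, 0.30, 12.0),
        (1373.0, 0.25, 12.0),
        (1415.0, 0.30, 12.0),
        (1425.0, 0.25, 12.0),
        (1430.0, 0.25, 12.0),
        (1457.0, 0.30, 12.0),
        (1610.0, 0.25, 12.0),
        (1734.0, 0.90, 16.0),   # C=O stretch in ester groups
        (2946.0, 0.30, 60.0),
        (3449.0, 0.60, 180.0),
    )),
    ComponentSpectrumSpec("lignin", (
        (1268.0, 0.50, 20.0),   # guaiacyl ring breathing
        (1504.0, 0.90, 12.0),   # diagnostic aromatic C=C
        (1592.0, 0.50, 14.0),
        (1610.0, 0.35, 12.0),
        (1734.0, 0.45, 16.0),   # carbonyl overlap: the 1734 image tracks
                                # hemicellulose + lignin, not hemicellulose
        (2946.0, 0.30, 60.0),
        (3449.0, 0.40, 180.0),
    )),
)

#: Featureless fourth component carrying the non-lignocellulosic mass.
RESIDUE_SPEC = ComponentSpectrumSpec("residue", (
    (1100.0, 0.30, 80.0),
    (1640.0, 0.30, 60.0),   # O-H bending of absorbed water
    (2920.0, 0.20, 80.0),
    (3400.0, 0.40, 220.0),
))


def restrict_specs(specs, lo: float, hi: float) -> list[ComponentSpectrumSpec]:
    """Drop peaks outside [lo, hi] cm^-1 (for work on trimmed grids)."""
    out = []
    for s in specs:
        peaks = tuple(p for p in s.peaks if lo <= p[0] <= hi)
        if peaks:
            out.append(ComponentSpectrumSpec(s.component, peaks))
    return out


def gen_pure_spectra(specs, grid: WavenumberGrid) -> np.ndarray:
    """Sum-of-Gaussians pure spectra, one row per component spec."""
    lo, hi = grid.span
    out = np.zeros((len(specs), len(grid)))
    for i, spec in enumerate(specs):
        for c, h, w in spec.peaks:
            if not (lo <= c <= hi):
                raise SpecError(f"peak {c} cm^-1 outside grid span [{lo}, {hi}]")
            sigma = w * _FWHM_TO_SIGMA
            out[i] += h * np.exp(-0.5 * ((grid.values - c) / sigma) ** 2)
    return out


# ---------------------------------------------------------------------------
# Factorial design and concentrations
# ---------------------------------------------------------------------------

SITES = ("MY", "BT", "DSH")
PARTS = ("base", "middle", "top", "node")

#: Strand-minus-parenchyma concentration contrast (cellulose, hemi, lignin).
#: Thick-walled fibers are markedly richer in cellulose and lignin than
#: parenchyma; hemicellulose is mildly depleted there.
STRAND_DELTA = np.array([0.10, -0.03, 0.07])
#: Fiber-strand area fraction of each site's imaged field.
SITE_STRAND_FRACTION = {"MY": 0.25, "BT": 0.45, "DSH": 0.65}
#: Per-site hemicellulose offset (second transfer direction), zero-sum.
SITE_HEMI_OFFSET = {"MY": 0.006, "BT": 0.006, "DSH": -0.012}

# zero-sum age effects: 1-year culms have more cellulose, less hemi/lignin
_AGE_EFFECT = {
    "cellulose": {1: 0.012, 2: -0.003, 3: -0.003, 4: -0.003, 5: -0.003},
    "hemicellulose": {1: -0.008, 2: 0.002, 3: 0.002, 4: 0.002, 5: 0.002},
    "lignin": {1: -0.008, 2: 0.002, 3: 0.002, 4: 0.002, 5: 0.002},
}
# zero-sum part effects: nodes poorer in cellulose, richer in hemi/lignin
_PART_EFFECT = {
    "cellulose": {"base": 0.002, "middle": 0.002, "top": 0.005, "node": -0.009},
    "hemicellulose": {"base": -0.003, "middle": -0.003, "top": -0.003, "node": 0.009},
    "lignin": {"base": -0.003, "middle": -0.003, "top": -0.003, "node": 0.009},
}


def mean_strandness(site: str) -> float:
    """Realized mean of the strand-ness field for a site's default geometry.

    The smooth transition band makes the field mean differ from the nominal
    disk-area fraction; site concentration effects are tied to this realized
    mean so that macro site means and cube pixel means describe the same
    concentrations -- the coherence that makes 3-standard DS well-posed.
    """
    return float(strand_profile(21, 21, SITE_STRAND_FRACTION[site]).mean())


def _site_effect(site: str) -> np.ndarray:
    """Site concentration offset, tied to the strand-ness of its tissue."""
    f_bar = float(np.mean([mean_strandness(s) for s in SITES]))
    eff = (mean_strandness(site) - f_bar) * STRAND_DELTA
    return eff + np.array([0.0, SITE_HEMI_OFFSET[site], 0.0])


@dataclass
class DesignSpec:
    """Full factorial design and cohort concentration statistics."""

    sites: tuple[str, ...] = SITES
    ages: tuple[int, ...] = (1, 2, 3, 4, 5)
    parts: tuple[str, ...] = PARTS
    replicates: int = 3
    means: np.ndarray = field(
        default_factory=lambda: np.array([0.446, 0.237, 0.204]))
    stds: np.ndarray = field(
        default_factory=lambda: np.array([0.029, 0.025, 0.019]))
    seed: int = 0

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.stds = np.asarray(self.stds, dtype=float)
        if np.any(self.means <= 0) or np.any(self.means >= 1):
            raise SpecError("component means must lie in (0, 1)")
        if np.any(self.stds <= 0):
            raise SpecError("component STDs must be positive")
        if self.means.sum() >= 1:
            raise SpecError("component means must sum to < 1")

    @property
    def n_samples(self) -> int:
        return len(self.sites) * len(self.ages) * len(self.parts) * self.replicates


def gen_design(spec: DesignSpec | None = None) -> tuple[list[SampleMeta], np.ndarray]:
    """Factorial metadata plus concentration matrix Y (n x 3 mass fractions)."""
    spec = spec or DesignSpec()
    rng = np.random.default_rng(spec.seed)
    meta: list[SampleMeta] = []
    rows: list[np.ndarray] = []
    for site in spec.sites:
        for age in spec.ages:
            for part in spec.parts:
                for rep in range(1, spec.replicates + 1):
                    meta.append(SampleMeta(site, age, part, rep))
                    base = rng.normal(spec.means, spec.stds)
                    # truncate: redraw any component outside a plausible window
                    for _ in range(100):
                        bad = (base < 0.02) | (base > 0.9)
                        if not bad.any():
                            break
                        base[bad] = rng.normal(spec.means[bad], spec.stds[bad])
                    y = base.copy()
                    if site in SITE_STRAND_FRACTION:
                        y = y + _site_effect(site)
                    for j, comp in enumerate(COMPONENTS):
                        y[j] += _AGE_EFFECT[comp].get(age, 0.0)
                        y[j] += _PART_EFFECT[comp].get(part, 0.0)
                    y = np.clip(y, 0.02, 0.9)
                    if y.sum() >= 0.95:
                        y *= 0.95 / y.sum() * 0.999
                    rows.append(y)
    return meta, np.array(rows)


# ---------------------------------------------------------------------------
# Macro (master-instrument) spectra
# ---------------------------------------------------------------------------


def gen_macro_spectra(Y: np.ndarray, pure: np.ndarray, grid: WavenumberGrid,
                      snr: float = 200.0, baseline: tuple[float, float] = (0.02, 5e-6),
                      seed: int = 0, residue: np.ndarray | None = None,
                      meta: list[SampleMeta] | None = None,
                      gain_jitter_sd: float = 0.015,
                      offset_jitter_sd: float = 0.004,
                      ref_noise_sd: float = 0.004) -> SpectralDataset:
    """Beer-Lambert forward model: X = Y @ pure + residue term + baseline + noise.

    The non-lignocellulosic mass (1 - row sum of Y) absorbs through a fourth
    residue spectrum.  Detector noise is i.i.d. Gaussian scaled so that the
    mean signal divided by the noise SD equals ``snr``.  On top of the shared
    linear baseline, each sample carries a multiplicative path-length jitter
    (KBr pellet thickness, ``gain_jitter_sd``) and an additive baseline
    offset jitter (``offset_jitter_sd``) -- the pellet-to-pellet variability
    that keeps the calibration problem realistically imperfect.  The
    *reported* reference concentrations additionally carry the wet-chemistry
    assay error ``ref_noise_sd`` (absolute mass-fraction units), which sets
    the realistic floor on the achievable prediction error.  Set all three
    to zero for an exact noise-free mixture.
    """
    Y = np.asarray(Y, dtype=float)
    pure = np.asarray(pure, dtype=float)
    if snr <= 0:
        raise SpecError("snr must be positive")
    if Y.shape[1] != pure.shape[0]:
        raise SpectraIOError("Y columns must match pure spectrum count")
    if pure.shape[1] != len(grid):
        raise SpectraIOError("pure spectra width must match grid")
    if residue is None:
        residue = gen_pure_spectra([RESIDUE_SPEC], grid)[0]
    a, b = baseline
    n = Y.shape[0]
    rng = np.random.default_rng(seed)
    clean = Y @ pure + np.outer(1.0 - Y.sum(axis=1), residue)
    gains = 1.0 + (rng.normal(0.0, gain_jitter_sd, size=n)
                   if gain_jitter_sd > 0 else np.zeros(n))
    offsets = (rng.normal(0.0, offset_jitter_sd, size=n)
               if offset_jitter_sd > 0 else np.zeros(n))
    clean = gains[:, None] * clean + a + b * grid.values + offsets[:, None]
    noise_sd = float(clean.mean()) / snr if np.isfinite(snr) else 0.0
    X = clean + rng.normal(0.0, noise_sd, size=clean.shape)
    Y_ref = Y.copy()
    if ref_noise_sd > 0:
        Y_ref = np.clip(Y + rng.normal(0.0, ref_noise_sd, size=Y.shape),
                        0.005, 0.95)
        over = Y_ref.sum(axis=1) >= 0.95
        Y_ref[over] *= 0.95 / Y_ref[over].sum(axis=1, keepdims=True) * 0.999
    if meta is None:
        meta = [SampleMeta("SYN", 1, "middle", i + 1) for i in range(n)]
    return SpectralDataset(X=X, Y=Y_ref, meta=meta, grid=grid)


def gen_macro_dataset(spec: DesignSpec | None = None,
                      grid: WavenumberGrid | None = None,
                      snr: float = 200.0, seed: int | None = None) -> SpectralDataset:
    """Convenience: factorial design rendered to a macro SpectralDataset."""
    from .preprocess import common_grid

    spec = spec or DesignSpec()
    grid = grid or common_grid()
    meta, Y = gen_design(spec)
    pure = gen_pure_spectra(DEFAULT_COMPONENT_SPECS, grid)
    use_seed = spec.seed if seed is None else seed
    return gen_macro_spectra(Y, pure, grid, snr=snr, seed=use_seed + 1, meta=meta)


def plant_outlier(y: np.ndarray, idx: int, k_std: float = 10.0) -> np.ndarray:
    """Return a copy of ``y`` with sample ``idx`` shifted by ``k_std`` pooled STDs."""
    y = np.array(y, dtype=float)
    y[idx] += k_std * y.std()
    return y


# ---------------------------------------------------------------------------
# Slave-instrument response
# ---------------------------------------------------------------------------


@dataclass
class SlaveResponseSpec:
    """Distortion linking master to slave acquisition.

    Defaults: broadening from the master's 4 cm^-1 resolution to the slave's
    8 cm^-1, a 2 cm^-1 registration shift, gain 0.8 with a small additive
    offset, and extra detector noise (absorbance units).
    """

    broadening_fwhm: float = 8.0
    master_fwhm: float = 4.0
    shift: float = 2.0
    gain: float = 0.8
    offset: float = 0.02
    noise_sd: float = 0.002
    pathlength_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.broadening_fwhm < self.master_fwhm:
            raise SpecError("slave broadening must be >= master resolution")
        if self.gain <= 0:
            raise SpecError("gain must be positive")

    @property
    def is_identity(self) -> bool:
        return (self.broadening_fwhm == self.master_fwhm and self.shift == 0
                and self.gain == 1 and self.offset == 0 and self.noise_sd == 0
                and self.pathlength_factor == 1)


def gen_slave(X: np.ndarray, grid: WavenumberGrid, resp: SlaveResponseSpec,
              seed: int = 0) -> np.ndarray:
    """Apply the slave response to spectra (rows of ``X``) on ``grid``.

    Broadening convolves with the Gaussian whose width tops the master
    resolution up to the slave resolution; the registration shift re-samples
    through a cubic spline (edge values held at the boundary sliver); then
    gain/path-length/offset scaling and extra noise.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(grid):
        raise SpectraIOError("spectrum width must match grid")
    lo, hi = grid.span
    if abs(resp.shift) >= (hi - lo):
        raise SpecError("shift pushes the spectrum outside the grid span")
    out = X
    extra = resp.broadening_fwhm ** 2 - resp.master_fwhm ** 2
    if extra > 0:
        sigma_cm = np.sqrt(extra) * _FWHM_TO_SIGMA
        sigma_steps = sigma_cm / grid.spacing
        out = gaussian_filter1d(out, sigma_steps, axis=1, mode="nearest")
    if resp.shift != 0:
        spline = CubicSpline(grid.values, out, bc_type="natural", axis=1)
        coords = np.clip(grid.values - resp.shift, lo, hi)
        out = spline(coords)
    out = resp.gain * resp.pathlength_factor * out + resp.offset
    if resp.noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, resp.noise_sd, size=out.shape)
    return out


# ---------------------------------------------------------------------------
# Tissue hypercubes
# ---------------------------------------------------------------------------


def strand_profile(rows: int = 21, cols: int = 21,
                   strand_fraction: float = 0.45,
                   transition_px: float = 1.5) -> np.ndarray:
    """Smooth strand-ness field t in [0, 1]: 1 inside the fiber strand.

    A central disk whose area matches ``strand_fraction`` of the field, with
    a sigmoidal transition band emulating the strand/parenchyma boundary.
    """
    if not (0 < strand_fraction < 1):
        raise SpecError("strand_fraction must be in (0, 1)")
    r0 = np.sqrt(strand_fraction * rows * cols / np.pi)
    yy, xx = np.mgrid[0:rows, 0:cols]
    d = np.hypot(yy - (rows - 1) / 2.0, xx - (cols - 1) / 2.0)
    return 1.0 / (1.0 + np.exp((d - r0) / transition_px))


def gen_hypercube(rows: int = 21, cols: int = 21, site: str = "BT",
                  grid: WavenumberGrid | None = None,
                  resp: SlaveResponseSpec | None = None,
                  region_mask: np.ndarray | None = None,
                  site_mean: np.ndarray | None = None,
                  pixel_noise_sd: float = 0.006,
                  pixel_size: float = 10.0,
                  seed: int = 0) -> tuple[Hypercube, dict]:
    """Synthetic tissue section rendered through the slave response.

    Pixel concentrations follow ``base + t * STRAND_DELTA`` where t is the
    strand-ness field, plus small i.i.d. jitter (within-section
    heterogeneity, SD ``pixel_noise_sd``).  If ``site_mean`` is given (the
    measured mean composition of the site's collected material, e.g. its
    macro-dataset site mean) the base is chosen so the cube's pixel-mean
    concentration equals it -- the imaged section and the powdered
    calibration samples describe the same material, which is the premise
    that makes the transfer standards representative.  Otherwise the base
    derives from the design's cohort means and the site's designed effects.

    Returns the cube and a ground-truth dict with per-component concentration
    maps, the strand-ness field, and the boolean strand mask (t > 0.5).
    """
    from .preprocess import common_grid

    grid = grid or common_grid()
    resp = resp or SlaveResponseSpec()
    spec = DesignSpec()
    if region_mask is not None:
        t = np.asarray(region_mask, dtype=float)
        if t.shape != (rows, cols):
            raise SpecError("region_mask shape must be (rows, cols)")
    else:
        t = strand_profile(rows, cols, SITE_STRAND_FRACTION.get(site, 0.45))
    if site_mean is not None:
        base = np.asarray(site_mean, dtype=float) - float(t.mean()) * STRAND_DELTA
    else:
        f_bar = float(np.mean([mean_strandness(s) for s in SITES]))
        base = (spec.means - f_bar * STRAND_DELTA
                + np.array([0.0, SITE_HEMI_OFFSET.get(site, 0.0), 0.0]))
    if np.any(base <= 0) or np.any(base + STRAND_DELTA >= 1):
        raise SpecError("region profile means outside (0, 1)")
    rng = np.random.default_rng(seed)
    conc = (base[None, None, :]
            + t[:, :, None] * STRAND_DELTA[None, None, :]
            + rng.normal(0.0, pixel_noise_sd, size=(rows, cols, 3)))
    conc = np.clip(conc, 0.02, 0.9)
    over = conc.sum(axis=2) >= 0.98  # keep a positive residue share
    conc[over] *= 0.98 / conc[over].sum(axis=1, keepdims=True) * 0.999
    lo, hi = grid.span
    pure = gen_pure_spectra(restrict_specs(DEFAULT_COMPONENT_SPECS, lo, hi), grid)
    residue = gen_pure_spectra(restrict_specs([RESIDUE_SPEC], lo, hi), grid)[0]
    Yp = conc.reshape(rows * cols, 3)
    clean = Yp @ pure + np.outer(1.0 - Yp.sum(axis=1), residue)
    slave = gen_slave(clean, grid, resp, seed=seed + 1)
    cube = Hypercube(slave.reshape(rows, cols, len(grid)), grid,
                     pixel_size=pixel_size)
    truth = {comp: conc[:, :, j] for j, comp in enumerate(COMPONENTS)}
    truth["strandness"] = t
    truth["strand_mask"] = t > 0.5
    return cube, truth


def gen_site_cubes(grid: WavenumberGrid | None = None,
                   resp: SlaveResponseSpec | None = None,
                   seed: int = 0,
                   master_ds: SpectralDataset | None = None
                   ) -> tuple[dict[str, Hypercube], dict[str, dict]]:
    """One 21 x 21 cube per growth site, with per-site strand fractions.

    When ``master_ds`` is given, each cube's mean composition is pinned to
    that dataset's realized site mean (sections cut from the same collected
    culms as the calibration powder).
    """
    cubes: dict[str, Hypercube] = {}
    truths: dict[str, dict] = {}
    for i, site in enumerate(SITES):
        site_mean = None
        if master_ds is not None:
            rows = [j for j, m in enumerate(master_ds.meta) if m.site == site]
            if rows:
                site_mean = master_ds.Y[rows].mean(axis=0)
        cube, truth = gen_hypercube(site=site, grid=grid, resp=resp,
                                    site_mean=site_mean,
                                    seed=seed + 97 * (i + 1))
        cubes[site] = cube
        truths[site] = truth
    return cubes, truths
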