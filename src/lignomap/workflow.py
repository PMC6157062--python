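"""End-to-end pipelines: macro calibration and micro chemical imaging.

``calibrate_pipeline`` runs, per component: effective-range restriction,
rank-ordered calibration/prediction allocation, a full-band baseline model,
Monte-Carlo outlier screening and removal, iPLS region selection, CARS band
selection, and the final model on the selected bands.  The report records
the metric progression across the four model stages (full, screened,
interval, bands), the machine-readable analogue of the usual results tables.

``image_pipeline`` builds site-mean representative pairs, fits the direct
standardization transfer, and renders pixelwise concentration maps per
component per cube, plus the classical single-band comparison maps at
1157, 1504, and 1734 cm^-1.

One global seed fans out to stage seeds through a fixed counter scheme
(``stage_seed = (seed * 1009 + k) % 2^31``) so that each stage is
independently reproducible and replaying a recipe on identical inputs
reproduces identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

from . import bandselect, plsr, sampling, transfer
from .imaging import ConcentrationMap, predict_map, single_band_map
from .preprocess import effective_indices
from .spectra_io import COMPONENTS, Hypercube, SpectralDataset

#: Assignment wavenumbers for the single-band comparison maps (cm^-1).
SINGLE_BAND_WAVENUMBERS = (1157.0, 1504.0, 1734.0)


@dataclass
class CalibrationRecipe:
    components: tuple[str, ...] = COMPONENTS
    window: int = 99
    cars_iterations: int = 50
    mc_fraction: float = 0.8
    mcs_loops: int = 5000
    val_fraction: float = 0.2
    max_lv: int = 20
    select_max_lv: int = 15
    n_splits: int = 5
    do_outliers: bool = True
    do_selection: bool = True
    seed: int = 0

    def stage_seed(self, k: int) -> int:
        return (self.seed * 1009 + k) % (2 ** 31)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _stage_metrics(model: plsr.PLSRModel, Xc, yc, Xp, yp,
                   rmsecv: float | None = None) -> dict:
    m = plsr.evaluate(model, Xc, yc, Xp, yp, rmsecv=rmsecv)
    out = {"n_lv": model.n_lv, "n_bands": int(model.coef.size)}
    out.update({k: float(v) for k, v in m.as_dict().items()})
    return out


def _fit_cv(Xc, yc, recipe: CalibrationRecipe, seed: int, max_lv: int,
            grid=None, component=None, band_idx=None):
    cap = min(max_lv, Xc.shape[0] - 1, Xc.shape[1])
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        curve, best = plsr.cross_validate(Xc, yc, max_lv=cap,
                                          n_splits=recipe.n_splits, seed=seed)
    model = plsr.fit(Xc, yc, n_lv=best, grid=grid, component=component,
                     band_idx=band_idx)
    return model, float(curve[best - 1])


def calibrate_pipeline(ds: SpectralDataset,
                       recipe: CalibrationRecipe | None = None
                       ) -> tuple[dict[str, plsr.PLSRModel], dict]:
    """Per-component calibration with outlier screening and band selection.

    The returned models carry ``band_idx`` into the *input* dataset grid, so
    they apply directly to transfer-corrected spectra on that grid.
    """
    recipe = recipe or CalibrationRecipe()
    eff_idx = effective_indices(ds.grid)
    eff = ds.subset_bands(eff_idx)
    models: dict[str, plsr.PLSRModel] = {}
    report: dict = {"recipe": asdict(recipe), "recipe_digest": recipe.digest(),
                    "components": {}}
    for ci, comp in enumerate(recipe.components):
        y = eff.y(comp)
        split = sampling.allocate(y)
        cal, pred = split.calibration_idx, split.prediction_idx
        Xc, yc = eff.X[cal], y[cal]
        Xp, yp = eff.X[pred], y[pred]
        comp_rep: dict = {"n_calibration": int(cal.size),
                          "n_prediction": int(pred.size), "stages": {}}

        model, rcv = _fit_cv(Xc, yc, recipe, recipe.stage_seed(10 + ci),
                             recipe.max_lv)
        comp_rep["stages"]["full"] = _stage_metrics(model, Xc, yc, Xp, yp, rcv)

        if recipe.do_outliers:
            rep = sampling.mcs_outliers(
                Xc, yc, n_loops=recipe.mcs_loops,
                val_fraction=recipe.val_fraction, n_lv=model.n_lv,
                seed=recipe.stage_seed(20 + ci))
            keep = np.setdiff1d(np.arange(cal.size), rep.flagged_idx)
            Xc, yc = Xc[keep], yc[keep]
            comp_rep["outliers"] = {
                "flagged": [int(cal[i]) for i in rep.flagged_idx],
                "n_loops": rep.n_loops, "n_lv": rep.n_lv,
            }
            model, rcv = _fit_cv(Xc, yc, recipe, recipe.stage_seed(30 + ci),
                                 recipe.max_lv)
            comp_rep["stages"]["screened"] = _stage_metrics(
                model, Xc, yc, Xp, yp, rcv)

        band_idx = eff_idx  # indices into the input grid
        if recipe.do_selection:
            isel = bandselect.ipls(Xc, yc, window=recipe.window,
                                   max_lv=recipe.select_max_lv,
                                   n_splits=recipe.n_splits,
                                   seed=recipe.stage_seed(40 + ci))
            combo_cols = isel.combo_indices()
            model, rcv = _fit_cv(Xc[:, combo_cols], yc, recipe,
                                 recipe.stage_seed(50 + ci),
                                 recipe.select_max_lv,
                                 band_idx=eff_idx[combo_cols])
            comp_rep["stages"]["interval"] = _stage_metrics(
                model, Xc[:, combo_cols], yc, Xp[:, combo_cols], yp, rcv)
            comp_rep["ipls"] = {
                "window": isel.window,
                "n_intervals": len(isel.intervals),
                "best_combo": [int(i) for i in isel.best_combo],
                "combo_rmsecv": float(isel.combo_rmsecv),
            }

            csel = bandselect.cars(
                Xc[:, combo_cols], yc, n_iterations=recipe.cars_iterations,
                mc_fraction=recipe.mc_fraction, max_lv=recipe.select_max_lv,
                n_splits=recipe.n_splits, seed=recipe.stage_seed(60 + ci),
                wavenumbers=eff.grid.values[combo_cols])
            band_idx = eff_idx[combo_cols[csel.selected_idx]]
            model, rcv = _fit_cv(Xc[:, combo_cols[csel.selected_idx]], yc,
                                 recipe, recipe.stage_seed(70 + ci),
                                 recipe.select_max_lv, band_idx=band_idx)
            comp_rep["stages"]["bands"] = _stage_metrics(
                model, Xc[:, combo_cols[csel.selected_idx]], yc,
                Xp[:, combo_cols[csel.selected_idx]], yp, rcv)
            comp_rep["cars"] = {
                "n_selected": int(csel.selected_idx.size),
                "fraction_of_effective": float(
                    csel.selected_idx.size / eff_idx.size),
                "rmsecv": float(csel.rmsecv),
                "wavenumbers": [float(v) for v in csel.selected_wavenumbers],
            }
        model.component = comp
        model.band_idx = band_idx
        models[comp] = model
        report["components"][comp] = comp_rep
    return models, report


def image_pipeline(models: dict[str, plsr.PLSRModel],
                   master_ds: SpectralDataset,
                   cubes: dict[str, Hypercube],
                   svd_tol: float = 1e-8,
                   single_bands: tuple[float, ...] = SINGLE_BAND_WAVENUMBERS
                   ) -> tuple[dict[str, dict[str, ConcentrationMap]], dict]:
    """Transfer-correct each cube and map every component pixelwise.

    Returns ``maps[site][component]`` plus a report holding the transfer
    provenance and the raw single-band comparison maps.
    """
    reps = transfer.make_representatives(master_ds, cubes)
    tm = transfer.ds_fit(reps, svd_tol=svd_tol)
    transfer_id = hashlib.sha256(tm.E.tobytes()).hexdigest()[:12]
    maps: dict[str, dict[str, ConcentrationMap]] = {}
    band_maps: dict[str, dict[float, np.ndarray]] = {}
    for site, cube in cubes.items():
        maps[site] = {}
        for comp, model in models.items():
            cmap = predict_map(cube, model, tm)
            cmap.provenance["transfer_id"] = transfer_id
            cmap.provenance["site"] = site
            maps[site][comp] = cmap
        band_maps[site] = {wn: single_band_map(cube, wn) for wn in single_bands}
    report = {
        "transfer": {"id": transfer_id, "n_reps": tm.n_reps,
                     "svd_tol": tm.svd_tol, "labels": reps.labels},
        "single_band_wavenumbers": list(single_bands),
        "single_band_maps": band_maps,
        "out_of_range": {site: {c: maps[site][c].out_of_range_fraction
                                for c in maps[site]} for site in maps},
    }
    return maps, report
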