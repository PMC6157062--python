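"""Partial least-squares regression (PLS1) with cross-validation and metrics.

One model is built per lignocellulose component (PLS1, a single response at
a time), mirroring the three separate calibrations the workflow produces.
The algorithm is NIPALS with deflation of X only, on mean-centred data;
prediction is ``(x - x_mean) @ coef + y_mean``.

The implementation is vectorized and allocation-light because the outlier
screen and the band-selection search each run thousands of small fits.
Coefficients for *all* latent-variable counts up to A come out of a single
decomposition (the ``R = W (P'W)^-1`` triangular recursion), which makes the
per-LV cross-validation curve cheap.

Metric conventions (chemometric): R^2 is the squared Pearson correlation,
reported separately for calibration (R2c) and prediction (R2p); RMSE is the
population root mean square error; RPD is the reference-set STD divided by
RMSEP.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .spectra_io import DomainError, SpectraIOError, WavenumberGrid


class RankError(SpectraIOError):
    """Requested more latent variables than the data support."""


@dataclass
class PLSRModel:
    """Fitted PLS1 calibration for one component."""

    x_mean: np.ndarray
    y_mean: float
    n_lv: int
    coef: np.ndarray
    grid: WavenumberGrid | None = None
    component: str | None = None
    band_idx: np.ndarray | None = None  # indices into a parent grid, if a subset

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.x_mean) @ self.coef + self.y_mean


@dataclass
class FitMetrics:
    """Calibration/prediction diagnostics in the usual chemometric notation."""

    r2_c: float | None = None
    rmsec: float | None = None
    r2_p: float | None = None
    rmsep: float | None = None
    rmsecv: float | None = None
    rpd: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def _coef_path(Xc: np.ndarray, yc: np.ndarray, max_lv: int) -> np.ndarray:
    """NIPALS PLS1 on centred data; returns (max_lv, p) coefficient paths.

    Row a-1 holds the regression vector using a latent variables.  Stops
    early (repeating the last row) if X deflates to numerical zero.
    """
    X = np.array(Xc, dtype=float)
    y = np.asarray(yc, dtype=float)
    n, p = X.shape
    coefs = np.zeros((max_lv, p))
    R = np.zeros((max_lv, p))  # r_a rows of the triangular recursion
    P = np.zeros((max_lv, p))
    beta = np.zeros(p)
    x_scale = float(np.abs(X).max()) or 1.0
    for a in range(max_lv):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw <= 1e-14 * x_scale * np.linalg.norm(y):
            coefs[a:] = beta  # exhausted: freeze remaining rows
            return coefs
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt <= (1e-14 * x_scale) ** 2 * n:
            coefs[a:] = beta
            return coefs
        pl = (X.T @ t) / tt
        q = float(y @ t) / tt
        X -= np.outer(t, pl)
        # r_a = w_a - sum_{b<a} (p_b . w_a) r_b  (P'W is unit upper triangular)
        r = w - R[:a].T @ (P[:a] @ w)
        R[a] = r
        P[a] = pl
        beta = beta + q * r
        coefs[a] = beta
    return coefs


def fit(X: np.ndarray, y: np.ndarray, n_lv: int,
        grid: WavenumberGrid | None = None,
        component: str | None = None,
        band_idx: np.ndarray | None = None) -> PLSRModel:
    """Fit a PLS1 model with ``n_lv`` latent variables."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n_lv < 1:
        raise RankError("n_lv must be >= 1")
    if n < n_lv + 1:
        raise RankError(f"need at least n_lv+1={n_lv + 1} samples, got {n}")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    coefs = _coef_path(X - x_mean, y - y_mean, n_lv)
    return PLSRModel(x_mean=x_mean, y_mean=y_mean, n_lv=n_lv,
                     coef=coefs[n_lv - 1], grid=grid, component=component,
                     band_idx=band_idx)


def make_folds(n: int, n_splits: int, seed: int) -> list[np.ndarray]:
    """Deterministic k-fold assignment by seeded shuffle of 0..n-1."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, n_splits)]


def cross_validate(X: np.ndarray, y: np.ndarray, max_lv: int,
                   n_splits: int = 5, seed: int = 0,
                   folds: list[np.ndarray] | None = None
                   ) -> tuple[np.ndarray, int]:
    """RMSECV per latent-variable count 1..max_lv and the best count.

    ``best_lv`` is the argmin of the curve (first minimum on ties).  An
    infeasible ``max_lv`` is reduced with a warning rather than raising.
    Passing ``folds`` pins the split; otherwise folds come from ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if folds is None:
        folds = make_folds(n, n_splits, seed)
    min_train = min(n - f.size for f in folds)
    cap = min(min_train - 1, p)
    if max_lv > cap:
        warnings.warn(f"max_lv={max_lv} infeasible; reduced to {cap}", stacklevel=2)
        max_lv = cap
    if max_lv < 1:
        raise RankError("no feasible latent-variable count")
    press = np.zeros(max_lv)
    for val in folds:
        train = np.setdiff1d(np.arange(n), val, assume_unique=False)
        Xt, yt = X[train], y[train]
        xm = Xt.mean(axis=0)
        ym = yt.mean()
        coefs = _coef_path(Xt - xm, yt - ym, max_lv)  # (max_lv, p)
        pred = (X[val] - xm) @ coefs.T + ym  # (n_val, max_lv)
        press += ((pred - y[val, None]) ** 2).sum(axis=0)
    rmsecv = np.sqrt(press / n)
    best_lv = int(np.argmin(rmsecv)) + 1
    return rmsecv, best_lv


def rmse(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    return float(np.sqrt(np.mean((y_pred - y_true) ** 2)))


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Squared Pearson correlation between reference and prediction."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.size < 2:
        raise DomainError("need at least two observations for R^2")
    st = y_true.std()
    sp = y_pred.std()
    if st == 0:
        raise DomainError("R^2 undefined: zero variance in reference values")
    if sp == 0:
        return 0.0
    c = np.corrcoef(y_true, y_pred)[0, 1]
    return float(c * c)


def metrics(y_true: np.ndarray, y_pred: np.ndarray,
            reference_std: float | None = None) -> FitMetrics:
    """Prediction-set diagnostics: R2p, RMSEP, and RPD if a reference STD is given."""
    e = rmse(y_true, y_pred)
    out = FitMetrics(r2_p=r_squared(y_true, y_pred), rmsep=e)
    if reference_std is not None:
        if e == 0:
            out.rpd = float("inf")
        else:
            out.rpd = float(reference_std) / e
    return out


def evaluate(model: PLSRModel, X_cal: np.ndarray, y_cal: np.ndarray,
             X_pred: np.ndarray, y_pred_ref: np.ndarray,
             rmsecv: float | None = None) -> FitMetrics:
    """Full Table-style metrics block for a fitted model."""
    yc_hat = model.predict(X_cal)
    yp_hat = model.predict(X_pred)
    ref_std = float(np.std(y_pred_ref, ddof=1))
    m = metrics(y_pred_ref, yp_hat, reference_std=ref_std)
    m.r2_c = r_squared(y_cal, yc_hat)
    m.rmsec = rmse(y_cal, yc_hat)
    m.rmsecv = rmsecv
    return m


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def model_to_json(model: PLSRModel, path: str, provenance: dict | None = None) -> None:
    doc = {
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean,
        "n_lv": model.n_lv,
        "coef": model.coef.tolist(),
        "component": model.component,
        "grid": model.grid.values.tolist() if model.grid is not None else None,
        "band_idx": model.band_idx.tolist() if model.band_idx is not None else None,
        "provenance": provenance or {},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def model_from_json(path: str) -> PLSRModel:
    with open(path) as fh:
        doc = json.load(fh)
    return PLSRModel(
        x_mean=np.array(doc["x_mean"], dtype=float),
        y_mean=float(doc["y_mean"]),
        n_lv=int(doc["n_lv"]),
        coef=np.array(doc["coef"], dtype=float),
        grid=WavenumberGrid(np.array(doc["grid"])) if doc.get("grid") else None,
        component=doc.get("component"),
        band_idx=np.array(doc["band_idx"], dtype=int) if doc.get("band_idx") else None,
    )
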