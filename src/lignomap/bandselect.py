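"""Two-stage spectral variable selection: iPLS regions, then CARS bands.

Stage 1 -- interval PLS (iPLS): the effective range is cut into equidistant
windows (99 variables each by default; the last window may be short), a
cross-validated PLS1 model is scored on every window, and a greedy forward
search over window combinations returns the combination with the lowest
RMSECV.  This discards whole uninformative regions cheaply.

Stage 2 -- competitive adaptive reweighted sampling (CARS): within the iPLS
region, an iterative competition removes bands with small absolute regression
coefficients.  Each of N iterations (i) fits PLS1 on a Monte-Carlo subsample
of the calibration samples, (ii) normalizes |coefficients| into weights,
(iii) enforces an exponentially decaying retention ratio
``r_i = a * exp(-k * i)`` with ``r_1 = 1`` and ``r_N = 2/p`` (keeping the
largest-weight bands), (iv) resamples the retained set with probability
proportional to weight (adaptive reweighted sampling), and (v) records the
5-fold RMSECV of the surviving subset.  The subset with the global minimum
RMSECV wins.  Retention counts are non-increasing by construction.

Latent-variable counts inside both stages come from an inner 5-fold
cross-validation capped at 15, with fold assignment held fixed across every
candidate subset within one selection run so that RMSECV values compare
like-for-like.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import plsr
from .spectra_io import SpectraIOError


class WindowError(SpectraIOError):
    pass


@dataclass
class IntervalSelection:
    window: int
    intervals: list[tuple[int, int, float]]  # (start, stop_exclusive, rmsecv)
    best_combo: list[int]  # interval ids, ascending
    combo_rmsecv: float

    def combo_indices(self) -> np.ndarray:
        """Variable indices covered by the winning interval combination."""
        parts = [np.arange(self.intervals[i][0], self.intervals[i][1])
                 for i in self.best_combo]
        return np.concatenate(parts) if parts else np.array([], dtype=int)


@dataclass
class BandSelection:
    selected_idx: np.ndarray
    selected_wavenumbers: np.ndarray | None
    rmsecv: float
    n_iterations: int
    trace: list[tuple[int, float]]  # (n_retained, rmsecv) per recorded iteration


def _cv_rmsecv(X: np.ndarray, y: np.ndarray, folds: list[np.ndarray],
               max_lv: int) -> tuple[float, int]:
    """Best RMSECV over 1..max_lv on fixed folds; returns (rmsecv, best_lv)."""
    cap = min(max_lv, X.shape[1], min(X.shape[0] - f.size for f in folds) - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        curve, best = plsr.cross_validate(X, y, max_lv=cap, folds=folds)
    return float(curve[best - 1]), best


def ipls(X: np.ndarray, y: np.ndarray, window: int = 99,
         max_lv: int = 15, n_splits: int = 5, seed: int = 0) -> IntervalSelection:
    """Interval PLS region screening with greedy forward combination search."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if window < 2:
        raise WindowError("window must span at least 2 variables")
    if p < window:
        raise WindowError(f"p={p} smaller than window={window}")
    folds = plsr.make_folds(n, n_splits, seed)
    starts = list(range(0, p, window))
    intervals: list[tuple[int, int, float]] = []
    for s in starts:
        e = min(s + window, p)
        r, _ = _cv_rmsecv(X[:, s:e], y, folds, max_lv)
        intervals.append((s, e, r))

    # greedy forward search, seeded at the best single interval
    k = len(intervals)
    chosen = [int(np.argmin([iv[2] for iv in intervals]))]
    best_r = intervals[chosen[0]][2]
    remaining = [i for i in range(k) if i not in chosen]
    while remaining:
        trial_scores = []
        for cand in remaining:
            ids = sorted(chosen + [cand])
            cols = np.concatenate([np.arange(intervals[i][0], intervals[i][1])
                                   for i in ids])
            r, _ = _cv_rmsecv(X[:, cols], y, folds, max_lv)
            trial_scores.append((r, cand))
        r_best, cand_best = min(trial_scores)
        if r_best < best_r:
            best_r = r_best
            chosen.append(cand_best)
            remaining.remove(cand_best)
        else:
            break
    return IntervalSelection(window=window, intervals=intervals,
                             best_combo=sorted(chosen), combo_rmsecv=best_r)


def cars(X: np.ndarray, y: np.ndarray, n_iterations: int = 50,
         mc_fraction: float = 0.8, max_lv: int = 15, n_splits: int = 5,
         seed: int = 0, wavenumbers: np.ndarray | None = None) -> BandSelection:
    """Competitive adaptive reweighted sampling over the columns of X."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if p < 10:
        raise SpectraIOError("CARS needs at least 10 candidate bands")
    if n < 20:
        raise SpectraIOError("CARS needs at least 20 samples")
    rng = np.random.default_rng(seed)
    folds = plsr.make_folds(n, n_splits, seed)
    # EDF endpoints: r_1 = 1 (all bands), r_N = 2/p
    N = n_iterations
    k = np.log(p / 2.0) / (N - 1)
    a = np.exp(k)
    n_mc = max(2, int(round(mc_fraction * n)))

    retained = np.arange(p)
    trace: list[tuple[int, float]] = []
    best: tuple[float, np.ndarray] | None = None
    warned_skip = False
    for i in range(1, N + 1):
        sub = rng.choice(n, size=n_mc, replace=False)
        Xi = X[np.ix_(sub, retained)]
        _, lv_i = _cv_rmsecv(Xi, y[sub], plsr.make_folds(n_mc, n_splits, seed + i),
                             max_lv)
        model = plsr.fit(Xi, y[sub], n_lv=lv_i)
        w = np.abs(model.coef)
        wsum = w.sum()
        if wsum == 0:
            break
        w = w / wsum
        r_i = a * np.exp(-k * i)
        n_keep = min(retained.size, max(2, int(np.ceil(r_i * p))))
        # enforced retention: largest-weight bands survive the EDF cut
        top = np.argsort(w, kind="stable")[::-1][:n_keep]
        # adaptive reweighted sampling among the survivors; drawing p times
        # keeps the retained count tracking the EDF schedule while still
        # letting weak bands drop out stochastically
        w_top = w[top] / w[top].sum()
        draws = rng.choice(top, size=p, replace=True, p=w_top)
        keep_local = np.unique(draws)
        retained = np.sort(retained[keep_local])
        if retained.size < 2:
            break
        r, best_lv = _cv_rmsecv(X[:, retained], y, folds, max_lv)
        if retained.size <= best_lv:
            if not warned_skip:
                warnings.warn("retained subset smaller than n_lv+1; skipped",
                              stacklevel=2)
                warned_skip = True
            continue
        trace.append((retained.size, r))
        if best is None or r < best[0]:
            best = (r, retained.copy())
    if best is None:
        raise SpectraIOError("CARS recorded no valid subset")
    sel = best[1]
    return BandSelection(
        selected_idx=sel,
        selected_wavenumbers=(np.asarray(wavenumbers, dtype=float)[sel]
                              if wavenumbers is not None else None),
        rmsecv=best[0], n_iterations=N, trace=trace,
    )


def selection_summary(sel: BandSelection, full_p: int) -> float:
    """Fraction of the full variable count retained by a band selection."""
    if full_p <= 0:
        raise SpectraIOError("full_p must be positive")
    return sel.selected_idx.size / full_p
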