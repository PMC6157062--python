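"""Calibration/prediction allocation and Monte-Carlo abnormal-sample screening.

Allocation (rank-ordered triple split): samples are sorted ascending by
reference concentration, cut into consecutive triples, and the middle-ranked
member of each complete triple goes to the prediction set.  The extremes of
every triple stay in calibration, so the calibration range always covers the
prediction range; any incomplete trailing group also stays in calibration.
For n = 180 this yields 120 calibration and 60 prediction samples.

Outlier screening (Monte-Carlo sampling, MCS): over many random 4:1
calibration/validation splits a PLS1 model is fit on the 80% and the
prediction residual of each validation sample is recorded.  A sample whose
residual *mean* or residual *STD* over its validation appearances deviates
from the cohort by more than 3 robust sigmas (1.4826 x MAD about the median)
is flagged as abnormal.  The robust cut automates what is otherwise a visual
read of the mean-vs-STD scatter, and stays stable in the presence of the very
outliers being hunted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import plsr
from .spectra_io import SpectraIOError, SpectralDataset


class TooFewSamplesError(SpectraIOError):
    pass


class CoverageError(SpectraIOError):
    """Some sample was never drawn into a validation fold."""


@dataclass
class SplitResult:
    calibration_idx: np.ndarray
    prediction_idx: np.ndarray


@dataclass
class OutlierReport:
    mean_residual: np.ndarray
    std_residual: np.ndarray
    flagged_idx: np.ndarray
    n_loops: int
    val_fraction: float
    n_lv: int
    counts: np.ndarray = field(default_factory=lambda: np.array([]))


def allocate(y: np.ndarray) -> SplitResult:
    """Rank-ordered triple split of samples by concentration ``y``.

    Ties break by (value, original index) via a stable sort, for determinism.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise TooFewSamplesError(f"need at least 3 samples, got {n}")
    order = np.argsort(y, kind="stable")
    pred: list[int] = []
    cal: list[int] = []
    for start in range(0, n - n % 3, 3):
        triple = order[start:start + 3]
        cal.append(int(triple[0]))
        pred.append(int(triple[1]))
        cal.append(int(triple[2]))
    cal.extend(int(i) for i in order[n - n % 3:])  # trailing partial group
    return SplitResult(
        calibration_idx=np.sort(np.array(cal, dtype=int)),
        prediction_idx=np.sort(np.array(pred, dtype=int)),
    )


def mcs_outliers(X: np.ndarray, y: np.ndarray, n_loops: int = 5000,
                 val_fraction: float = 0.2, n_lv: int | None = None,
                 seed: int = 0, threshold: float = 3.0) -> OutlierReport:
    """Monte-Carlo residual screening for abnormal samples.

    Parameters
    ----------
    n_loops : random split repetitions (5000 by default).
    val_fraction : validation share of each split (0.2 = the 4:1 proportion).
    n_lv : latent variables for the inner models; ``None`` selects it once by
        5-fold cross-validation on the full data, then holds it fixed.
    threshold : robust z cut applied to both the residual mean and STD.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    if n < 10:
        raise TooFewSamplesError("MCS screening needs at least 10 samples")
    n_val = max(1, int(round(n * val_fraction)))
    if n_lv is None:
        max_lv = min(15, (n - n_val) - 1, X.shape[1])
        _, n_lv = plsr.cross_validate(X, y, max_lv=max_lv, seed=seed)
    if n_lv >= 0.8 * n:
        raise SpectraIOError("n_lv too large relative to sample count")
    rng = np.random.default_rng(seed)
    res_sum = np.zeros(n)
    res_sq = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    for _ in range(n_loops):
        perm = rng.permutation(n)
        val, train = perm[:n_val], perm[n_val:]
        model = plsr.fit(X[train], y[train], n_lv=n_lv)
        resid = model.predict(X[val]) - y[val]
        res_sum[val] += resid
        res_sq[val] += resid ** 2
        counts[val] += 1
    if np.any(counts == 0):
        raise CoverageError("n_loops too small: some samples never validated")
    mean_r = res_sum / counts
    var_r = np.maximum(res_sq / counts - mean_r ** 2, 0.0)
    std_r = np.sqrt(var_r)

    # scatter below this floor is numerical, not evidence of abnormality
    eps = 1e-10 * (y.std() if y.std() > 0 else 1.0)

    def robust_flags(v: np.ndarray) -> np.ndarray:
        med = np.median(v)
        scale = 1.4826 * np.median(np.abs(v - med))
        if scale <= eps:
            return np.zeros_like(v, dtype=bool)
        return np.abs(v - med) > threshold * scale

    med_s = np.median(std_r)
    scale_s = 1.4826 * np.median(np.abs(std_r - med_s))
    if scale_s > eps:  # STD cut is one-sided: only inflated scatter is abnormal
        flag_std = (std_r - med_s) > threshold * scale_s
    else:
        flag_std = np.zeros(n, dtype=bool)
    flagged = robust_flags(mean_r) | flag_std
    return OutlierReport(mean_residual=mean_r, std_residual=std_r,
                         flagged_idx=np.flatnonzero(flagged), n_loops=n_loops,
                         val_fraction=val_fraction, n_lv=n_lv, counts=counts)


def remove(ds: SpectralDataset, idx: np.ndarray | list[int]) -> SpectralDataset:
    """Drop samples ``idx`` from X, Y, and metadata consistently."""
    idx = np.asarray(idx, dtype=int)
    n = ds.n_samples
    if idx.size and (idx.min() < 0 or idx.max() >= n):
        raise IndexError(f"sample index out of range 0..{n - 1}")
    keep = np.setdiff1d(np.arange(n), idx)
    return SpectralDataset(
        X=ds.X[keep], Y=ds.Y[keep],
        meta=[ds.meta[i] for i in keep], grid=ds.grid, mode=ds.mode,
    )
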