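"""Voxel-wise global connectedness after nuisance filtering.

The raw volumes x voxels matrix B is cleaned by regressing out a filter
matrix F (tissue mean signals, drift, constant, motion expansions,
within-volume motion proxies, sniff regressors, spike dummies; everything
but the constant z-scored):

    W = (F'F)^-1 F'B,    R = B - F W.

A gray-matter voxel's global connectedness is then the mean absolute
Fisher-z-transformed Pearson correlation between its residual time series
and every other gray-matter voxel's.  Time-resolved variants split each run
into halves and recompute the filter within each segment, and session
comparisons use one-sided Wilcoxon signed-rank tests per time bin.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings as _warnings

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .similarity import CLIP_EPS

__all__ = [
    "build_filter_matrix",
    "residualize",
    "global_connectedness",
    "timebin_connectedness",
    "compare_sessions",
    "seed_peak_select",
    "ConnectednessMap",
]

#: tissue probability thresholds used when masks come from probability maps
GRAY_THRESHOLD = 0.1
WHITE_CSF_THRESHOLD = 0.9
MIN_BIN_VOLUMES = 10


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - x.mean(axis=0)) / sd


def build_filter_matrix(
    B: np.ndarray,
    tissue_labels: np.ndarray,
    confounds: np.ndarray | pd.DataFrame | None = None,
    spikes: np.ndarray | None = None,
) -> np.ndarray:
    """Assemble the nuisance filter F for one segment of data.

    Columns: mean gray / white / CSF signals computed from ``B`` (labels 1 =
    gray, 2 = white, 3 = CSF; 0 = outside), a linear drift, the constant,
    any supplied confound columns (motion and sniff regressors, already
    expanded by the caller or by :func:`expand_motion`), and one dummy
    column per spike volume.  All columns except the constant are z-scored;
    duplicate spike columns are dropped.
    """
    B = np.asarray(B, float)
    n_vol = B.shape[0]
    cols = []
    for lab in (1, 2, 3):  # absent tissue classes contribute no column
        m = tissue_labels == lab
        if m.any():
            cols.append(B[:, m].mean(axis=1))
    cols.append(np.linspace(-1.0, 1.0, n_vol))  # drift
    F = np.column_stack(cols)
    if confounds is not None:
        F = np.column_stack([F, np.asarray(confounds, float)])
    F = _zscore(F)
    if spikes is not None:
        spike_idx = np.unique(np.asarray(spikes, int))
        for i in spike_idx:
            d = np.zeros(n_vol)
            d[i] = 1.0
            F = np.column_stack([F, _zscore(d[:, None])])
    return np.column_stack([F, np.ones(n_vol)])  # constant last, not z-scored


def expand_motion(params: np.ndarray) -> np.ndarray:
    """Derivative, square and squared-derivative expansion of motion traces."""
    p = np.asarray(params, float)
    deriv = np.vstack([np.zeros((1, p.shape[1])), np.diff(p, axis=0)])
    return np.column_stack([p, deriv, p**2, deriv**2])


def residualize(B: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Remove the filter-matrix subspace from every voxel time series.

    Implements the least-squares solution W = (F'F)^-1 F'B and returns
    R = B - F W; the residuals are orthogonal to every filter column and a
    second application is a no-op (projection).
    """
    B = np.asarray(B, float)
    F = np.asarray(F, float)
    if B.shape[0] != F.shape[0]:
        raise ValueError("B and F must have the same number of volumes")
    rank = np.linalg.matrix_rank(F)
    if rank < F.shape[1]:
        dependent = [
            j
            for j in range(F.shape[1])
            if np.linalg.matrix_rank(np.delete(F, j, axis=1)) == rank
        ]
        raise np.linalg.LinAlgError(
            f"filter matrix is rank deficient; dependent columns: {dependent}"
        )
    W, _, _, _ = np.linalg.lstsq(F, B, rcond=None)
    return B - F @ W


@dataclass
class ConnectednessMap:
    """Per-voxel global connectedness (NaN outside gray matter)."""

    values: np.ndarray
    n_constant_dropped: int


def global_connectedness(
    R: np.ndarray,
    gray_mask: np.ndarray,
    exclude_mask: np.ndarray | None = None,
) -> ConnectednessMap:
    """Mean |Fisher z| correlation of each gray voxel with all other gray voxels.

    ``exclude_mask`` removes voxels (e.g. an LPFC ROI) from the *reference*
    set only — every gray voxel still receives a value, computed against the
    remaining gray voxels.  Correlations are clipped away from +/-1 before
    the z-transform; voxels with constant residual series get NaN and are
    dropped from the reference set (their count is reported).
    """
    R = np.asarray(R, float)
    if R.shape[0] < 3:
        raise ValueError("need at least 3 volumes")
    gray_mask = np.asarray(gray_mask, bool)
    gray_idx = np.flatnonzero(gray_mask)
    if gray_idx.size < 2:
        raise ValueError("need at least 2 gray-matter voxels")
    X = R[:, gray_idx]
    sd = X.std(axis=0)
    ok = sd > 0
    n_dropped = int((~ok).sum())
    Z = np.zeros_like(X)
    Z[:, ok] = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
    C = (Z.T @ Z) / R.shape[0]
    A = np.abs(np.arctanh(np.clip(C, -1 + CLIP_EPS, 1 - CLIP_EPS)))

    ref = ok.copy()
    if exclude_mask is not None:
        ref &= ~np.asarray(exclude_mask, bool)[gray_idx]
    values = np.full(R.shape[1], np.nan)
    for pos, vox in enumerate(gray_idx):
        if not ok[pos]:
            continue
        others = ref.copy()
        others[pos] = False
        if not others.any():
            continue
        values[vox] = A[pos, others].mean()
    return ConnectednessMap(values, n_dropped)


def timebin_connectedness(
    B: np.ndarray,
    run_lengths: list[int],
    tissue_labels: np.ndarray,
    roi_mask: np.ndarray,
    confounds: np.ndarray | None = None,
    n_bins_per_run: int = 2,
    exclude_mask: np.ndarray | None = None,
) -> np.ndarray:
    """ROI-mean global connectedness per within-run time bin.

    Each run is split into ``n_bins_per_run`` contiguous segments (the first
    segment takes any extra volume) and the nuisance filter — including the
    tissue means, drift and constant — is re-estimated within each segment
    before computing connectedness.  Returns an array of length
    ``n_runs * n_bins_per_run`` with the ROI average (NaN-voxels excluded).
    """
    B = np.asarray(B, float)
    if sum(run_lengths) != B.shape[0]:
        raise ValueError("run lengths do not sum to the number of volumes")
    gray_mask = tissue_labels == 1
    roi_mask = np.asarray(roi_mask, bool)
    out = []
    offset = 0
    for run_i, n in enumerate(run_lengths):
        base = n // n_bins_per_run
        extra = n - base * n_bins_per_run
        sizes = [base + (1 if b < extra else 0) for b in range(n_bins_per_run)]
        start = offset
        for size in sizes:
            if size < MIN_BIN_VOLUMES:
                _warnings.warn(
                    f"time bin of {size} volumes in run {run_i} is very short",
                    stacklevel=2,
                )
            seg = slice(start, start + size)
            conf_seg = confounds[seg] if confounds is not None else None
            F = build_filter_matrix(B[seg], tissue_labels, conf_seg)
            Rseg = residualize(B[seg], F)
            cmap = global_connectedness(Rseg, gray_mask, exclude_mask)
            out.append(float(np.nanmean(cmap.values[roi_mask & gray_mask])))
            start += size
        offset += n
    return np.array(out)


def compare_sessions(
    sham_bins: np.ndarray, ctbs_bins: np.ndarray, alternative: str = "greater"
) -> pd.DataFrame:
    """Per-bin one-sided Wilcoxon signed-rank tests, sham vs cTBS.

    Inputs are subjects x bins matrices of ROI connectedness.  With the
    default alternative the test asks whether sham exceeds cTBS (stimulation
    lowered connectedness).  For fewer than 5 pairs the exact distribution is
    used (scipy's default for small samples) and a note is attached.
    """
    sham = np.asarray(sham_bins, float)
    ctbs = np.asarray(ctbs_bins, float)
    if sham.shape != ctbs.shape:
        raise ValueError("session matrices must be paired (same subjects x bins)")
    rows = []
    for b in range(sham.shape[1]):
        res = wilcoxon(sham[:, b], ctbs[:, b], alternative=alternative)
        rows.append(
            {
                "bin": b,
                "V": float(res.statistic),
                "p": float(res.pvalue),
                "note": "exact small-sample distribution" if sham.shape[0] < 5 else "",
            }
        )
    return pd.DataFrame(rows)


def seed_peak_select(
    data: np.ndarray,
    seed_mask: np.ndarray,
    search_mask: np.ndarray,
    confounds: np.ndarray | None = None,
) -> tuple[int, float]:
    """Pick the search-ROI voxel most correlated with the seed-ROI mean.

    After regressing confounds (plus a constant) out of all series, the seed
    ROI's mean time course is correlated with every voxel in the search ROI;
    the argmax voxel index (flat, into the full voxel axis) and its
    correlation are returned.  Exact ties resolve to the lowest index.
    """
    data = np.asarray(data, float)
    seed_mask = np.asarray(seed_mask, bool)
    search_mask = np.asarray(search_mask, bool)
    if not seed_mask.any() or not search_mask.any():
        raise ValueError("seed and search ROIs must be non-empty")
    if confounds is not None:
        F = np.column_stack([_zscore(np.asarray(confounds, float)), np.ones(len(data))])
        data = residualize(data, F)
    else:
        data = data - data.mean(axis=0)
    seed_ts = data[:, seed_mask].mean(axis=1)
    search_idx = np.flatnonzero(search_mask)
    X = data[:, search_idx]
    seed_c = seed_ts - seed_ts.mean()
    Xc = X - X.mean(axis=0)
    denom = np.sqrt((seed_c**2).sum()) * np.sqrt((Xc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (Xc.T @ seed_c) / denom, -np.inf)
    best = int(np.argmax(r))
    return int(search_idx[best]), float(r[best])
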