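"""Multivoxel identity-expectation similarity (the ΔS statistic).

For each identity reversal, the cue-evoked pattern on the reversal trial is
correlated with the pattern from the preceding same-cue trial (S_same; the
old association still applies at cue time on both trials) and with the
pattern from the following same-cue trial (S_different; the association has
changed).  The Pearson correlations are Fisher z-transformed and the
difference S_same - S_different, averaged over reversals, indexes how
strongly the patterns carry the currently expected outcome identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import wilcoxon

__all__ = [
    "SimilarityResult",
    "delta_s",
    "searchlight_delta_s",
    "compare_expectation_sessions",
    "reversal_triplets",
    "fisher_z",
]

#: correlations are clipped to +/- (1 - CLIP_EPS) before atanh so planted
#: perfect copies do not produce infinities
CLIP_EPS = 1e-7


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """atanh with clipping away from +/-1."""
    return np.arctanh(np.clip(r, -1.0 + CLIP_EPS, 1.0 - CLIP_EPS))


def _pearson(x: np.ndarray, y: np.ndarray, constant_policy: str) -> float | None:
    """Pearson r with an explicit policy for zero-variance inputs.

    ``"skip"`` returns None (the caller drops the reversal); for
    ``"identical_one"`` two identical constant vectors correlate at 1 (the
    frozen-belief limit of the model curves) and anything else is an error.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        if constant_policy == "skip":
            return None
        if constant_policy == "identical_one":
            if np.array_equal(x, y):
                return 1.0
            raise ValueError("correlation undefined for non-identical constant vectors")
        raise ValueError(f"unknown constant_policy {constant_policy!r}")
    return float(np.corrcoef(x, y)[0, 1])


def reversal_triplets(schedule: pd.DataFrame) -> tuple[list[tuple[int, int, int]], int]:
    """(rev-1, rev, rev+1) row-index triplets for every usable reversal.

    Triplets are formed within one cue's sequence of trials and all three
    members must fall in the same run; reversals whose neighbors straddle a
    run boundary are skipped and counted.
    """
    schedule = schedule.reset_index(drop=True)
    triplets: list[tuple[int, int, int]] = []
    skipped = 0
    for _, idx in schedule.groupby("cue").groups.items():
        idx = np.asarray(idx)
        runs = schedule.loc[idx, "run"].to_numpy()
        revs = np.flatnonzero(schedule.loc[idx, "is_reversal"].to_numpy())
        for k in revs:
            if k - 1 < 0 or k + 1 >= len(idx) or not (runs[k - 1] == runs[k] == runs[k + 1]):
                skipped += 1
                continue
            triplets.append((int(idx[k - 1]), int(idx[k]), int(idx[k + 1])))
    return triplets, skipped


@dataclass
class SimilarityResult:
    """Reversal-averaged pattern similarities; ``delta_s = s_same - s_different``."""

    s_same: float
    s_different: float
    delta_s: float
    n_reversals_used: int
    n_skipped: int
    per_reversal: pd.DataFrame


def delta_s(
    patterns: np.ndarray,
    schedule: pd.DataFrame,
    voxel_subset: np.ndarray | None = None,
    constant_policy: str = "skip",
) -> SimilarityResult:
    """Identity-expectation similarity over a voxel subset.

    ``patterns`` is a trial x voxel matrix row-aligned with ``schedule`` —
    every trial contributes a pattern irrespective of the behavioral
    response.  ``voxel_subset`` may be a boolean mask or integer index into
    the voxel axis (default: all voxels).
    """
    patterns = np.asarray(patterns, float)
    if len(patterns) != len(schedule):
        raise ValueError("patterns and schedule must have one row per trial")
    if voxel_subset is not None:
        patterns = patterns[:, voxel_subset]
    triplets, skipped = reversal_triplets(schedule)
    rows = []
    for prev, rev, nxt in triplets:
        r_same = _pearson(patterns[rev], patterns[prev], constant_policy)
        r_diff = _pearson(patterns[rev], patterns[nxt], constant_policy)
        if r_same is None or r_diff is None:
            skipped += 1
            continue
        zs, zd = float(fisher_z(r_same)), float(fisher_z(r_diff))
        rows.append({"rev_row": rev, "s_same": zs, "s_different": zd, "delta_s": zs - zd})
    if not rows:
        raise ValueError("no usable reversal triplets")
    per = pd.DataFrame(rows)
    s_same = float(per["s_same"].mean())
    s_diff = float(per["s_different"].mean())
    return SimilarityResult(s_same, s_diff, s_same - s_diff, len(per), skipped, per)


def searchlight_delta_s(
    patterns: np.ndarray,
    schedule: pd.DataFrame,
    coords: np.ndarray,
    radius: float = 2.0,
    center_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Map ΔS over searchlight spheres on a voxel grid.

    For every center voxel (optionally restricted to ``center_mask``), ΔS is
    computed over the voxels within Euclidean distance ``radius`` (in voxel
    units) and assigned to the center.  Spheres containing fewer than 3
    voxels are skipped (NaN) — with the default 2-voxel radius a sphere in
    the grid interior holds 33 voxels.
    """
    coords = np.asarray(coords, float)
    n_vox = coords.shape[0]
    if patterns.shape[1] != n_vox:
        raise ValueError("coords must have one row per voxel")
    centers = np.arange(n_vox) if center_mask is None else np.flatnonzero(center_mask)
    tree = cKDTree(coords)
    out = np.full(n_vox, np.nan)
    for c in centers:
        ball = tree.query_ball_point(coords[c], radius)
        if len(ball) < 3:
            continue
        try:
            res = delta_s(patterns, schedule, voxel_subset=np.asarray(ball))
        except ValueError:  # all triplets degenerate in this sphere
            continue
        out[c] = res.delta_s
    return out


def compare_expectation_sessions(
    sham: np.ndarray, ctbs: np.ndarray
) -> dict[str, dict[str, float]]:
    """One-sided Wilcoxon signed-rank tests on per-subject ΔS.

    Tests ΔS_sham > 0 and ΔS_ctbs > 0 (one-sample against zero) and the
    paired contrast ΔS_sham > ΔS_ctbs.  Returns ``{test: {"V": ..., "p": ...}}``.
    """
    sham = np.asarray(sham, float)
    ctbs = np.asarray(ctbs, float)
    if sham.shape != ctbs.shape:
        raise ValueError("sessions must contain the same paired subjects")
    out = {}
    for name, a, b in (
        ("sham_gt_zero", sham, None),
        ("ctbs_gt_zero", ctbs, None),
        ("sham_gt_ctbs", sham, ctbs),
    ):
        res = wilcoxon(a, b, alternative="greater")
        out[name] = {"V": float(res.statistic), "p": float(res.pvalue)}
    return out
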