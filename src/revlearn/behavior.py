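"""Behavioral trial filtering and accuracy-by-position statistics.

Filtering marks trials invalid rather than dropping rows: non-responses
(no choice within the 3 s window) and response-time outliers beyond +/- 3 SD
of the subject's mean RT are excluded from accuracy computations.  Because
the RT statistics are always computed over the full set of responded
trials, applying the filter twice gives the same result as applying it
once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr, ttest_rel

from .task import REV_LABELS

__all__ = [
    "filter_trials",
    "accuracy_by_position",
    "tms_effect",
    "correlate_alpha_effect",
    "TmsEffectResult",
    "RESPONSE_WINDOW_S",
    "ODOR_ID_ACCURACY_CUTOFF",
]

RESPONSE_WINDOW_S = 3.0
RT_SD_CUTOFF = 3.0
#: subjects below this odor-identification accuracy are flagged for exclusion
ODOR_ID_ACCURACY_CUTOFF = 0.8


def filter_trials(
    behavior: pd.DataFrame,
    odor_id_accuracy: float | None = None,
) -> pd.DataFrame:
    """Mark valid trials and report the excluded fraction.

    Adds/overwrites a boolean ``valid`` column and attaches the excluded
    fraction as ``df.attrs["excluded_fraction"]``.  If the subject's mean
    odor-identification accuracy is supplied and falls below 80%,
    ``df.attrs["subject_excluded"]`` is set — the trials themselves remain.
    Raises if nothing survives.
    """
    if "rt" not in behavior or "response" not in behavior:
        raise ValueError("behavior table needs 'rt' and 'response' columns")
    out = behavior.copy()
    rt = out["rt"].to_numpy(float)
    responded = out["response"].notna().to_numpy() & (rt <= RESPONSE_WINDOW_S)
    if "subject" in out:
        groups = out.loc[responded].groupby("subject")["rt"]
        mean = out["subject"].map(groups.mean()).to_numpy(float)
        sd = out["subject"].map(groups.std(ddof=1)).to_numpy(float)
    else:
        mean = np.full(len(out), rt[responded].mean()) if responded.any() else np.nan
        sd = np.full(len(out), rt[responded].std(ddof=1)) if responded.any() else np.nan
    with np.errstate(invalid="ignore"):
        outlier = np.abs(rt - mean) > RT_SD_CUTOFF * np.where(np.isnan(sd), np.inf, sd)
    valid = responded & ~outlier
    if not valid.any():
        raise ValueError("all trials excluded by behavioral filtering")
    out["valid"] = valid
    out.attrs["excluded_fraction"] = float(1.0 - valid.mean())
    if odor_id_accuracy is not None:
        out.attrs["subject_excluded"] = bool(odor_id_accuracy < ODOR_ID_ACCURACY_CUTOFF)
    return out


def accuracy_by_position(
    behavior: pd.DataFrame,
    schedule: pd.DataFrame | None = None,
    per_run: bool = False,
) -> pd.Series | pd.DataFrame:
    """Mean prediction accuracy at rev-1 / rev / rev+1 / rev+2 trials.

    On reversal trials "correct" means predicting the newly delivered odor —
    the subject cannot know the reversal happened, so chance-level accuracy
    is expected there.  Only valid trials count; a position with no valid
    trials yields NaN, not zero.  With ``per_run`` a run x position table is
    returned, otherwise a pooled Series.
    """
    df = behavior
    if "rev_label" not in df:
        if schedule is None:
            raise ValueError("need rev_label in behavior or a classified schedule")
        if len(schedule) != len(df):
            raise ValueError("behavior and schedule tables are misaligned")
        df = df.copy()
        df["rev_label"] = schedule["rev_label"].to_numpy()
    if "valid" in df:
        df = df[df["valid"]]
    df = df[df["rev_label"].isin(REV_LABELS)]
    if per_run:
        table = df.groupby(["run", "rev_label"])["correct"].mean().unstack()
        return table.reindex(columns=REV_LABELS)
    return df.groupby("rev_label")["correct"].mean().reindex(REV_LABELS)


@dataclass
class TmsEffectResult:
    """Per-subject accuracy-change effects and the paired one-sided test."""

    per_subject: pd.DataFrame  # delta_sham, delta_ctbs, effect = sham - ctbs
    t: float
    p: float
    dropped_subjects: list


def tms_effect(sham: pd.DataFrame, ctbs: pd.DataFrame) -> TmsEffectResult:
    """Compare the rev-1 -> rev+1 accuracy change between sessions.

    Inputs are per-subject accuracy tables (index: subject; columns include
    ``rev-1`` and ``rev+1``, e.g. from :func:`accuracy_by_position` applied
    per subject).  For each subject Delta = acc(rev+1) - acc(rev-1) per
    session; a paired one-sided t-test asks whether Delta is larger under
    sham than under cTBS (i.e. stimulation blunts post-reversal recovery).
    Unpaired subjects are dropped with a record.
    """
    common = sham.index.intersection(ctbs.index)
    dropped = sorted(set(sham.index.symmetric_difference(ctbs.index)))
    if len(common) < 2:
        raise ValueError("need at least two paired subjects")
    d_sham = (sham.loc[common, "rev+1"] - sham.loc[common, "rev-1"]).astype(float)
    d_ctbs = (ctbs.loc[common, "rev+1"] - ctbs.loc[common, "rev-1"]).astype(float)
    if np.allclose(d_sham, d_ctbs):
        # identical sessions: zero effect, no evidence either way
        res = type("R", (), {"statistic": 0.0, "pvalue": 0.5})()
    else:
        res = ttest_rel(d_sham, d_ctbs, alternative="greater")
    per = pd.DataFrame(
        {
            "delta_sham": d_sham,
            "delta_ctbs": d_ctbs,
            "effect": d_sham - d_ctbs,
        }
    )
    return TmsEffectResult(per, float(res.statistic), float(res.pvalue), dropped)


def correlate_alpha_effect(
    alpha_diffs: np.ndarray, behavior_effects: np.ndarray
) -> tuple[float, float]:
    """Spearman rank correlation of learning-rate vs behavioral TMS effects.

    ``alpha_diffs`` should be per-subject differences of logit-transformed
    learning rates (sham minus cTBS) and ``behavior_effects`` the matching
    accuracy-change differences.  Returns (rho, p).
    """
    x = np.asarray(alpha_diffs, float)
    y = np.asarray(behavior_effects, float)
    if x.shape != y.shape:
        raise ValueError("vectors must cover the same subjects")
    if x.size < 3:
        raise ValueError("need at least three subjects")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p = spearmanr(x, y)
    return float(rho), float(p)
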