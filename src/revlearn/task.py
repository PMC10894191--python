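"""Trans-reinforcer reversal learning task schedules.

A session consists of several runs of a cue -> odor association task.  On
every trial one of two visual cues is shown and one of three equally valued
food odors is delivered.  Within each run the cue-odor association reverses
a fixed number of times per cue, independently for the two cues, with a
variable (3-5 trial) gap between reversals so that reversal timing cannot be
anticipated.  The two cues' trial sequences are randomly interleaved.

Trials are classified relative to each cue's reversals: the reversal trial
itself (``rev``), the one or two trials after it (``rev+1``, ``rev+2``) and
the trial before it (``rev-1``); everything else is ``other``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TaskConfig",
    "generate_schedule",
    "classify_trials",
    "read_schedule",
    "write_schedule",
    "to_events",
    "REV_LABELS",
]

#: rev-relative labels in canonical plotting order
REV_LABELS = ("rev-1", "rev", "rev+1", "rev+2")

# trial phase durations (seconds): cue, response window, fixation, odor
CUE_S = 1.0
RESPONSE_S = 3.0
FIXATION_S = 4.0
ODOR_S = 2.0
#: cue onset -> odor onset lag
ODOR_LAG_S = CUE_S + RESPONSE_S + FIXATION_S
#: trial length excluding the ITI
TRIAL_FIXED_S = ODOR_LAG_S + ODOR_S


class ScheduleConfigError(ValueError):
    """Raised when a TaskConfig admits no valid schedule."""


@dataclass(frozen=True)
class TaskConfig:
    """Structural parameters of a reversal-learning session."""

    n_runs: int = 3
    n_cues: int = 2
    n_odors: int = 3
    reversals_per_cue_per_run: int = 6
    segment_length_range: tuple[int, int] = (3, 5)
    trials_per_run: int = 64
    iti_range_s: tuple[float, float] = (2.0, 4.0)
    lead_in_s: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.segment_length_range
        if self.n_odors < 2:
            raise ScheduleConfigError("need at least two odors to reverse between")
        if self.trials_per_run % self.n_cues:
            raise ScheduleConfigError("trials_per_run must divide evenly across cues")
        n_seg = self.reversals_per_cue_per_run + 1
        per_cue = self.trials_per_run // self.n_cues
        if not (n_seg * lo <= per_cue <= n_seg * hi):
            raise ScheduleConfigError(
                f"no composition of {n_seg} segments of length {lo}-{hi} "
                f"sums to {per_cue} trials per cue"
            )

    @property
    def trials_per_cue_per_run(self) -> int:
        return self.trials_per_run // self.n_cues


def _segment_lengths(cfg: TaskConfig, rng: np.random.Generator) -> np.ndarray:
    """Segment lengths for one cue in one run, uniform over valid compositions.

    Rejection-samples i.i.d. uniform lengths on the allowed range until they
    sum to the per-cue trial count, which is uniform over the set of
    compositions satisfying both printed task constraints.
    """
    lo, hi = cfg.segment_length_range
    n_seg = cfg.reversals_per_cue_per_run + 1
    target = cfg.trials_per_cue_per_run
    if n_seg * lo == target:
        return np.full(n_seg, lo)
    for _ in range(100_000):
        lengths = rng.integers(lo, hi + 1, size=n_seg)
        if lengths.sum() == target:
            return lengths
    raise ScheduleConfigError("segment-length rejection sampling did not converge")


def generate_schedule(config: TaskConfig) -> pd.DataFrame:
    """Generate a full session schedule.

    Per cue and run, ``reversals_per_cue_per_run + 1`` constant-odor segments
    are drawn; the odor changes (to a uniformly chosen *different* odor)
    exactly at the first trial of every segment after the first.  The
    association carries over across run boundaries, so run starts are not
    reversals.  The cues' within-run sequences are then randomly interleaved
    and ITIs drawn uniformly.

    Returns a tidy trial table with columns ``run, trial, cue, odor,
    is_reversal, rev_label, onset_cue_s, onset_odor_s, iti_s`` (onsets on a
    per-run clock, offset by the lead-in).
    """
    rng = np.random.default_rng(config.seed)
    per_cue = config.trials_per_cue_per_run

    # within-cue odor sequences across the whole session
    odor_seq: dict[int, list[int]] = {}
    rev_seq: dict[int, list[bool]] = {}
    for cue in range(config.n_cues):
        odors: list[int] = []
        revs: list[bool] = []
        current = int(rng.integers(config.n_odors))
        for _ in range(config.n_runs):
            lengths = _segment_lengths(config, rng)
            for seg_i, seg_len in enumerate(lengths):
                if seg_i > 0:  # reversal at segment starts within a run
                    others = [o for o in range(config.n_odors) if o != current]
                    current = int(rng.choice(others))
                for k in range(seg_len):
                    odors.append(current)
                    revs.append(seg_i > 0 and k == 0)
        odor_seq[cue] = odors
        rev_seq[cue] = revs

    records = []
    consumed = {cue: 0 for cue in range(config.n_cues)}
    for run in range(config.n_runs):
        order = np.repeat(np.arange(config.n_cues), per_cue)
        rng.shuffle(order)
        t = config.lead_in_s
        for trial, cue in enumerate(order):
            i = consumed[cue]
            iti = rng.uniform(*config.iti_range_s)
            records.append(
                {
                    "run": run,
                    "trial": trial,
                    "cue": int(cue),
                    "odor": odor_seq[cue][i],
                    "is_reversal": rev_seq[cue][i],
                    "onset_cue_s": t,
                    "onset_odor_s": t + ODOR_LAG_S,
                    "iti_s": iti,
                }
            )
            consumed[cue] += 1
            t += TRIAL_FIXED_S + iti
    schedule = pd.DataFrame.from_records(records)
    return classify_trials(schedule)


def classify_trials(schedule: pd.DataFrame) -> pd.DataFrame:
    """Assign rev-relative labels from the ``is_reversal`` flags.

    Positions are counted within each cue's trial sequence across the whole
    session (run boundaries do not interrupt the count).  Labels are mutually
    exclusive; where a trial is both ``rev+2`` of one reversal and ``rev-1``
    of the next (a 3-trial segment), ``rev-1`` takes precedence, and the
    reversal trial itself always wins.
    """
    schedule = schedule.sort_values(["run", "trial"]).reset_index(drop=True)
    labels = np.full(len(schedule), "other", dtype=object)
    for _, idx in schedule.groupby("cue").groups.items():
        idx = np.asarray(idx)
        revs = np.flatnonzero(schedule.loc[idx, "is_reversal"].to_numpy())
        # increasing precedence: rev+2 < rev+1 < rev-1 < rev
        for offset, lab in ((2, "rev+2"), (1, "rev+1"), (-1, "rev-1"), (0, "rev")):
            pos = revs + offset
            pos = pos[(pos >= 0) & (pos < len(idx))]
            labels[idx[pos]] = lab
    out = schedule.copy()
    out["rev_label"] = labels
    return out


def write_schedule(schedule: pd.DataFrame, path: str | Path) -> None:
    schedule.to_csv(path, sep="\t", index=False)


def read_schedule(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["is_reversal"] = df["is_reversal"].astype(bool)
    return df


def to_events(schedule: pd.DataFrame, kind: str = "both") -> pd.DataFrame:
    """Export a BIDS-style events table (onset, duration, trial_type, run).

    ``kind`` selects cue events (``"cue"``), odor-delivery events labelled by
    rev position (``"odor"``) or both.
    """
    frames = []
    if kind in ("cue", "both"):
        frames.append(
            pd.DataFrame(
                {
                    "run": schedule["run"],
                    "onset": schedule["onset_cue_s"],
                    "duration": CUE_S,
                    "trial_type": "cue",
                    "trial": schedule["trial"],
                }
            )
        )
    if kind in ("odor", "both"):
        frames.append(
            pd.DataFrame(
                {
                    "run": schedule["run"],
                    "onset": schedule["onset_odor_s"],
                    "duration": ODOR_S,
                    "trial_type": "odor_" + schedule["rev_label"].astype(str),
                    "trial": schedule["trial"],
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["run", "onset"]).reset_index(drop=True)
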