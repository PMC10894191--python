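"""Vector delta-rule identity learning model.

The agent maintains, per visual cue, a vector V of expectation strengths
over the possible outcome identities (odors).  After each trial the vector
moves toward the one-hot representation I of the delivered identity:

    delta = I - V
    V <- V + alpha * delta

Choices are generated by a softmax over V with inverse temperature theta,
and the scalar identity prediction error (iPE) is e = sum_i |delta_i|,
which is largest (2) when a fully expected identity is replaced by another
and zero when the outcome is fully expected.  Because the update is a convex
combination of simplex points, V initialized on the probability simplex
stays there, and e is bounded by [0, 2].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import REV_LABELS, TaskConfig, generate_schedule

__all__ = [
    "AgentParams",
    "update_belief",
    "choice_probs",
    "scalar_ipe",
    "minmax_normalize",
    "simulate_agent",
    "simulate_position_curves",
    "model_similarity_curves",
]


@dataclass(frozen=True)
class AgentParams:
    """Learning rate alpha in [0, 1] and softmax inverse temperature theta >= 0."""

    alpha: float
    theta: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.theta < 0.0:
            raise ValueError(f"theta must be >= 0, got {self.theta}")


def update_belief(
    V: np.ndarray, I: np.ndarray, alpha: float
) -> tuple[np.ndarray, np.ndarray]:
    """One delta-rule step; returns (V_next, delta)."""
    V = np.asarray(V, dtype=float)
    I = np.asarray(I, dtype=float)
    if V.shape != I.shape:
        raise ValueError(f"V and I must have equal shapes, got {V.shape} vs {I.shape}")
    delta = I - V
    return V + alpha * delta, delta


def choice_probs(V: np.ndarray, theta: float) -> np.ndarray:
    """Softmax choice probabilities p_i = exp(theta V_i) / sum_z exp(theta V_z)."""
    if theta < 0:
        raise ValueError("theta must be >= 0")
    u = theta * np.asarray(V, dtype=float)
    u = u - u.max()
    e = np.exp(u)
    return e / e.sum()


def scalar_ipe(delta: np.ndarray) -> float:
    """Scalar identity prediction error: L1 norm of the error vector."""
    return float(np.abs(np.asarray(delta, dtype=float)).sum())


def minmax_normalize(series: np.ndarray) -> np.ndarray:
    """Map a series affinely onto [0, 1]; its min becomes 0 and max becomes 1."""
    x = np.asarray(series, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("min-max normalization undefined for a constant series")
    return (x - lo) / (hi - lo)


def one_hot(index: int, n: int) -> np.ndarray:
    v = np.zeros(n)
    v[index] = 1.0
    return v


def simulate_agent(
    schedule: pd.DataFrame,
    params: AgentParams,
    seed: int | np.random.Generator = 0,
    n_odors: int | None = None,
    rt_mean_s: float = 1.2,
    rt_sd_s: float = 0.25,
) -> pd.DataFrame:
    """Play a schedule with a delta-rule/softmax agent.

    On each trial the agent samples a predicted odor from the softmax over
    the presented cue's current V; the *delivered* odor (which does not
    depend on the choice) then drives the update.  V starts uniform for each
    cue and carries over across runs within the session.

    Returns the schedule augmented with ``choice``, ``response``, ``correct``,
    ``rt``, ``e`` (scalar iPE) and ``V_0..V_{n-1}`` (expectations at cue
    time, i.e. before the update).  Simulated response times are log-normal
    around ``rt_mean_s`` so the behavioral filtering pipeline has something
    to act on.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_odors is None:
        n_odors = int(schedule["odor"].max()) + 1
    cues = schedule["cue"].to_numpy()
    odors = schedule["odor"].to_numpy()
    V = {c: np.full(n_odors, 1.0 / n_odors) for c in np.unique(cues)}

    n = len(schedule)
    choice = np.empty(n, dtype=int)
    correct = np.empty(n, dtype=int)
    e = np.empty(n)
    V_rec = np.empty((n, n_odors))
    for t in range(n):
        c, o = cues[t], odors[t]
        p = choice_probs(V[c], params.theta)
        choice[t] = rng.choice(n_odors, p=p)
        correct[t] = int(choice[t] == o)
        V_rec[t] = V[c]
        V[c], delta = update_belief(V[c], one_hot(o, n_odors), params.alpha)
        e[t] = scalar_ipe(delta)

    out = schedule.copy()
    out["choice"] = choice
    out["response"] = choice  # all simulated trials answered
    out["correct"] = correct
    mu = np.log(rt_mean_s) - 0.5 * (rt_sd_s / rt_mean_s) ** 2
    out["rt"] = np.exp(rng.normal(mu, rt_sd_s / rt_mean_s, size=n))
    out["e"] = e
    for i in range(n_odors):
        out[f"V_{i}"] = V_rec[:, i]
    return out


def _position_means(df: pd.DataFrame, col: str) -> dict[str, float]:
    g = df.groupby("rev_label")[col].mean()
    return {lab: float(g.get(lab, np.nan)) for lab in REV_LABELS}


def simulate_position_curves(
    alpha_grid,
    theta: float = 5.0,
    n_reps: int = 200,
    seed: int = 0,
    task_config: TaskConfig | None = None,
) -> pd.DataFrame:
    """Monte-Carlo accuracy and normalized iPE at rev-relative positions.

    For each learning rate, ``n_reps`` sessions are simulated on fresh
    schedules and prediction accuracy / mean scalar iPE are aggregated at
    rev-1, rev, rev+1 and rev+2 trials.  The four mean-iPE values are
    min-max normalized within each alpha, mirroring how simulated iPE
    magnitudes are usually displayed.
    """
    base = task_config or TaskConfig()
    rows = []
    ss = np.random.SeedSequence(seed)
    for alpha in alpha_grid:
        acc = {lab: [] for lab in REV_LABELS}
        ipe = {lab: [] for lab in REV_LABELS}
        for child in ss.spawn(n_reps):
            sched_seed = int(child.generate_state(1)[0] % (2**31))
            sched = generate_schedule(
                TaskConfig(
                    n_runs=base.n_runs,
                    n_cues=base.n_cues,
                    n_odors=base.n_odors,
                    reversals_per_cue_per_run=base.reversals_per_cue_per_run,
                    segment_length_range=base.segment_length_range,
                    trials_per_run=base.trials_per_run,
                    iti_range_s=base.iti_range_s,
                    seed=sched_seed,
                )
            )
            beh = simulate_agent(
                sched, AgentParams(alpha, theta), np.random.default_rng(child)
            )
            a = _position_means(beh, "correct")
            i = _position_means(beh, "e")
            for lab in REV_LABELS:
                acc[lab].append(a[lab])
                ipe[lab].append(i[lab])
        mean_ipe = np.array([np.nanmean(ipe[lab]) for lab in REV_LABELS])
        norm_ipe = minmax_normalize(mean_ipe)
        for k, lab in enumerate(REV_LABELS):
            rows.append(
                {
                    "alpha": float(alpha),
                    "position": lab,
                    "accuracy": float(np.nanmean(acc[lab])),
                    "ipe": float(mean_ipe[k]),
                    "ipe_norm": float(norm_ipe[k]),
                }
            )
    return pd.DataFrame(rows)


def model_similarity_curves(
    alpha_grid,
    theta: float = 5.0,
    n_reps: int = 50,
    seed: int = 0,
    task_config: TaskConfig | None = None,
) -> pd.DataFrame:
    """Similarity of identity-expectation vectors around reversals.

    For each alpha, sessions are simulated and the cue-time V vectors are
    treated as trial "patterns": S_same is the Fisher-z Pearson correlation
    between the rev and rev-1 vectors, S_different between rev and rev+1,
    averaged over reversals; their difference is the model analogue of the
    neural identity-expectation statistic.
    """
    from .similarity import delta_s  # local import to avoid a cycle

    base = task_config or TaskConfig()
    n_odors = base.n_odors
    rows = []
    ss = np.random.SeedSequence(seed)
    for alpha in alpha_grid:
        s_same, s_diff = [], []
        for child in ss.spawn(n_reps):
            sched_seed = int(child.generate_state(1)[0] % (2**31))
            cfg = TaskConfig(
                n_runs=base.n_runs,
                n_cues=base.n_cues,
                n_odors=base.n_odors,
                reversals_per_cue_per_run=base.reversals_per_cue_per_run,
                segment_length_range=base.segment_length_range,
                trials_per_run=base.trials_per_run,
                seed=sched_seed,
            )
            beh = simulate_agent(
                generate_schedule(cfg),
                AgentParams(alpha, theta),
                np.random.default_rng(child),
            )
            patterns = beh[[f"V_{i}" for i in range(n_odors)]].to_numpy()
            res = delta_s(patterns, beh, constant_policy="identical_one")
            s_same.append(res.s_same)
            s_diff.append(res.s_different)
        rows.append(
            {
                "alpha": float(alpha),
                "s_same": float(np.mean(s_same)),
                "s_different": float(np.mean(s_diff)),
                "delta_s": float(np.mean(s_same) - np.mean(s_diff)),
            }
        )
    return pd.DataFrame(rows)
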