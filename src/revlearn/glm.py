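"""Event-related GLMs: design construction, contrasts and single-trial betas.

Task regressors are indicator trains at event onsets convolved with a
canonical double-gamma hemodynamic response function and sampled at the
volume acquisition times; runs are concatenated with one constant column
per run.  The outcome contrast of interest compares reversal-trial odor
responses against the mean of the non-reversal positions,
rev - mean(rev-1, rev+1, rev+2).  Single-trial cue patterns use the
"least squares separate" scheme: one GLM per trial whose first regressor is
that trial's cue event, with all other cue events, the trial's outcome,
all other outcomes and the nuisance set as covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist
from scipy.stats import t as t_dist

__all__ = [
    "canonical_hrf",
    "build_design",
    "fit_glm_contrast",
    "lss_single_trial",
    "group_onesample",
    "GlmResult",
]

HRF_LENGTH_S = 32.0
# double-gamma shape: peak delay 6 s, undershoot delay 16 s, unit
# dispersions, undershoot ratio 1/6 (the standard canonical parameters)
_PEAK_DELAY = 6.0
_UNDERSHOOT_DELAY = 16.0
_UNDERSHOOT_RATIO = 1.0 / 6.0


def canonical_hrf(dt: float) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``dt`` seconds over 32 s.

    Peak-normalized to 1; the kernel is exactly zero at t = 0 and peaks
    near 5 s.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, HRF_LENGTH_S, dt)
    h = gamma_dist.pdf(t, _PEAK_DELAY) - _UNDERSHOOT_RATIO * gamma_dist.pdf(
        t, _UNDERSHOOT_DELAY
    )
    return h / h.max()


def _convolve_run(
    onsets: np.ndarray,
    amplitudes: np.ndarray,
    n_vols: int,
    tr: float,
    dt: float = 0.1,
) -> np.ndarray:
    """HRF-convolved regressor sampled at volume times for one run."""
    run_len = n_vols * tr
    if np.any(onsets < 0) or np.any(onsets >= run_len):
        raise ValueError("event onset outside run duration")
    grid = np.zeros(int(np.ceil(run_len / dt)) + 1)
    idx = np.round(onsets / dt).astype(int)
    np.add.at(grid, idx, amplitudes)
    conv = np.convolve(grid, canonical_hrf(dt))[: len(grid)]
    vol_idx = np.round(np.arange(n_vols) * tr / dt).astype(int)
    return conv[vol_idx]


def build_design(
    events: pd.DataFrame,
    n_vols_per_run: int | list[int],
    tr: float = 2.0,
    confounds: np.ndarray | pd.DataFrame | None = None,
    dt: float = 0.1,
) -> pd.DataFrame:
    """Run-concatenated design matrix from a BIDS-style events table.

    ``events`` needs columns ``run``, ``onset``, ``trial_type`` and
    optionally ``amplitude`` (parametric modulation, default 1).  Task
    regressors span the concatenated runs (zero outside a condition's runs),
    nuisance columns are appended as given, and one constant column per run
    closes the matrix.  Rows = total volumes across runs.
    """
    runs = sorted(events["run"].unique())
    if isinstance(n_vols_per_run, int):
        n_vols = {r: n_vols_per_run for r in runs}
    else:
        n_vols = dict(zip(runs, n_vols_per_run))
    conditions = list(dict.fromkeys(events["trial_type"]))
    blocks = []
    for r in runs:
        sub = events[events["run"] == r]
        cols = {}
        for cond in conditions:
            ev = sub[sub["trial_type"] == cond]
            amp = (
                ev["amplitude"].to_numpy(float)
                if "amplitude" in ev
                else np.ones(len(ev))
            )
            cols[cond] = (
                _convolve_run(ev["onset"].to_numpy(float), amp, n_vols[r], tr, dt)
                if len(ev)
                else np.zeros(n_vols[r])
            )
        blocks.append(pd.DataFrame(cols))
    X = pd.concat(blocks, ignore_index=True)
    if confounds is not None:
        conf = pd.DataFrame(np.asarray(confounds))
        conf.columns = [f"nuisance_{c}" for c in conf.columns]
        if len(conf) != len(X):
            raise ValueError("confound rows must match total volume count")
        X = pd.concat([X, conf.reset_index(drop=True)], axis=1)
    offset = 0
    for r in runs:
        const = np.zeros(len(X))
        const[offset : offset + n_vols[r]] = 1.0
        X[f"constant_run{r}"] = const
        offset += n_vols[r]
    return X


@dataclass
class GlmResult:
    betas: np.ndarray  # regressor x voxel
    effect: np.ndarray  # contrast value per voxel
    t: np.ndarray
    dof: int
    columns: list[str]


def _check_rank(X: np.ndarray, columns: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name columns whose removal does not reduce the rank
        dependent = [
            columns[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear columns: {dependent}"
        )


def fit_glm_contrast(
    Y: np.ndarray, X: pd.DataFrame | np.ndarray, contrast: dict[str, float] | np.ndarray
) -> GlmResult:
    """Voxel-wise OLS with a linear contrast and t statistics.

    ``contrast`` is either a weight vector over design columns or a mapping
    from column name to weight (unnamed columns get 0) — e.g.
    ``{"odor_rev": 1, "odor_rev-1": -1/3, "odor_rev+1": -1/3,
    "odor_rev+2": -1/3}``.
    """
    columns = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"col{j}" for j in range(np.asarray(X).shape[1])
    ]
    Xm = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if Y.shape[0] != Xm.shape[0]:
        raise ValueError("Y and X must have the same number of volumes")
    _check_rank(Xm, columns)
    if isinstance(contrast, dict):
        c = np.array([contrast.get(name, 0.0) for name in columns])
    else:
        c = np.asarray(contrast, float)
    betas, _, _, _ = np.linalg.lstsq(Xm, Y, rcond=None)
    resid = Y - Xm @ betas
    dof = Xm.shape[0] - Xm.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(Xm.T @ Xm)
    effect = c @ betas
    se = np.sqrt(sigma2 * float(c @ xtx_inv @ c))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se, 0.0)
    return GlmResult(betas, effect, t, dof, columns)


def lss_single_trial(
    Y: np.ndarray,
    schedule: pd.DataFrame,
    n_vols_per_run: int | list[int],
    tr: float = 2.0,
    confounds: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Least-squares-separate single-trial cue betas.

    Returns a trial x voxel beta matrix (one row per cue event, schedule
    order) and the matching trial metadata (run, trial, cue, rev_label).
    """
    Y = np.asarray(Y, float)
    sched = schedule.reset_index(drop=True)
    n_trials = len(sched)
    betas = np.empty((n_trials, Y.shape[1]))
    for i in range(n_trials):
        ev = []
        for j in range(n_trials):
            role = "cue_this" if j == i else "cue_other"
            ev.append(
                {"run": sched.loc[j, "run"], "onset": sched.loc[j, "onset_cue_s"],
                 "trial_type": role}
            )
            role = "odor_this" if j == i else "odor_other"
            ev.append(
                {"run": sched.loc[j, "run"], "onset": sched.loc[j, "onset_odor_s"],
                 "trial_type": role}
            )
        events = pd.DataFrame(ev)
        # keep the regressor of interest first
        events["trial_type"] = pd.Categorical(
            events["trial_type"], ["cue_this", "cue_other", "odor_this", "odor_other"]
        )
        events = events.sort_values("trial_type", kind="stable")
        events["trial_type"] = events["trial_type"].astype(str)
        X = build_design(events, n_vols_per_run, tr, confounds)
        Xm = X.to_numpy()
        b, _, _, _ = np.linalg.lstsq(Xm, Y, rcond=None)
        betas[i] = b[list(X.columns).index("cue_this")]
    meta = sched[["run", "trial", "cue", "rev_label"]].copy()
    return betas, meta


def group_onesample(
    effects: np.ndarray,
    method: str = "permutation",
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict[str, np.ndarray | float]:
    """Group inference on subject x voxel effect maps against zero.

    ``method="permutation"`` runs a sign-flip max-statistic permutation test
    (family-wise error controlled over voxels); ``"bonferroni"`` applies a
    Bonferroni-corrected one-sample t-test.  Returns the group t map,
    corrected p-values and the significance mask at ``alpha``.
    """
    E = np.asarray(effects, float)
    n_subj, n_vox = E.shape
    se = E.std(axis=0, ddof=1) / np.sqrt(n_subj)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_obs = np.where(se > 0, E.mean(axis=0) / se, 0.0)
    if method == "bonferroni":
        p = t_dist.sf(t_obs, df=n_subj - 1) * n_vox
        p = np.minimum(p, 1.0)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        max_t = np.empty(n_perm)
        for k in range(n_perm):
            signs = rng.choice([-1.0, 1.0], size=(n_subj, 1))
            Ep = E * signs
            sep = Ep.std(axis=0, ddof=1) / np.sqrt(n_subj)
            with np.errstate(divide="ignore", invalid="ignore"):
                tp = np.where(sep > 0, Ep.mean(axis=0) / sep, 0.0)
            max_t[k] = tp.max()
        p = (1.0 + (max_t[None, :] >= t_obs[:, None]).sum(axis=1)) / (n_perm + 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {"t": t_obs, "p_corrected": p, "significant": p < alpha}
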