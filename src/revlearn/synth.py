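"""Synthetic study generator: behavioral cohorts, voxel time series, sniff traces.

Everything downstream of the task simulator consumes data produced here.
The behavioral generator draws session-wise learning rates from the same
hierarchical Beta structure the fitting module assumes, with hyper means
chosen to mirror an intact (sham ~ 0.8) versus perturbed (cTBS ~ 0.55)
session.  The voxel generator emits AR(1) noise on a small 3-D grid with
labeled tissue boxes and plants three effects the analysis modules are
meant to recover: a high-connectedness hub whose latent-signal coupling is
transiently attenuated in the "cTBS" session's early time bins, cue-evoked
multivoxel patterns whose identity content follows the agent's expectation
vector V, and outcome responses scaling with the scalar identity prediction
error.  A synthetic nasal-airflow trace supplies the four sniff nuisance
regressors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, fftconvolve, filtfilt, lfilter

from .bayes import SubjectData
from .behavior import filter_trials
from .glm import canonical_hrf
from .model import AgentParams, simulate_agent
from .task import TaskConfig, generate_schedule

__all__ = [
    "CohortConfig",
    "VoxelSimConfig",
    "VoxelDataset",
    "gen_cohort",
    "gen_voxel_timeseries",
    "gen_sniff_trace",
    "sniff_regressors",
    "assemble_confound_columns",
]


@dataclass(frozen=True)
class CohortConfig:
    """Behavioral cohort: hierarchical learning-rate truth per session."""

    n_subjects: int = 31
    hyper_mu: dict = field(default_factory=lambda: {"sham": 0.8, "ctbs": 0.55})
    kappa: float = 12.0
    theta_prior: tuple[float, float] = (5.0, 1.0)  # Gamma shape, rate
    seed: int = 0


def gen_cohort(
    cohort_config: CohortConfig, task_config: TaskConfig | None = None
) -> tuple[list[SubjectData], pd.DataFrame]:
    """Simulate a cohort; returns (subjects, truth table).

    Per subject and session: alpha ~ Beta(mu*kappa, (1-mu)*kappa) around the
    session hyper mean; theta ~ Gamma(5, 1) per subject, shared across
    sessions.  Each session gets a fresh schedule, and behavior is generated
    by the delta-rule/softmax agent and passed through the validity filter.
    The truth table records the generating parameters for recovery checks.
    """
    base = task_config or TaskConfig()
    rng = np.random.default_rng(cohort_config.seed)
    t_shape, t_rate = cohort_config.theta_prior
    subjects, truth = [], []
    for j in range(cohort_config.n_subjects):
        sid = f"s{j:02d}"
        theta = float(rng.gamma(t_shape, 1.0 / t_rate))
        sessions = {}
        for name, mu in cohort_config.hyper_mu.items():
            alpha = float(
                np.clip(
                    rng.beta(mu * cohort_config.kappa, (1 - mu) * cohort_config.kappa),
                    0.02,
                    0.98,
                )
            )
            cfg = TaskConfig(
                n_runs=base.n_runs,
                n_cues=base.n_cues,
                n_odors=base.n_odors,
                reversals_per_cue_per_run=base.reversals_per_cue_per_run,
                segment_length_range=base.segment_length_range,
                trials_per_run=base.trials_per_run,
                iti_range_s=base.iti_range_s,
                seed=int(rng.integers(2**31)),
            )
            beh = simulate_agent(generate_schedule(cfg), AgentParams(alpha, theta), rng)
            beh = filter_trials(beh)
            beh["subject"] = sid
            beh["session"] = name
            sessions[name] = beh
            truth.append(
                {"subject": sid, "session": name, "alpha": alpha, "theta": theta,
                 "hyper_mu": mu}
            )
        subjects.append(SubjectData(sid, sessions))
    return subjects, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# voxel time series


def _box(dims, xs, ys, zs) -> np.ndarray:
    """Boolean mask for a box given fractional [lo, hi) ranges per axis."""

    def rng(frac, d):
        lo = int(np.floor(frac[0] * d))
        hi = max(lo, int(np.ceil(frac[1] * d)) - 1)
        return lo, min(hi, d - 1)

    m = np.zeros(dims, bool)
    (x0, x1), (y0, y1), (z0, z1) = (
        rng(xs, dims[0]),
        rng(ys, dims[1]),
        rng(zs, dims[2]),
    )
    m[x0 : x1 + 1, y0 : y1 + 1, z0 : z1 + 1] = True
    return m.reshape(-1)


@dataclass(frozen=True)
class VoxelSimConfig:
    """Geometry, noise and planted-effect amplitudes of the voxel simulator.

    The grid is a labeled box phantom, not a brain: tissue classes and ROIs
    are rectangular regions.  Defaults give signal amplitudes detectable by
    the downstream tests at realistic cohort sizes while leaving the
    background unstructured.
    """

    dims: tuple[int, int, int] = (12, 12, 8)
    tr: float = 2.0
    n_vols_per_run: int = 430
    ar_coef: float = 0.3
    noise_sd: float = 1.0
    hub_loading: float = 1.0
    ctbs_attenuation: float = 0.5
    n_attenuated_bins: int = 2  # early half-run bins with reduced hub coupling
    n_bins_per_run: int = 2
    identity_amp: float = 1.0
    ipe_amp: float = 1.0
    sniff_fs: float = 100.0
    event_dt: float = 0.2

    def masks(self) -> dict[str, np.ndarray]:
        d = self.dims
        return {
            "white": _box(d, (0.0, 0.25), (0.0, 0.25), (0.0, 1.0)),
            "csf": _box(d, (0.75, 1.0), (0.0, 0.25), (0.0, 1.0)),
            "hub": _box(d, (0.35, 0.55), (0.35, 0.55), (0.25, 0.6)),  # "OFC" node
            "lpfc": _box(d, (0.35, 0.55), (0.7, 0.9), (0.25, 0.6)),
            "identity": _box(d, (0.7, 0.9), (0.4, 0.6), (0.25, 0.6)),
            "ipe": _box(d, (0.0, 0.2), (0.7, 0.9), (0.25, 0.6)),
        }

    def tissue_labels(self) -> np.ndarray:
        m = self.masks()
        labels = np.ones(int(np.prod(self.dims)), int)  # gray by default
        labels[m["white"]] = 2
        labels[m["csf"]] = 3
        return labels

    def coords(self) -> np.ndarray:
        return np.argwhere(np.ones(self.dims, bool)).astype(float)


@dataclass
class VoxelDataset:
    """Concatenated-run voxel data plus everything the filters need."""

    data: np.ndarray  # volumes x voxels
    coords: np.ndarray
    tissue_labels: np.ndarray
    run_lengths: list[int]
    masks: dict[str, np.ndarray]
    confounds: pd.DataFrame
    tr: float


def _ar1(rng, n, n_series, phi, sd) -> np.ndarray:
    w = rng.normal(0.0, sd * np.sqrt(1.0 - phi**2), size=(n, n_series))
    return lfilter([1.0], [1.0, -phi], w, axis=0)


def _event_signal(
    onsets: np.ndarray, amplitudes: np.ndarray, n_vols: int, tr: float, dt: float
) -> np.ndarray:
    """HRF-convolved event train(s) sampled at volume times.

    ``amplitudes`` is (n_events,) or (n_events, n_series); returns
    (n_vols, n_series or 1).
    """
    A = np.atleast_2d(np.asarray(amplitudes, float))
    if A.shape[0] == 1 and len(onsets) != 1:
        A = A.T
    run_len = n_vols * tr
    if np.any(onsets < 0) or np.any(onsets >= run_len):
        raise ValueError("event onset outside run duration")
    grid = np.zeros((int(np.ceil(run_len / dt)) + 1, A.shape[1]))
    idx = np.round(onsets / dt).astype(int)
    np.add.at(grid, idx, A)
    h = canonical_hrf(dt)[:, None]
    conv = fftconvolve(grid, h, axes=0)[: len(grid)]
    vol_idx = np.round(np.arange(n_vols) * tr / dt).astype(int)
    return conv[vol_idx]


def gen_voxel_timeseries(
    vox_config: VoxelSimConfig,
    schedule: pd.DataFrame,
    agent_trace: pd.DataFrame,
    seed: int = 0,
    session: str = "sham",
) -> VoxelDataset:
    """Simulate a session of 4-D data on the box phantom.

    Per voxel: AR(1) noise; hub and LPFC voxels additionally load on a
    shared latent AR(1) signal whose loading is multiplied by
    ``ctbs_attenuation`` during the first ``n_attenuated_bins`` half-run
    bins when ``session == "ctbs"`` (transient perturbation, recovered
    afterwards).  Identity-region voxels receive cue-locked responses whose
    amplitude is a fixed per-odor template weighted by the agent's current
    expectation vector V; iPE-region voxels receive outcome-locked responses
    scaling with the scalar prediction error e.  A confound table (motion,
    within-volume proxies, sniff regressors) row-aligned to the volumes is
    attached.
    """
    cfg = vox_config
    rng = np.random.default_rng(seed)
    n_vox = int(np.prod(cfg.dims))
    masks = cfg.masks()
    labels = cfg.tissue_labels()
    runs = sorted(schedule["run"].unique())
    n_runs = len(runs)
    nv = cfg.n_vols_per_run
    run_lengths = [nv] * n_runs

    n_odors = int(schedule["odor"].max()) + 1
    V_cols = [f"V_{i}" for i in range(n_odors)]
    if not set(V_cols) <= set(agent_trace.columns) or "e" not in agent_trace:
        raise ValueError("agent_trace must carry V_* and e columns (simulate_agent output)")
    if len(agent_trace) != len(schedule):
        raise ValueError("agent_trace and schedule are misaligned")

    # fixed per-voxel structure
    hub_w = rng.uniform(0.8, 1.2, size=int(masks["hub"].sum()))
    lpfc_w = rng.uniform(0.8, 1.2, size=int(masks["lpfc"].sum()))
    templates = rng.choice([-1.0, 1.0], size=(int(masks["identity"].sum()), n_odors))
    ipe_w = rng.uniform(0.8, 1.2, size=int(masks["ipe"].sum()))

    data = np.empty((n_runs * nv, n_vox))
    sniff_frames = []
    for run_i, run in enumerate(runs):
        block = _ar1(rng, nv, n_vox, cfg.ar_coef, cfg.noise_sd)
        # latent network signal with per-bin loading multiplier
        latent = _ar1(rng, nv, 1, cfg.ar_coef, 1.0)[:, 0]
        mult = np.ones(nv)
        half = nv // 2
        if session == "ctbs":
            for b in range(cfg.n_bins_per_run):
                global_bin = run_i * cfg.n_bins_per_run + b
                if global_bin < cfg.n_attenuated_bins:
                    seg = slice(b * half, (b + 1) * half if b < cfg.n_bins_per_run - 1 else nv)
                    mult[seg] = cfg.ctbs_attenuation
        loaded = latent * mult
        block[:, masks["hub"]] += cfg.hub_loading * loaded[:, None] * hub_w
        block[:, masks["lpfc"]] += cfg.hub_loading * loaded[:, None] * lpfc_w

        sched_run = schedule[schedule["run"] == run]
        trace_run = agent_trace.loc[sched_run.index]
        if cfg.identity_amp > 0 and len(sched_run):
            amp = cfg.identity_amp * trace_run[V_cols].to_numpy() @ templates.T
            block[:, masks["identity"]] += _event_signal(
                sched_run["onset_cue_s"].to_numpy(), amp, nv, cfg.tr, cfg.event_dt
            )
        if cfg.ipe_amp > 0 and len(sched_run):
            amp = cfg.ipe_amp * trace_run["e"].to_numpy()[:, None] * ipe_w[None, :]
            block[:, masks["ipe"]] += _event_signal(
                sched_run["onset_odor_s"].to_numpy(), amp, nv, cfg.tr, cfg.event_dt
            )
        data[run_i * nv : (run_i + 1) * nv] = block
        sniff = gen_sniff_trace(
            sched_run["onset_odor_s"].to_numpy(),
            run_duration_s=nv * cfg.tr,
            seed=int(rng.integers(2**31)),
            fs=cfg.sniff_fs,
        )
        sniff_frames.append(sniff_regressors(sniff, cfg.sniff_fs, cfg.tr, nv))

    motion = np.cumsum(rng.normal(0, 0.02, size=(n_runs * nv, 6)), axis=0)
    proxies = _ar1(rng, n_runs * nv, 2, 0.2, 1.0)
    confounds = pd.DataFrame(
        np.column_stack([motion, proxies]),
        columns=[f"motion_{k}" for k in range(6)] + ["slice_diff", "slice_var"],
    )
    confounds = pd.concat(
        [confounds, pd.concat(sniff_frames, ignore_index=True)], axis=1
    )
    return VoxelDataset(
        data, cfg.coords(), labels, run_lengths, masks, confounds, cfg.tr
    )


def assemble_confound_columns(confounds: pd.DataFrame) -> np.ndarray:
    """Expand the raw confound table into the full nuisance roster.

    Motion and within-volume proxy columns get derivative, square and
    squared-derivative expansions; the four sniff regressors enter as-is.
    Tissue means, drift and constant are added later by the filter builder.
    """
    from .connectivity import expand_motion

    motion_cols = [c for c in confounds if c.startswith("motion_")]
    proxy_cols = [c for c in confounds if c in ("slice_diff", "slice_var")]
    sniff_cols = [c for c in confounds if c.startswith("sniff_")]
    parts = []
    if motion_cols:
        parts.append(expand_motion(confounds[motion_cols].to_numpy()))
    if proxy_cols:
        parts.append(expand_motion(confounds[proxy_cols].to_numpy()))
    if sniff_cols:
        parts.append(confounds[sniff_cols].to_numpy())
    return np.column_stack(parts)


# ---------------------------------------------------------------------------
# sniffing


def gen_sniff_trace(
    odor_onsets_s: np.ndarray,
    run_duration_s: float,
    seed: int = 0,
    fs: float = 1000.0,
    inhale_duration_s: float = 1.5,
    inhale_amp: float = 1.0,
) -> np.ndarray:
    """Synthetic nasal airflow for one run, sampled at ``fs`` Hz.

    Baseline respiration (slow sinusoid plus noise) with a half-sine
    inhalation bump at every odor-delivery (sniff cue) onset.
    """
    rng = np.random.default_rng(seed)
    n = int(round(run_duration_s * fs))
    t = np.arange(n) / fs
    trace = 0.3 * np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
    trace += rng.normal(0, 0.05, size=n)
    bump_n = int(inhale_duration_s * fs)
    bump = inhale_amp * np.sin(np.pi * np.arange(bump_n) / bump_n)
    for onset in np.asarray(odor_onsets_s, float):
        i = int(round(onset * fs))
        j = min(i + bump_n, n)
        trace[i:j] += bump[: j - i]
    return trace


def sniff_regressors(
    trace: np.ndarray, fs: float, tr: float, n_vols: int
) -> pd.DataFrame:
    """Preprocess an airflow trace into the four sniff nuisance regressors.

    Chain: 250 ms moving-average smoothing, down-sampling to 10 Hz,
    high-pass filtering (50 s cutoff), z-normalization across the run, and a
    final down-sample to one sample per TR.  Sniff volume is the integral of
    the (smoothed, pre-high-pass) airflow over each TR window, so a single
    inhalation's volume equals its area under the curve.  Returns columns
    ``sniff_flow``, ``sniff_volume`` and their squares.
    """
    x = np.asarray(trace, float)
    win = max(int(round(0.25 * fs)), 1)
    kernel = np.ones(win) / win
    smooth = np.convolve(x, kernel, mode="same")
    # down-sample to 10 Hz by block averaging
    step = fs / 10.0
    n10 = int(len(smooth) / step)
    idx = (np.arange(n10) * step).astype(int)
    edges = np.append(idx, len(smooth))
    x10 = np.array([smooth[edges[k] : edges[k + 1]].mean() for k in range(n10)])
    b, a = butter(2, (1.0 / 50.0) / (10.0 / 2.0), btype="highpass")
    hp = filtfilt(b, a, x10)
    sd = hp.std()
    z = (hp - hp.mean()) / sd if sd > 0 else np.zeros_like(hp)
    per_tr = int(round(10.0 * tr))
    flow = z[::per_tr][:n_vols]
    volume = np.array(
        [x10[k * per_tr : (k + 1) * per_tr].sum() * 0.1 for k in range(n_vols)]
    )
    if len(flow) < n_vols:  # trace slightly short of the run: pad with last value
        flow = np.pad(flow, (0, n_vols - len(flow)), mode="edge")
    return pd.DataFrame(
        {
            "sniff_flow": flow,
            "sniff_volume": volume,
            "sniff_flow_sq": flow**2,
            "sniff_volume_sq": volume**2,
        }
    )
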