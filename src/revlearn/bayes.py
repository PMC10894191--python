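"""Hierarchical Bayesian estimation of delta-rule learning rates.

Model.  Subject j's learning rate in session c is drawn from a Beta
distribution in mean / sample-size parameterization,

    alpha_{j,c} ~ Beta(alpha_mu_c * kappa, (1 - alpha_mu_c) * kappa),

with hyper-priors alpha_mu_c ~ Beta(8, 2) (learning in this task is easy,
so rates are expected near 1), kappa ~ Gamma(shape 1, rate 0.1), and one
softmax inverse temperature per subject, theta_j ~ Gamma(shape 5, rate 1),
shared across sessions.  A baseline ("fixed") variant ties alpha_{j} across
sessions under a single hyper mean.  The likelihood of a session is the
softmax probability of each observed choice given the expectation vector V
propagated by the delta rule from the delivered-odor sequence; trials
flagged invalid contribute no likelihood but still drive the updates.

Sampling is adaptive Metropolis-within-Gibbs: each parameter gets a
random-walk proposal on an unconstrained scale (logit for rates and hyper
means, log for kappa and theta) whose step size is tuned toward ~40%
acceptance during burn-in and frozen afterwards.  The deviance
-2 log p(choices | alpha, theta) is recorded for every retained draw for
DIC computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln
from scipy.stats import gaussian_kde

__all__ = [
    "HierarchicalSpec",
    "MCMCSettings",
    "SubjectData",
    "PosteriorSamples",
    "FitSummary",
    "choice_loglik",
    "fit_hierarchical",
    "rhat",
    "map_estimate",
    "dic",
    "posterior_predictive",
    "summarize_fit",
]

RHAT_THRESHOLD = 1.1


@dataclass(frozen=True)
class HierarchicalSpec:
    """Priors of the hierarchical learning-rate model (shape/rate Gammas)."""

    session_wise: bool = True
    hyper_alpha_prior: tuple[float, float] = (8.0, 2.0)
    kappa_prior: tuple[float, float] = (1.0, 0.1)
    theta_prior: tuple[float, float] = (5.0, 1.0)


@dataclass(frozen=True)
class MCMCSettings:
    n_chains: int = 3
    n_iter: int = 5000
    n_burnin: int = 2000
    seed: int = 0

    @property
    def n_retained(self) -> int:
        return self.n_chains * (self.n_iter - self.n_burnin)


@dataclass
class SubjectData:
    """One subject's behavior, keyed by session label (e.g. sham / ctbs)."""

    subject: str
    sessions: dict[str, pd.DataFrame]


# ---------------------------------------------------------------------------
# likelihood


class _SessionLik:
    """Vectorized choice log-likelihood for one session.

    With one-hot outcomes the delta rule has the closed form
    V_k = g^k * V0 + alpha * sum_{j<k} g^(k-1-j) * I_j  (g = 1 - alpha),
    so the whole V trajectory of a cue is a lower-triangular weighted sum of
    the delivered-odor indicators — no sequential loop per evaluation.
    """

    def __init__(self, behavior: pd.DataFrame, n_odors: int | None = None):
        if len(behavior) == 0:
            raise ValueError("empty behavioral table")
        if n_odors is None:
            n_odors = int(max(behavior["odor"].max(), behavior["choice"].max())) + 1
        self.n_odors = n_odors
        self.n_trials_scored = 0
        self._cues = []
        valid = (
            behavior["valid"].to_numpy(bool)
            if "valid" in behavior
            else np.ones(len(behavior), bool)
        )
        for _, sub in behavior.groupby("cue"):
            d = sub["odor"].to_numpy(int)
            ch = sub["choice"].to_numpy(int)
            v = valid[sub.index.to_numpy()] if "valid" in behavior else np.ones(len(sub), bool)
            m = len(d)
            D = np.zeros((m, n_odors))
            D[np.arange(m), d] = 1.0
            # exponent matrix E[k, j] = k - 1 - j for j < k
            k = np.arange(m)
            E = k[:, None] - 1 - k[None, :]
            mask = (E >= 0).astype(float)
            self._cues.append((D, ch, v, np.maximum(E, 0), mask, m, np.arange(m)))
            self.n_trials_scored += int(v.sum())

    def loglik(self, alpha: float, theta: float) -> float:
        g = 1.0 - alpha
        total = 0.0
        for D, ch, v, E, mask, m, ar in self._cues:
            powers = g**ar  # m scalar pows; W is a masked Toeplitz of these
            W = alpha * mask * powers[E]
            V = powers[:, None] / self.n_odors + W @ D
            U = theta * V
            umax = U.max(axis=1)
            ll = U[ar, ch] - umax - np.log(np.exp(U - umax[:, None]).sum(axis=1))
            total += ll[v].sum()
        return float(total)


def choice_loglik(
    behavior: pd.DataFrame,
    schedule: pd.DataFrame | None = None,
    alpha: float = 0.5,
    theta: float = 5.0,
) -> float:
    """Choice log-likelihood of one session at (alpha, theta).

    ``behavior`` must carry ``cue``, ``odor`` (delivered) and ``choice``
    columns; if a ``schedule`` is given it must align row-wise with the
    behavior (same run/trial sequence) and supplies cue/odor when absent
    from the behavior table.  Invalid trials (``valid`` column False) are
    excluded from the sum but still propagate the belief updates.
    """
    if schedule is not None:
        if len(schedule) != len(behavior):
            raise ValueError("behavior and schedule tables are misaligned")
        cols = behavior.copy()
        for col in ("cue", "odor"):
            if col not in cols:
                cols[col] = schedule[col].to_numpy()
            elif not np.array_equal(cols[col].to_numpy(), schedule[col].to_numpy()):
                raise ValueError(f"behavior and schedule disagree on {col!r}")
        behavior = cols
    if not 0.0 <= alpha <= 1.0 or theta < 0:
        raise ValueError("alpha must lie in [0,1] and theta must be >= 0")
    return _SessionLik(behavior.reset_index(drop=True)).loglik(alpha, theta)


# ---------------------------------------------------------------------------
# sampler


def _logit(x):
    return np.log(x) - np.log1p(-x)


def _expit(z):
    # clipped away from {0, 1} so proposals stay in the open interval
    return np.clip(1.0 / (1.0 + np.exp(-np.clip(z, -500, 500))), 1e-12, 1 - 1e-12)


def _log_beta_pdf(x, a, b):
    return (a - 1) * np.log(x) + (b - 1) * np.log1p(-x) - betaln(a, b)


def _log_gamma_pdf(x, shape, rate):
    return shape * np.log(rate) + (shape - 1) * np.log(x) - rate * x - gammaln(shape)


@dataclass
class PosteriorSamples:
    """MCMC draws: each entry is a (n_chains, n_kept) array."""

    draws: dict[str, np.ndarray]
    deviance: np.ndarray
    settings: MCMCSettings
    spec: HierarchicalSpec
    session_names: tuple[str, ...]
    subject_ids: tuple[str, ...]

    @property
    def n_retained(self) -> int:
        return int(next(iter(self.draws.values())).size)

    def pooled(self, parameter: str) -> np.ndarray:
        return self.draws[parameter].reshape(-1)


@dataclass
class FitSummary:
    rhat: dict[str, float]
    map: dict[str, float]
    dic: float | None
    converged: bool
    warnings: list[str] = field(default_factory=list)


class _State:
    """Current parameter values plus cached per-(subject, session) log-liks."""

    __slots__ = ("alpha", "alpha_mu", "kappa", "theta", "lik", "total_ll")

    def __init__(self, alpha, alpha_mu, kappa, theta, lik):
        self.alpha = alpha  # (n_subj, n_alpha_cols)
        self.alpha_mu = alpha_mu  # (n_alpha_cols,)
        self.kappa = kappa
        self.theta = theta  # (n_subj,)
        self.lik = lik  # (n_subj, n_sessions) cached loglik values


def fit_hierarchical(
    cohort: list[SubjectData],
    spec: HierarchicalSpec = HierarchicalSpec(),
    mcmc: MCMCSettings = MCMCSettings(),
    seed: int | None = None,
    prior_only: bool = False,
) -> PosteriorSamples:
    """Sample the hierarchical posterior for a cohort.

    ``prior_only=True`` drops the likelihood terms, so the chains target the
    prior — useful to validate the sampler against the analytic Beta(8, 2)
    hyper prior.  The number of retained draws is exactly
    ``n_chains * (n_iter - n_burnin)``.
    """
    if not cohort:
        raise ValueError("cohort must contain at least one subject")
    if seed is not None:
        mcmc = MCMCSettings(mcmc.n_chains, mcmc.n_iter, mcmc.n_burnin, seed)
    session_names = tuple(cohort[0].sessions.keys())
    for s in cohort:
        if tuple(s.sessions.keys()) != session_names:
            raise ValueError("all subjects must provide the same sessions")
        for name, df in s.sessions.items():
            if len(df) == 0:
                raise ValueError(f"subject {s.subject} has no trials in {name}")
    subject_ids = tuple(s.subject for s in cohort)
    n_subj, n_sess = len(cohort), len(session_names)
    # column structure of the alpha matrix: one per session, or one shared
    n_acol = n_sess if spec.session_wise else 1

    liks = [
        [_SessionLik(s.sessions[name].reset_index(drop=True)) for name in session_names]
        for s in cohort
    ]

    a_hyp, b_hyp = spec.hyper_alpha_prior
    k_shape, k_rate = spec.kappa_prior
    t_shape, t_rate = spec.theta_prior

    def subj_ll(state: _State, j: int, sess: int, alpha: float, theta: float) -> float:
        if prior_only:
            return 0.0
        return liks[j][sess].loglik(alpha, theta)

    param_names = (
        [f"alpha[{sid},{c}]" for sid in subject_ids for c in
         (session_names if spec.session_wise else ("all",))]
        + [f"alpha_mu[{c}]" for c in (session_names if spec.session_wise else ("all",))]
        + ["kappa"]
        + [f"theta[{sid}]" for sid in subject_ids]
    )
    n_kept = mcmc.n_iter - mcmc.n_burnin
    if n_kept <= 0:
        raise ValueError("n_iter must exceed n_burnin")
    draws = {p: np.empty((mcmc.n_chains, n_kept)) for p in param_names}
    deviance = np.empty((mcmc.n_chains, n_kept))

    root = np.random.SeedSequence(mcmc.seed)
    for chain, chain_ss in enumerate(root.spawn(mcmc.n_chains)):
        rng = np.random.default_rng(chain_ss)
        alpha_mu = rng.beta(a_hyp, b_hyp, size=n_acol)
        kappa = rng.gamma(k_shape, 1.0 / k_rate)
        theta = rng.gamma(t_shape, 1.0 / t_rate, size=n_subj)
        alpha = np.clip(
            rng.beta(alpha_mu * kappa, (1 - alpha_mu) * kappa, size=(n_subj, n_acol)),
            1e-4,
            1 - 1e-4,
        )
        lik = np.zeros((n_subj, n_sess))
        state = _State(alpha, alpha_mu, kappa, theta, lik)
        for j in range(n_subj):
            for c in range(n_sess):
                a_jc = alpha[j, c if spec.session_wise else 0]
                lik[j, c] = subj_ll(state, j, c, a_jc, theta[j])

        # one adaptive step size per scalar parameter
        scales = {
            "alpha": np.full((n_subj, n_acol), 0.5),
            "alpha_mu": np.full(n_acol, 0.3),
            "kappa": 0.4,
            "theta": np.full(n_subj, 0.3),
        }

        def adapt(scale, accepted, it, target=0.40):
            if it >= mcmc.n_burnin:
                return scale
            step = min(0.2, 2.0 / np.sqrt(it + 1))
            return scale * np.exp(step * ((1.0 if accepted else 0.0) - target))

        for it in range(mcmc.n_iter):
            # --- subject/session learning rates ------------------------------
            for j in range(n_subj):
                for col in range(n_acol):
                    a_cur = state.alpha[j, col]
                    z = _logit(a_cur) + rng.normal(0, scales["alpha"][j, col])
                    a_new = _expit(z)
                    mu = state.alpha_mu[col]
                    pa, pb = mu * state.kappa, (1 - mu) * state.kappa
                    # prior + logit-scale Jacobian
                    lp_cur = _log_beta_pdf(a_cur, pa, pb) + np.log(a_cur * (1 - a_cur))
                    lp_new = _log_beta_pdf(a_new, pa, pb) + np.log(a_new * (1 - a_new))
                    sess_cols = [col] if spec.session_wise else list(range(n_sess))
                    ll_cur = sum(state.lik[j, c] for c in sess_cols)
                    ll_new_each = [
                        subj_ll(state, j, c, a_new, state.theta[j]) for c in sess_cols
                    ]
                    log_r = (lp_new + sum(ll_new_each)) - (lp_cur + ll_cur)
                    accepted = np.log(rng.uniform()) < log_r
                    if accepted:
                        state.alpha[j, col] = a_new
                        for c, v in zip(sess_cols, ll_new_each):
                            state.lik[j, c] = v
                    scales["alpha"][j, col] = adapt(
                        scales["alpha"][j, col], accepted, it
                    )
            # --- hyper means -------------------------------------------------
            for col in range(n_acol):
                mu_cur = state.alpha_mu[col]
                z = _logit(mu_cur) + rng.normal(0, scales["alpha_mu"][col])
                mu_new = _expit(z)

                def hyper_lp(mu):
                    pa, pb = mu * state.kappa, (1 - mu) * state.kappa
                    return (
                        _log_beta_pdf(mu, a_hyp, b_hyp)
                        + np.log(mu * (1 - mu))
                        + _log_beta_pdf(state.alpha[:, col], pa, pb).sum()
                    )

                accepted = np.log(rng.uniform()) < hyper_lp(mu_new) - hyper_lp(mu_cur)
                if accepted:
                    state.alpha_mu[col] = mu_new
                scales["alpha_mu"][col] = adapt(scales["alpha_mu"][col], accepted, it)
            # --- kappa -------------------------------------------------------
            k_cur = state.kappa
            k_new = np.exp(np.log(k_cur) + rng.normal(0, scales["kappa"]))

            def kappa_lp(k):
                pa = state.alpha_mu * k
                pb = (1 - state.alpha_mu) * k
                return (
                    _log_gamma_pdf(k, k_shape, k_rate)
                    + np.log(k)  # log-scale Jacobian
                    + sum(
                        _log_beta_pdf(state.alpha[:, col], pa[col], pb[col]).sum()
                        for col in range(n_acol)
                    )
                )

            accepted = np.log(rng.uniform()) < kappa_lp(k_new) - kappa_lp(k_cur)
            if accepted:
                state.kappa = k_new
            scales["kappa"] = adapt(scales["kappa"], accepted, it)
            # --- inverse temperatures ---------------------------------------
            for j in range(n_subj):
                t_cur = state.theta[j]
                t_new = np.exp(np.log(t_cur) + rng.normal(0, scales["theta"][j]))
                lp_cur = _log_gamma_pdf(t_cur, t_shape, t_rate) + np.log(t_cur)
                lp_new = _log_gamma_pdf(t_new, t_shape, t_rate) + np.log(t_new)
                ll_new_each = [
                    subj_ll(
                        state, j, c,
                        state.alpha[j, c if spec.session_wise else 0], t_new,
                    )
                    for c in range(n_sess)
                ]
                log_r = (lp_new + sum(ll_new_each)) - (lp_cur + state.lik[j].sum())
                accepted = np.log(rng.uniform()) < log_r
                if accepted:
                    state.theta[j] = t_new
                    state.lik[j] = ll_new_each
                scales["theta"][j] = adapt(scales["theta"][j], accepted, it)

            if it >= mcmc.n_burnin:
                k = it - mcmc.n_burnin
                pos = 0
                for j in range(n_subj):
                    for col in range(n_acol):
                        draws[param_names[pos]][chain, k] = state.alpha[j, col]
                        pos += 1
                for col in range(n_acol):
                    draws[param_names[pos]][chain, k] = state.alpha_mu[col]
                    pos += 1
                draws["kappa"][chain, k] = state.kappa
                pos += 1
                for j in range(n_subj):
                    draws[param_names[pos]][chain, k] = state.theta[j]
                    pos += 1
                deviance[chain, k] = -2.0 * state.lik.sum()

    return PosteriorSamples(
        draws, deviance, mcmc, spec, session_names, subject_ids
    )


# ---------------------------------------------------------------------------
# diagnostics and summaries


def rhat(samples: PosteriorSamples) -> dict[str, float]:
    """Split rank-normalized R-hat per parameter (requires >= 2 chains)."""
    first = next(iter(samples.draws.values()))
    if first.shape[0] < 2:
        raise ValueError("R-hat requires at least two chains")
    return {
        name: float(az.rhat(az.convert_to_dataset(arr[None] if arr.ndim == 1 else arr))["x"])
        for name, arr in samples.draws.items()
    }


def map_estimate(
    samples: PosteriorSamples | np.ndarray,
    parameter: str | None = None,
    bounded01: bool | None = None,
    grid_size: int = 512,
) -> float:
    """Posterior mode via a kernel density estimate over pooled draws.

    For parameters supported on (0, 1) (learning rates and hyper means) the
    KDE uses boundary reflection so the mode is not biased away from the
    edges; positive parameters are reflected at zero.
    """
    if isinstance(samples, PosteriorSamples):
        if parameter is None:
            raise ValueError("parameter name required")
        x = samples.pooled(parameter)
        if bounded01 is None:
            bounded01 = parameter.startswith("alpha")
    else:
        x = np.asarray(samples, float).reshape(-1)
        bounded01 = bool(bounded01)
    if x.size < 100:
        raise ValueError(f"too few draws ({x.size}) for a stable MAP estimate")
    if np.ptp(x) == 0:
        return float(x[0])
    if bounded01:
        data = np.concatenate([x, -x, 2.0 - x])
        grid = np.linspace(0.0, 1.0, grid_size)
    else:
        data = np.concatenate([x, -x]) if x.min() >= 0 else x
        grid = np.linspace(x.min(), x.max(), grid_size)
    kde = gaussian_kde(data)
    return float(grid[np.argmax(kde(grid))])


def dic(
    samples: PosteriorSamples, cohort: list[SubjectData]
) -> dict[str, float]:
    """Deviance information criterion.

    Uses the classic effective-parameter count pD = mean(D) - D(posterior
    mean); DIC = mean(D) + pD.  Absolute values depend on this variant, so
    comparisons should be made between models fit with the same routine.
    """
    spec = samples.spec
    session_names = samples.session_names
    d_bar = float(samples.deviance.mean())
    liks = {
        (s.subject, name): _SessionLik(s.sessions[name].reset_index(drop=True))
        for s in cohort
        for name in session_names
    }
    d_hat = 0.0
    for s in cohort:
        theta_bar = float(samples.pooled(f"theta[{s.subject}]").mean())
        for name in session_names:
            col = name if spec.session_wise else "all"
            a_bar = float(samples.pooled(f"alpha[{s.subject},{col}]").mean())
            d_hat += -2.0 * liks[(s.subject, name)].loglik(a_bar, theta_bar)
    p_d = d_bar - d_hat
    return {"dic": d_bar + p_d, "d_bar": d_bar, "d_hat": d_hat, "p_d": p_d}


def summarize_fit(
    samples: PosteriorSamples, cohort: list[SubjectData] | None = None
) -> FitSummary:
    """Convergence check, MAP estimates and (when a cohort is given) DIC."""
    r = rhat(samples)
    warnings = [
        f"R-hat {v:.3f} >= {RHAT_THRESHOLD} for {k}"
        for k, v in r.items()
        if v >= RHAT_THRESHOLD
    ]
    maps = {k: map_estimate(samples, k) for k in samples.draws}
    d = dic(samples, cohort)["dic"] if cohort is not None else None
    return FitSummary(r, maps, d, converged=not warnings, warnings=warnings)


def posterior_predictive(
    map_params: dict[str, dict[str, float]],
    task_config,
    n_sim: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Forward-simulate accuracy-by-position at per-subject MAP parameters.

    ``map_params`` maps subject id -> {"alpha": ..., "theta": ...}.  Each of
    the ``n_sim`` simulations uses a fresh schedule, giving the predictive
    distribution of accuracy at rev-1 / rev / rev+1 / rev+2 to overlay on
    observed data.
    """
    from .model import AgentParams, _position_means, simulate_agent
    from .task import TaskConfig, generate_schedule

    rows = []
    ss = np.random.SeedSequence(seed)
    for sid, pars in map_params.items():
        for sim, child in enumerate(ss.spawn(n_sim)):
            cfg_seed = int(child.generate_state(1)[0] % (2**31))
            cfg = TaskConfig(
                n_runs=task_config.n_runs,
                n_cues=task_config.n_cues,
                n_odors=task_config.n_odors,
                reversals_per_cue_per_run=task_config.reversals_per_cue_per_run,
                segment_length_range=task_config.segment_length_range,
                trials_per_run=task_config.trials_per_run,
                seed=cfg_seed,
            )
            beh = simulate_agent(
                generate_schedule(cfg),
                AgentParams(pars["alpha"], pars["theta"]),
                np.random.default_rng(child),
            )
            acc = _position_means(beh, "correct")
            rows.append({"subject": sid, "sim": sim, **acc})
    return pd.DataFrame(rows)
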