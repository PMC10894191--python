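# Methods

## The scientific problem

When a cue predicts a specific reward (say, a particular food odor) and the
reward is swapped for an equally valued alternative, nothing about *value*
changes — only the expected *identity* of the outcome is violated. revlearn
implements the computational machinery used to study this kind of identity
learning: a trans-reinforcer reversal task, a vector delta-rule model of
identity expectations, hierarchical Bayesian estimation of its learning
rate, and the two fMRI statistics used to read expectations and their
perturbation out of voxel data — voxel-wise global connectedness and the
ΔS multivoxel similarity statistic. Everything runs on synthetic data
produced by the package's own generators, so every analysis path can be
validated against planted ground truth.

## Task model

A session has `n_runs = 3` runs of `trials_per_run = 64` trials. Two visual
cues are each deterministically paired with one of three odors; within each
run every cue's pairing reverses `reversals_per_cue_per_run = 6` times
(12 reversals per run, 36 per session). Between reversals a cue keeps its
odor for 3–5 trials. Both constraints are satisfied by rejection-sampling
seven segment lengths i.i.d. uniform on {3, 4, 5} until they sum to 32,
which makes the draw uniform over all feasible compositions. The two cues'
32-trial sequences are interleaved by a uniformly shuffled cue order,
preserving within-cue order. At a reversal the new odor is drawn uniformly
from the other two; the two cues evolve independently and may transiently
share an odor. Associations persist across run boundaries (run starts are
not reversals), so the 3–5-trial gap guarantee holds within runs; a
cross-run gap spans two segments. Trial timing is 1 s cue, 3 s response
window, 4 s fixation, 2 s odor, ITI uniform on [2, 4] s; odor onset trails
cue onset by 8 s.

Trials are labeled relative to each cue's reversals: `rev`, `rev+1`,
`rev+2`, `rev-1`, else `other`. With 3-trial segments a trial can be both
`rev+2` of one reversal and `rev-1` of the next; `rev-1` wins, because the
rev-1 → rev+1 accuracy change is the primary behavioral contrast and its
trial set must be complete. The reversal label itself always wins (it can
never actually collide given the 3-trial minimum gap).

## Identity learning model

Per cue the agent holds an expectation-strength vector V over odors,
initialized uniform (1/3 each; the symmetric choice that keeps V on the
probability simplex). After each trial, with I the one-hot delivered odor:

    δ = I − V,    V ← V + α δ,    e = Σᵢ |δᵢ|

α ∈ [0, 1] is the learning rate; e ∈ [0, 2] is the scalar identity
prediction error (iPE), maximal when a fully expected identity is replaced.
Choices are softmax over V with inverse temperature θ ≥ 0 (log-sum-exp
stabilized). Updates use the *delivered* odor regardless of the choice —
outcome delivery is choice-independent in this task. V carries across runs
within a session and resets between sessions. Model simulations use a fixed
θ = 5; for display the mean iPE across the four rev positions is min–max
normalized within each α.

The model similarity curves treat the cue-time V vectors as trial patterns
and apply exactly the ΔS machinery below (`constant_policy="identical_one"`
so the frozen-belief α = 0 limit correlates identical constant vectors at 1
instead of propagating NaN).

## Hierarchical Bayesian fitting

Learning rates get a hierarchical Beta structure in mean/sample-size
parameterization: α_{j,c} ~ Beta(α_μc·κ, (1−α_μc)·κ) for subject j and
session c, with α_μc ~ Beta(8, 2) (an informative prior: the task is easy,
so rates should skew high), κ ~ Gamma(shape 1, rate 0.1), and one
θ_j ~ Gamma(shape 5, rate 1) per subject shared across sessions (the
minimal reading of a single θ prior; a hierarchical θ would add unneeded
freedom for 64-trial sessions). The baseline ("fixed") model is identical
but ties α_j across sessions under a single hyper mean.

The session likelihood is the product of softmax choice probabilities along
the V trajectory propagated from the delivered-odor sequence. Trials marked
invalid contribute no likelihood but still drive updates. Because outcomes
are one-hot, the trajectory has the closed form
V_k = g^k V₀ + α Σ_{j<k} g^(k−1−j) I_j with g = 1−α, evaluated as a masked
Toeplitz weighting of the delivered-odor indicator matrix — no sequential
loop, which makes MCMC on a laptop-scale budget practical. The vectorized
evaluator is pinned to a trial-by-trial oracle at 1e−10 in the tests.

Sampling is adaptive Metropolis-within-Gibbs: logit-scale random walks for
α and α_μ, log-scale for κ and θ, with per-parameter step sizes tuned
toward ≈40% acceptance during burn-in (Robbins–Monro) and frozen
afterwards. Default settings are 3 chains × 5000 iterations with 2000
burn-in, retaining exactly chains × (iterations − burn-in) = 9000 draws.
Convergence is checked with the rank-normalized split R̂ (arviz), flagged
at 1.1. MAP estimates are modes of a Gaussian KDE over pooled draws, with
boundary reflection on (0, 1) for rate parameters (and at 0 for positive
parameters) so modes near the edges are not biased inward. DIC uses the
classic effective-parameter count pD = mean(D) − D(posterior mean); since
packages differ in this variant, only DIC *orderings* between models fit by
this routine are meaningful, never absolute values. Posterior-predictive
checks forward-simulate at per-subject MAP parameters on fresh schedules.

## Behavioral analysis

Filtering marks (never deletes) trials: non-responses (> 3 s) and RTs
beyond ±3 SD of the subject's mean are invalid; the RT statistics are
always computed over all responded trials of the full table, which makes
the filter exactly idempotent. Subjects below 80% odor-identification
accuracy are flagged for exclusion. Accuracy is summarized at the four
rev-relative positions over valid trials only (empty cells give NaN, not
zero); on reversal trials "correct" means predicting the newly delivered
odor, so chance-level accuracy is the expected signature. The session
contrast is per-subject Δ = acc(rev+1) − acc(rev−1), compared between
sessions by a one-sided paired t-test (the directional hypothesis is that
perturbation blunts post-reversal recovery); learning-rate differences are
logit-transformed before correlating (Spearman) with behavioral effects.

## Nuisance filtering and global connectedness

The filter matrix F contains, per data segment: mean gray/white/CSF
signals computed from the data, a linear drift, six motion parameters and
two within-volume motion proxies each expanded with derivative, square and
squared derivative, four sniff regressors (airflow, volume, and squares),
optional spike dummies, and a constant. All columns except the constant are
z-scored within the segment. Residuals R = B − F(F'F)⁻¹F'B are an exact
projection (F'R ≈ 0, idempotent; both tested).

Global connectedness of a gray-matter voxel is the mean of |atanh(r)| over
its Pearson correlations with every other gray voxel. Correlations are
clipped to ±(1 − 1e−7) before the Fisher transform (planted perfect copies
would otherwise produce infinities). Voxels with constant residuals get a
missing value and are dropped from the reference set, with a count.
An exclusion mask (e.g. the LPFC control) removes voxels from the
*reference* set only — coverage of the output never changes. Time-resolved
connectedness splits each run into 2 bins (first bin takes any odd volume)
and refits the whole filter within each segment — drift and tissue means
are segment-specific; this choice is the conservative one when the signal
of interest is itself nonstationary, and it is isolated in one function if
the alternative (run-level residuals, then binning) is wanted. Session
comparisons use one-sided Wilcoxon signed-rank tests per bin. Stimulation-
coordinate selection correlates the seed-ROI mean time course (after
confound removal) with each search-ROI voxel and returns the argmax,
breaking exact ties by the lowest flat index.

## GLM and single-trial patterns

The canonical HRF is the standard double gamma (peak delay 6 s, undershoot
delay 16 s, unit dispersions, undershoot ratio 1/6), 32 s long, peak-
normalized; it matches the SPM-style reference kernel in nilearn to
r > 0.999 (tested). Regressors are indicator trains at event onsets,
convolved at dt = 0.1 s and sampled at volume times; runs are concatenated
with one constant per run. No temporal derivatives and no autocorrelation
whitening are applied — the synthetic noise is AR(1) and this approximation
is shared by estimator and generator. The outcome contrast is
rev − mean(rev−1, rev+1, rev+2); group inference uses sign-flip
max-statistic permutation (or Bonferroni), not random-field theory.
Least-squares-separate betas fit one GLM per cue event: that event, all
other cue events pooled, the trial's outcome, all other outcomes pooled,
plus nuisance columns; the first beta is kept. Pooling other trials leaves
their amplitude spread unexplained, so even noiseless recovery carries a
structural ~1e−5 residue; in the non-overlap limit LSS equals the
per-trial-regressor GLM to 1e−3 (both tested).

## Pattern similarity (ΔS)

For every reversal with same-cue rev−1 and rev+1 neighbors in the same run,
S_same = atanh(r(rev, rev−1)) and S_different = atanh(r(rev, rev+1)) are
computed over the chosen voxels and averaged across reversals;
ΔS = S_same − S_different. All trials enter irrespective of behavioral
response. Reversals whose neighbors straddle a run boundary are skipped and
counted; zero-variance patterns skip the reversal (voxel data) or are
defined as r = 1 when identical (model V vectors). The searchlight maps ΔS
over spheres of radius 2 voxels onto center voxels, skipping spheres with
fewer than 3 voxels (radius 0 therefore yields an all-missing map). Session
comparisons are one-sided Wilcoxon tests of ΔS_sham > 0, ΔS_cTBS > 0 and
ΔS_sham > ΔS_cTBS. Note that with high learning rates the model-curve
S_same approaches atanh of the clip bound (≈ 8.4) because consecutive V
vectors become numerically identical; orderings, not magnitudes, are the
meaningful output there.

## Synthetic data generator

The generator produces the study's three data streams with planted ground
truth.

**Behavior.** Default cohort: 31 subjects, session hyper means 0.8 (sham)
and 0.55 (cTBS) with κ = 12 — chosen so the sham posterior concentrates
high while cTBS rates spread visibly lower — and θ_j drawn from its own
Gamma(5, 1) prior. Each session gets a fresh schedule; truth tables are
retained for recovery tests.

**Voxels.** A 12×12×8 box phantom (TR 2 s, 430 volumes/run, 3 runs) with
rectangular tissue boxes (white and CSF strips; the rest gray) and four
gray ROIs defined by fractional grid coordinates so configs scale: a hub
("OFC") and a coupled second region ("LPFC") that both load on a shared
latent AR(1) signal (loading 1.0 × per-voxel U(0.8, 1.2)); an identity-
coding region whose cue responses are a fixed ±1 per-odor template weighted
by the agent's current V (amplitude 1.0); and an iPE region whose outcome
responses scale with e (amplitude 1.0). Background is AR(1) noise
(coefficient 0.3, SD 1). The "cTBS" session multiplies the latent loading
by 0.5 during the first two half-run bins and restores it afterwards,
mirroring a transient perturbation with recovery. Power simulations in the
tests and acceptance script use a 10×10×6 grid with 150 volumes/run and
16-trial runs — sizes chosen so a 31-subject, multi-replicate simulation
completes in minutes while the planted effects remain detectable; the
methods are size-agnostic.

**Sniffing.** Synthetic nasal airflow (slow respiration sinusoid plus
noise, half-sine inhalation bumps at odor onsets) is generated at 1 kHz by
default (100 Hz inside the voxel simulator; the chain is rate-invariant
above 10 Hz) and preprocessed exactly as a real trace would be: 250 ms
moving-average smoothing, block down-sampling to 10 Hz, 50 s-cutoff
high-pass (2nd-order Butterworth, zero-phase), z-normalization, and a final
down-sample to one sample per TR. Sniff volume is the per-TR integral of
the smoothed (pre-high-pass) airflow so a single inhalation's volume equals
its area.

What the generator does *not* emulate: brain geometry, spatially smooth
noise, physiological noise beyond AR(1) + confounds, head motion coupled to
the data (motion regressors are independent traces), susceptibility
artifacts, or scanner drift nonlinearity. Passing tests therefore show that
the *estimators* are correct and powered under the stated noise model, not
that real acquisitions would yield the same effect sizes.

## Numerical choices

- Correlation clipping at 1 − 1e−7 before atanh, everywhere.
- Softmax shifted by the max before exponentiation.
- MCMC proposals clipped away from {0, 1} on the probability scale.
- Segment-length rejection sampling capped at 1e5 draws (a configuration
  error beyond that).
- Rank checks name the collinear columns before any lstsq on a deficient
  design; spike dummies are deduplicated.
- Odd-length runs give the extra volume to the first half-run bin.
- Tissue classes absent from a segment contribute no filter column.

## Problem sizes

Defaults follow the study conditions (3 × 64-trial runs, 430 volumes at
TR 2 s, 31 subjects, 3 × 5000/2000 MCMC). The test suite and acceptance
script run cohort-level Monte-Carlo at reduced sizes — 5–20 subjects for
fits, 8 subjects × 20 replicates for DIC model selection (2 × 700/250
chains), 31 subjects × 4–5 replicates on the reduced phantom for the
connectedness power runs — chosen as the smallest sizes at which the
qualitative claims are stable across seeds.

## Known limitations

- The sampler is random-walk Metropolis within Gibbs: adequate for these
  posteriors (dozens of weakly coupled parameters) but slower-mixing than
  gradient-based samplers; R̂ should always be inspected.
- DIC is computed with the Spiegelhalter pD; absolute values are not
  comparable across packages.
- LSS betas carry the structural pooled-regressor residue described above.
- The ΔS model curves saturate at the clip bound for high α.
- No slice timing, motion correction, normalization or smoothing is
  implemented; data are assumed to be in analysis space already.
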