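# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `rewardbias`.

## Task model

The simulated session crosses 2 reward contexts with 7 signed coherence
levels (0, ±0.04, ±0.12, ±0.64; a proportion of coherently moving dots,
positive = upward) at 20 repetitions per cell: 280 trials split evenly into
5 runs of 56, every (context, coherence) cell appearing exactly 4 times per
run. Trial order within a run is a seeded uniform permutation of this
balanced multiset. We deliberately use exact counterbalancing rather than
i.i.d. context draws: it preserves the equal-exposure property that rules
out frequency-driven bias, and the permutation leaves no usable serial
structure in the context sequence (its lag-1 autocorrelation is near zero;
tested). The correct direction of a 0%-coherence trial is a fair Bernoulli
draw per trial, so equality holds in expectation over the session.

Event timing per trial: context cue 1.0 s, stimulus 0.2 s, response window
0.8 s from stimulus onset, feedback 1.5 s. Inter-trial intervals are drawn
from an exponential distribution shifted to 2.7 s and truncated at 12.7 s
whose rate is solved numerically (Brent's method, cached per configuration)
so that the truncated mean equals 4.0 s; sampling uses
`scipy.stats.truncexpon`. A truncated exponential on [2.7, 12.7] can only
realize means in (2.7, 7.7), and the solver rejects targets outside that
interval.

Payoffs: a correct choice in the context's high-reward direction earns 2
points, a correct choice in the other direction 1 point, an incorrect or
omitted response 0. The two contexts favor opposite directions (an enforced
invariant). The point magnitudes are a design default of this package —
only their asymmetry matters for bias acquisition — and are fully
configurable, including the context-to-direction mapping.

A practice-session variant (9 coherence levels 0, ±0.06, ±0.12, ±0.64,
±0.80; 60 repetitions; six 90-trial blocks; no contexts or payoffs) is
provided for completeness, e.g. to estimate a pre-task bias.

## Choice and learning models

The probability of an upward choice is logistic in the learned value
difference and the stimulus:

    P_t(up) = 1 / (1 + exp(−[β₀ (Q_t(up) − Q_t(down)) + β₁ S_t])).

The sign convention is chosen so that P(up) increases with upward coherence
and with the value advantage of "up"; fitted β₁ are then positive for any
competent observer and the psychometric function rises.

Two delta-rule learners supply the Q values: the context-dependent rule
keeps a Q pair per reward context and updates only the (context, chosen
direction) cell with the contextual prediction error δ′_t = r_t −
Q_t(m_t|c_t), scaled by α′; the context-free rule keeps one pair and
ignores the context. The prediction error is reported unscaled (before
multiplication by the learning rate). With a single context the two rules
coincide exactly (tested). Q values initialized inside the payoff range
stay inside it, because the delta rule forms convex combinations of Q and
r.

Q values default to zero at the start of the session. An optional
initializer maps a pre-task logit intercept b (e.g. from a practice-session
fit) into an initial value split ΔQ = b/β₀; no stronger assumption is made
because there is no canonical way to distribute an intercept across four Q
cells.

The per-trial *bias amount* is |Q(up|c_t) − Q(down|c_t)| evaluated before
the choice, and the *indecision point* is S\* = −β₀ ΔQ/β₁, the coherence at
which both options are equally likely. S\* is undefined at β₁ = 0 (raised
as an error) and may legitimately fall outside the tested coherence range.

## Estimation

Per participant, θ = (β₀, β₁, α) is estimated by minimizing the negative
log-likelihood −Σ_t log P_t(chosen) along the deterministic forward pass.
The forward pass is a scalar loop (each trial depends on all earlier
feedback) JIT-compiled with numba; a bit-identical pure-Python fallback is
used when numba is unavailable, and the two are cross-checked in the tests
against a naive per-trial oracle.

Optimization is Nelder–Mead simplex from 10 seeded random starts (one
anchored at β₀ = 1, β₁ = 4, α = 0.05), with α passed through a logistic so
the search is unconstrained while α stays in [0, 1]; βs are unconstrained.
Convergence tolerances are 1e-8 on the objective and 1e-6 on the simplex.
Choice probabilities are clipped to [1e-12, 1 − 1e-12] inside likelihood
evaluation only — never in simulation. Standard errors come from the
inverse numerical Hessian at the optimum and are reported as NaN when the
Hessian is not positive definite (typically α at a boundary or a
deterministic-choice separation, where the ML estimate diverges).

Group model comparison uses AIC = Σₙ (2·NLL_n + 2k) with k = 3 per model;
per-participant AICs give "fits better for N of M participants" counts,
with |ΔAIC| < 1e-6 counted as unresolved ties rather than assigned to a
model (no principled tie-break exists at optimizer noise level).

### Identifiability of the learning rate

A caveat established by this package's own recovery experiments: at the
default study scale (280 trials, 2/1/0 payoffs, generative β₀ ≈ 0.8,
α ≈ 0.02), the likelihood is nearly flat along a β₀–α ridge — the profile
NLL changes by a fraction of a nat as α varies over more than an order of
magnitude, because β₀ can rescale to compensate for the size of the learned
value difference. Single-session estimates of α (and to a lesser degree β₀)
are therefore highly dispersed even though the *fitted bias trajectory* and
the *model ranking* are stable: β₀ and β₁ cohort medians recover within
tens of percent, and the generating learning rule wins the group AIC in
virtually every replicate cohort. Scientific conclusions should rest on
model comparison and on trajectory-level quantities, not on point estimates
of α from one session.

## Hierarchical logistic regression

Run-by-run changes of discrimination and bias are tested with a
random-intercept logistic regression: choice ~ coherence + context +
C(run) + context:C(run) + coherence:C(run), intercept random across
participants. Coherence enters as a single signed numeric covariate
(matching its role in the choice rule); run is a 5-level treatment-coded
factor, so each interaction carries 4 degrees of freedom. Only a random
intercept is used — no random slopes.

The marginal likelihood integrates the intercept out by adaptive
Gauss–Hermite quadrature (default 15 nodes): nodes are recentred at each
participant's conditional mode (found by Newton's method) and rescaled by
the conditional curvature. Quadrature was chosen over penalized
quasi-likelihood precisely so that deviances are comparable across nested
fits and χ² likelihood-ratio tests are valid. The quadrature agrees with
direct numerical integration to ~1e-8 and, in the σ → 0 limit, with the
pooled ordinary logistic deviance (both tested); on simulated cohorts the
fit matches lme4's `glmer` (nAGQ = 15) to the third decimal in σ and in the
LRT statistic. Optimization is BFGS on (β, log σ) starting from the pooled
logistic estimate; complete separation of the pooled fit is raised as an
error since the MLE does not exist. Clusters of equal size are evaluated on
a vectorized fast path that is numerically identical to the general
per-cluster loop (tested).

The LRT statistic is deviance(reduced) − deviance(full), clipped at zero
(optimizer noise can make it infinitesimally negative), referred to the χ²
upper tail with df = the fixed-effect count difference. Calibration checks
use simulated null cohorts of 10 participants × 140 trials: large enough
that the asymptotic χ²(4) reference holds (at 6 × 70 the test is visibly
anticonservative — a property of small-sample LRTs, reproduced by lme4 on
the same data, not an implementation artifact).

## Diagnostics

Psychometric summaries report observed P(up) per (context, run, coherence)
cell — 70 cells, 4 trials per cell per participant under the default
design — optionally paired with the fitted model's mean predicted
probability over the same cells; group curves average across participants
with s.e.m. Residual diagnostics compute the standard sample ACF
(mean-centered, normalized by lag-0 autocovariance; `statsmodels.tsa.acf`)
of per-trial response residuals choice − P̂(up), per participant, averaged
with equal weights, with the ±1.96/√T white-noise band; max lag defaults
to 20 (a choice — long enough to span a third of a run, short relative to
T = 280). Indecision-point trajectories evaluate S\* for both contexts at
every trial's pre-choice values, so the two context curves are defined on
every trial, and summarize them as group mean ± s.e.m. with run boundaries;
a single-participant "cohort" is flagged and its band omitted.

## fMRI regressors

Parametric modulators attach model quantities to event windows: |S_t| to
the stimulus (0.2 s), the bias amount to cue onset → stimulus offset
(1.2 s; "trial onset" is taken as cue onset), and prediction errors —
signed contextual δ′, signed context-free δ, or unsigned |δ′| as a surprise
control — to the feedback period (1.5 s). Weights are mean-centered within
run by default, matching per-run first-level GLMs; whole-session centering
is an option. Files follow the FSL three-column custom-timing convention
(onset, duration, weight; 6-decimal fixed format), one file per run per
regressor, plus an unmodulated trial-evoked boxcar (cue onset → feedback
offset) and, when reaction times are present in the data, a response
boxcar. Export is a pure function of (dataset, trajectory): identical
inputs produce byte-identical files. No HRF convolution, GLM estimation or
connectivity analysis is performed — those require imaging data.

## Synthetic data: what it does and does not emulate

Generative agents draw choices from the same logit rule they are fit with,
always respond, and earn rewards from the payoff table; schedules and
agents are seeded independently per participant. The generator reproduces
the task's design structure (balance, timing, payoff asymmetry) and the
learning dynamics of interest, but not: response omissions or lapses,
reaction times, session-to-session carryover (practice effects enter only
through optional Q initialization), context-cue misperception, or any
non-stationarity in the decision policy beyond the delta rule. Passing
recovery tests therefore certify the estimation machinery under the model's
own assumptions — they do not certify that real behavior follows the model;
that question is what the AIC comparison and residual-whiteness diagnostics
address on real data.

## Problem sizes used in validation

The test suite validates at the original study scale where it matters:
recovery experiments use 23 agents × 280 trials; model recovery uses 20
replicate cohorts per generating rule (5 optimizer starts per fit there,
which pilot runs showed gives fits indistinguishable from 10 starts); LRT
calibration uses 500 null cohorts of 10 × 140 trials; oracle checks
(likelihood loop, indecision bisection, quadrature integration) run at
small sizes where exhaustive reference computation is exact.
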