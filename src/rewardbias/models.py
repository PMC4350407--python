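"""Q-learning choice models for reward-biased perceptual decisions.

Two delta-rule learners share one logit choice rule.  On trial t the
probability of choosing upward motion (m1) is

    P_t(up) = 1 / (1 + exp(-[beta0 * (Q_t(m1) - Q_t(m0)) + beta1 * S_t]))

where S_t is the signed coherence (positive = upward) and the Q values are
the learned reward expectations of the two motion directions.  The
*context-dependent* learner keeps a separate Q pair per reward context and
updates only the (context, chosen-direction) cell,

    delta'_t = r_t - Q_t(m_t | c_t),   Q_{t+1}(m_t | c_t) += alpha' * delta'_t,

while the *context-free* learner keeps a single pair and ignores the context,

    delta_t = r_t - Q_t(m_t),          Q_{t+1}(m_t) += alpha * delta_t.

The value difference shifts the psychometric function horizontally; the
coherence at which both choices are equally likely (the indecision point) is
S* = -beta0 * (Q(m1) - Q(m0)) / beta1.

`RewardLearningModel` wraps a participant's trial table in a
statsmodels-style model object whose `fit` returns a
`RewardLearningResults` carrying the ML estimates, their standard errors,
AIC, and per-trial diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import norm

from . import task
from ._likelihood import nll_forward, prepare_arrays

CONTEXT_DEPENDENT = "context_dependent"
CONTEXT_FREE = "context_free"
MODEL_KINDS = (CONTEXT_DEPENDENT, CONTEXT_FREE)

#: Columns a behavioral dataset adds on top of the schedule columns.
BEHAVIOR_COLUMNS = task.TRIAL_COLUMNS + ["choice", "correct", "reward"]


class UndefinedIndecisionError(ZeroDivisionError):
    """beta1 = 0: no coherence can equalize the two choices."""


@dataclass(frozen=True)
class ModelParams:
    """Free parameters of a learning model.

    beta0 : weight of the Q-value difference (unitless)
    beta1 : weight of signed coherence (per unit signed proportion)
    alpha : learning rate in [0, 1]
    """

    beta0: float
    beta1: float
    alpha: float

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if not np.isfinite([self.beta0, self.beta1]).all():
            raise ValueError("beta0 and beta1 must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.alpha])

    names = ("beta0", "beta1", "alpha")


@dataclass
class ValueState:
    """Q values of the two motion directions, optionally per context.

    ``q`` is a (2, 2) array indexed [context, direction] with direction
    1 = up, 0 = down.  The context-free model uses row 0 only (row 1 is
    kept mirrored so either row can be read).
    """

    model_kind: str
    q: np.ndarray

    @classmethod
    def zeros(cls, model_kind: str) -> "ValueState":
        return cls(model_kind, np.zeros((2, 2)))

    @classmethod
    def from_values(cls, model_kind: str, q) -> "ValueState":
        arr = np.asarray(q, dtype=float)
        if arr.shape == (2,):  # direction pair shared across contexts
            arr = np.tile(arr, (2, 1))
        if arr.shape != (2, 2) or not np.isfinite(arr).all():
            raise ValueError("q must be a finite (2, 2) or (2,) array")
        return cls(model_kind, arr.copy())

    def _row(self, context: int) -> int:
        return int(context) if self.model_kind == CONTEXT_DEPENDENT else 0

    def q_pair(self, context: int) -> tuple[float, float]:
        """(Q(down), Q(up)) relevant for a trial in ``context``."""
        r = self._row(context)
        return float(self.q[r, 0]), float(self.q[r, 1])

    def q_diff(self, context: int) -> float:
        """Q(up) - Q(down) in ``context``."""
        q_down, q_up = self.q_pair(context)
        return q_up - q_down

    def copy(self) -> "ValueState":
        return ValueState(self.model_kind, self.q.copy())


# --------------------------------------------------------------------------
# Core rules
# --------------------------------------------------------------------------

def choice_probability(state: ValueState, context: int, coherence: float,
                       params: ModelParams) -> float:
    """P(choose up) from the logit choice rule.

    Strictly increasing in signed coherence and in the up-minus-down value
    difference.
    """
    dq = state.q_diff(context)
    x = params.beta0 * dq + params.beta1 * coherence
    if not np.isfinite(x):
        raise FloatingPointError("non-finite logit input")
    return float(expit(x))


def _update(state: ValueState, row: int, choice: int, reward: float,
            alpha: float) -> tuple[ValueState, float]:
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"learning rate must lie in [0, 1], got {alpha}")
    if choice not in (task.UP, task.DOWN):
        raise ValueError(f"invalid chosen direction {choice!r}")
    new = state.copy()
    delta = float(reward) - new.q[row, choice]
    new.q[row, choice] += alpha * delta
    if state.model_kind == CONTEXT_FREE:
        new.q[1] = new.q[0]  # keep mirror row consistent
    return new, delta


def update_context_dependent(state: ValueState, context: int, choice: int,
                             reward: float, alpha: float):
    """One delta-rule step of the context-dependent learner.

    Returns ``(new_state, rpe)`` where the reward prediction error is
    unscaled (before multiplication by the learning rate); only the
    (context, chosen direction) cell changes.
    """
    if state.model_kind != CONTEXT_DEPENDENT:
        raise ValueError("state is not context_dependent")
    return _update(state, int(context), choice, reward, alpha)


def update_context_free(state: ValueState, choice: int, reward: float,
                        alpha: float):
    """One delta-rule step of the context-free learner (context ignored)."""
    if state.model_kind != CONTEXT_FREE:
        raise ValueError("state is not context_free")
    return _update(state, 0, choice, reward, alpha)


def indecision_point(state: ValueState, context: int,
                     params: ModelParams) -> float:
    """Signed coherence S* at which P(up) = 0.5: S* = -beta0 * dQ / beta1.

    May lie outside the tested coherence range; undefined when beta1 = 0.
    """
    if params.beta1 == 0.0:
        raise UndefinedIndecisionError("indecision point undefined for beta1 = 0")
    return -params.beta0 * state.q_diff(context) / params.beta1


# --------------------------------------------------------------------------
# Trajectories and simulation
# --------------------------------------------------------------------------

def _resolve_q_init(model_kind: str, q_init) -> ValueState:
    if q_init is None:
        return ValueState.zeros(model_kind)
    if isinstance(q_init, ValueState):
        return q_init.copy()
    return ValueState.from_values(model_kind, q_init)


def initial_state_from_bias(model_kind: str, intercept: float,
                            beta0: float) -> ValueState:
    """Map a pre-task bias (logit intercept b, e.g. from a practice-session
    fit) into an initial value difference dQ = b / beta0, split symmetrically
    across the two directions in every context."""
    if beta0 == 0.0:
        raise ValueError("beta0 = 0 cannot absorb an intercept")
    dq = intercept / beta0
    return ValueState.from_values(model_kind, np.array([-dq / 2.0, dq / 2.0]))


def run_trajectory(data: pd.DataFrame, params: ModelParams, model_kind: str,
                   q_init=None) -> pd.DataFrame:
    """Deterministic forward pass over an observed/simulated dataset.

    Emits one row per trial with the pre-choice Q values, P(up), the reward
    prediction error of the chosen option, the trial-wise bias amount
    |Q(up) - Q(down)| in the trial's context, and the indecision points of
    both contexts evaluated at the pre-choice values.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    state = _resolve_q_init(model_kind, q_init)
    has_context = "context" in data.columns
    rows = []
    for t, tr in enumerate(data.itertuples(index=False)):
        c = int(tr.context) if has_context else 0
        choice = int(tr.choice)
        reward = float(tr.reward)
        if choice == task.NO_RESPONSE and reward != 0.0:
            raise ValueError(
                f"trial {t + 1}: missing choice with nonzero reward")
        p_up = choice_probability(state, c, float(tr.coherence), params)
        q_down, q_up = state.q_pair(c)
        rec = {
            "trial_index": int(tr.trial_index),
            "run": int(tr.run),
            "context": c if has_context else np.nan,
            "coherence": float(tr.coherence),
            "choice": choice,
            "q_down": q_down,
            "q_up": q_up,
            "p_up": p_up,
            "bias_amount": abs(q_up - q_down),
            "indecision_point": indecision_point(state, c, params),
            "ip_context0": indecision_point(state, 0, params),
            "ip_context1": indecision_point(state, 1, params),
        }
        if choice == task.NO_RESPONSE:
            rec["p_choice"] = np.nan
            rec["rpe"] = np.nan
        else:
            rec["p_choice"] = p_up if choice == task.UP else 1.0 - p_up
            if model_kind == CONTEXT_DEPENDENT:
                state, delta = update_context_dependent(
                    state, c, choice, reward, params.alpha)
            else:
                state, delta = update_context_free(
                    state, choice, reward, params.alpha)
            rec["rpe"] = delta
        rows.append(rec)
    return pd.DataFrame(rows)


def simulate_agent(schedule: task.TrialSchedule, params: ModelParams,
                   model_kind: str = CONTEXT_DEPENDENT, q_init=None,
                   seed: int | None = None,
                   participant_id: str | None = None) -> pd.DataFrame:
    """Generate choices from the model on a trial schedule.

    Each trial draws choice ~ Bernoulli(P(up)), earns the payoff-table
    reward, and applies the model's own update rule.  Fully reproducible
    given ``seed``.  The agent always responds.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    rng = np.random.default_rng(seed)
    state = _resolve_q_init(model_kind, q_init)
    config = schedule.config
    trials = schedule.trials
    n = len(trials)
    choices = np.empty(n, dtype=int)
    rewards = np.empty(n)
    context = trials["context"].to_numpy()
    coherence = trials["coherence"].to_numpy()
    correct_dir = trials["correct_direction"].to_numpy()
    u = rng.random(n)
    for t in range(n):
        c = int(context[t])
        p_up = choice_probability(state, c, float(coherence[t]), params)
        m = task.UP if u[t] < p_up else task.DOWN
        r = task.assign_outcome(c, int(correct_dir[t]), m, config)
        if model_kind == CONTEXT_DEPENDENT:
            state, _ = update_context_dependent(state, c, m, r, params.alpha)
        else:
            state, _ = update_context_free(state, m, r, params.alpha)
        choices[t] = m
        rewards[t] = r
    out = trials.copy()
    if participant_id is not None:
        out["participant_id"] = participant_id
    out["choice"] = choices
    out["correct"] = (choices == correct_dir).astype(int)
    out["reward"] = rewards
    return out


# --------------------------------------------------------------------------
# statsmodels-style model / results
# --------------------------------------------------------------------------

class RewardLearningModel:
    """Maximum-likelihood model of one participant's choice sequence.

    Parameters
    ----------
    data : DataFrame
        Trial table with at least ``context`` (for the context-dependent
        kind), ``coherence`` (signed proportion), ``choice`` (1 up / 0 down)
        and ``reward`` columns, ordered by trial.
    kind : {"context_dependent", "context_free"}
    q_init : optional initial Q values ((2,) pair or (2, 2) per context).
    """

    k_params = 3

    def __init__(self, data: pd.DataFrame, kind: str = CONTEXT_DEPENDENT,
                 q_init=None):
        if kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {kind!r}")
        if len(data) == 0:
            raise ValueError("dataset has zero trials")
        if (data["choice"] == task.NO_RESPONSE).all():
            raise ValueError("dataset has no observed choices")
        self.data = data.reset_index(drop=True)
        self.kind = kind
        self.q0 = _resolve_q_init(kind, q_init).q
        self._arrays = prepare_arrays(self.data)
        self.nobs = int((self.data["choice"] != task.NO_RESPONSE).sum())
        pid = data["participant_id"].iloc[0] if "participant_id" in data else None
        self.participant_id = pid

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, kind: str = CONTEXT_DEPENDENT,
                       q_init=None) -> "RewardLearningModel":
        return cls(data, kind=kind, q_init=q_init)

    # -- likelihood ---------------------------------------------------------

    def nloglike(self, params) -> float:
        """Negative log-likelihood (nats) of the observed choices."""
        if isinstance(params, ModelParams):
            b0, b1, a = params.beta0, params.beta1, params.alpha
        else:
            b0, b1, a = params
        context, choice, reward, coherence = self._arrays
        return float(nll_forward(context, choice, reward, coherence,
                                 float(b0), float(b1), float(a), self.q0,
                                 self.kind == CONTEXT_DEPENDENT))

    def loglike(self, params) -> float:
        return -self.nloglike(params)

    def _nll_unconstrained(self, z) -> float:
        # alpha passes through a logistic so the simplex search is unconstrained
        return self.nloglike((z[0], z[1], expit(z[2])))

    # -- fitting ------------------------------------------------------------

    def fit(self, n_starts: int = 10, seed: int | None = 0,
            start_params: ModelParams | None = None,
            xatol: float = 1e-6, fatol: float = 1e-8,
            maxiter: int = 4000) -> "RewardLearningResults":
        """Fit by Nelder-Mead simplex from multiple seeded random starts.

        alpha is constrained to [0, 1] through a logistic reparameterization;
        beta0 and beta1 are unconstrained.  Returns the best local optimum.
        """
        if self.nobs < 50:
            import warnings
            warnings.warn(f"only {self.nobs} trials; estimates may be "
                          "unstable", stacklevel=2)
        rng = np.random.default_rng(seed)
        starts = []
        if start_params is not None:
            starts.append(np.array([start_params.beta0, start_params.beta1,
                                    logit(np.clip(start_params.alpha,
                                                  1e-6, 1 - 1e-6))]))
        starts.append(np.array([1.0, 4.0, logit(0.05)]))
        while len(starts) < n_starts:
            starts.append(np.array([
                rng.uniform(0.0, 3.0),
                rng.uniform(0.5, 8.0),
                logit(rng.uniform(0.005, 0.5)),
            ]))
        best = None
        any_converged = False
        for z0 in starts[:max(n_starts, len(starts))]:
            res = minimize(self._nll_unconstrained, z0, method="Nelder-Mead",
                           options={"xatol": xatol, "fatol": fatol,
                                    "maxiter": maxiter})
            if not np.isfinite(res.fun):
                continue
            if best is None or res.fun < best.fun:
                best = res
                best_converged = bool(res.success)
            any_converged = any_converged or res.success
        if best is None:
            raise RuntimeError(
                f"all {len(starts)} optimization starts failed for "
                f"{self.kind} model (participant {self.participant_id})")
        params = ModelParams(best.x[0], best.x[1], float(expit(best.x[2])))
        return RewardLearningResults(self, params, float(best.fun),
                                     converged=best_converged)


class RewardLearningResults:
    """ML fit of a `RewardLearningModel`: estimates, uncertainty, diagnostics."""

    def __init__(self, model: RewardLearningModel, params: ModelParams,
                 nll: float, converged: bool = True):
        self.model = model
        self.params = params
        self.nll = nll
        self.converged = converged
        self.k = model.k_params
        self.nobs = model.nobs
        self._bse = None

    # -- information criteria ----------------------------------------------

    @property
    def llf(self) -> float:
        return -self.nll

    @property
    def aic(self) -> float:
        return 2.0 * self.nll + 2.0 * self.k

    # -- uncertainty --------------------------------------------------------

    @property
    def bse(self) -> np.ndarray:
        """Standard errors from the inverse numerical Hessian of the NLL.

        NaN where the Hessian is not positive definite (e.g. alpha at a
        boundary).
        """
        if self._bse is None:
            self._bse = self._hessian_bse()
        return self._bse

    def _hessian_bse(self) -> np.ndarray:
        theta = self.params.as_array()
        h = np.maximum(1e-4, 1e-4 * np.abs(theta))
        # keep alpha +/- step inside [0, 1]
        h[2] = min(h[2], 0.49 * max(self.params.alpha, 1e-3),
                   0.49 * max(1 - self.params.alpha, 1e-3)) or 1e-5
        n = len(theta)
        H = np.empty((n, n))
        f = self.model.nloglike
        f0 = f(theta)
        for i in range(n):
            for j in range(i, n):
                ei = np.zeros(n); ei[i] = h[i]
                ej = np.zeros(n); ej[j] = h[j]
                if i == j:
                    H[i, i] = (f(theta + ei) - 2 * f0 + f(theta - ei)) / h[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        f(theta + ei + ej) - f(theta + ei - ej)
                        - f(theta - ei + ej) + f(theta - ei - ej)
                    ) / (4 * h[i] * h[j])
        try:
            cov = np.linalg.inv(H)
            d = np.diag(cov)
            if np.any(d <= 0):
                raise np.linalg.LinAlgError
            return np.sqrt(d)
        except np.linalg.LinAlgError:
            return np.full(n, np.nan)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = norm.ppf(1 - alpha / 2)
        est = self.params.as_array()
        se = self.bse
        return pd.DataFrame({"lower": est - z * se, "upper": est + z * se},
                            index=ModelParams.names)

    # -- diagnostics --------------------------------------------------------

    def trajectory(self) -> pd.DataFrame:
        """Per-trial Q values, P(up), RPE, bias amount and indecision points."""
        return run_trajectory(self.model.data, self.params, self.model.kind,
                              q_init=self.model.q0)

    def predict(self) -> np.ndarray:
        """Fitted P(up) per trial."""
        return self.trajectory()["p_up"].to_numpy()

    def resid(self) -> np.ndarray:
        """Response residuals choice(0/1) - fitted P(up)."""
        traj = self.trajectory()
        ch = traj["choice"].to_numpy().astype(float)
        ch[ch == task.NO_RESPONSE] = np.nan
        return ch - traj["p_up"].to_numpy()

    def summary(self) -> str:
        lines = [
            "Reward-learning choice model"
            + (f" (participant {self.model.participant_id})"
               if self.model.participant_id else ""),
            f"  kind: {self.model.kind}   trials: {self.nobs}   "
            f"converged: {self.converged}",
            f"  NLL: {self.nll:.4f}   AIC: {self.aic:.4f}",
            f"  {'param':<8}{'estimate':>12}{'std err':>12}",
        ]
        for name, est, se in zip(ModelParams.names, self.params.as_array(),
                                 self.bse):
            lines.append(f"  {name:<8}{est:>12.4f}{se:>12.4f}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        p = self.params
        return (f"<RewardLearningResults {self.model.kind} beta0={p.beta0:.3f} "
                f"beta1={p.beta1:.3f} alpha={p.alpha:.4f} nll={self.nll:.2f}>")
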