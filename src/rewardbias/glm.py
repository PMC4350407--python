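"""Random-intercept (hierarchical) logistic regression of choices, with
likelihood-ratio tests between nested fixed-effect specifications.

The full model regresses choice (up = 1) on signed coherence, reward
context, scanning run (5-level factor), and the context-by-run and
coherence-by-run interactions, with a participant-level random intercept.
Dropping a 4-df interaction and comparing deviances with a chi-square test
asks whether bias (context-by-run) or discrimination (coherence-by-run)
changed over the experiment.

The marginal likelihood integrates the random intercept out by adaptive
Gauss-Hermite quadrature: for participant i with linear predictor
eta_t = x_t' beta and intercept u ~ N(0, sigma^2),

    L_i = int prod_t Bernoulli(y_t | logistic(eta_t + u)) phi(u; sigma) du

is approximated on quadrature nodes recentred at the conditional mode and
rescaled by the conditional curvature, so deviances are directly comparable
across nested fits (unlike penalized quasi-likelihood).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import patsy
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, log_expit, logsumexp
from scipy.stats import chi2

FULL_TERMS = ("coherence", "context", "C(run)", "context:C(run)",
              "coherence:C(run)")


class SeparationError(RuntimeError):
    """Complete separation: the logistic MLE does not exist."""


@dataclass(frozen=True)
class LogisticSpec:
    """Fixed-effect specification (random intercept per participant implied).

    ``terms`` are patsy term strings; the intercept is always included.
    """

    terms: tuple[str, ...] = FULL_TERMS
    response: str = "choice"
    groups: str = "participant_id"

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.terms) if self.terms else "1"
        return f"{self.response} ~ {rhs}"

    def drop(self, term: str) -> "LogisticSpec":
        """A reduced spec without ``term`` (must be present)."""
        if term not in self.terms:
            raise ValueError(f"term {term!r} not in spec")
        return replace(self, terms=tuple(t for t in self.terms if t != term))

    def is_nested_in(self, other: "LogisticSpec") -> bool:
        return (set(self.terms) <= set(other.terms)
                and self.response == other.response
                and self.groups == other.groups)


@dataclass
class LrtResult:
    """Chi-square likelihood-ratio test between nested fits."""

    chi_sq: float
    df: int
    p_value: float

    def __str__(self) -> str:
        return f"chi2({self.df}) = {self.chi_sq:.2f}, p = {self.p_value:.4g}"


class HierarchicalLogit:
    """Random-intercept logistic regression fit by quadrature ML.

    Parameters
    ----------
    data : DataFrame with the response, covariates and a participant column.
    spec : LogisticSpec (defaults to the full run-by-run model).
    n_nodes : Gauss-Hermite nodes (>= 15 recommended).
    adaptive : recenter/rescale nodes at each participant's conditional mode.
    """

    def __init__(self, data: pd.DataFrame, spec: LogisticSpec | None = None,
                 n_nodes: int = 15, adaptive: bool = True):
        self.spec = spec or LogisticSpec()
        self.n_nodes = int(n_nodes)
        self.adaptive = adaptive
        data = data.reset_index(drop=True)
        groups = data[self.spec.groups]
        if groups.nunique() < 2:
            raise ValueError("need >= 2 participants for a random intercept")
        y, X = patsy.dmatrices(self.spec.formula, data,
                               return_type="dataframe")
        self.exog_names = list(X.columns)
        self._y_all = np.ascontiguousarray(y.to_numpy().ravel())
        self._X_all = np.ascontiguousarray(X.to_numpy())
        if not set(np.unique(self._y_all)) <= {0.0, 1.0}:
            raise ValueError("response must be binary 0/1")
        codes, self.group_labels = pd.factorize(groups)
        self._splits = [np.flatnonzero(codes == g)
                        for g in range(len(self.group_labels))]
        sizes = {len(s) for s in self._splits}
        # equal cluster sizes admit a fully vectorized (P, T) fast path
        self._stack_idx = (np.vstack(self._splits) if len(sizes) == 1
                           else None)
        self.nobs = len(data)
        self.k_fe = self._X_all.shape[1]
        z, w = hermgauss(self.n_nodes)
        self._nodes = z
        self._logw = np.log(w) + z**2  # reweighted for exp(h) integrand

    # -- marginal likelihood ------------------------------------------------

    def loglike(self, params: np.ndarray) -> float:
        """Marginal log-likelihood at ``params`` = (beta..., log sigma)."""
        beta = params[:-1]
        sigma = float(np.exp(params[-1]))
        eta_all = self._X_all @ beta
        total = 0.0
        inv_s2 = 1.0 / max(sigma, 1e-10) ** 2
        log_norm = -0.5 * np.log(2 * np.pi) - np.log(max(sigma, 1e-10))
        if self._stack_idx is not None:
            return self._loglike_stacked(eta_all, sigma, inv_s2, log_norm)
        for idx in self._splits:
            eta = eta_all[idx]
            y = self._y_all[idx]
            sgn = 2.0 * y - 1.0
            if self.adaptive:
                u_hat = 0.0
                for _ in range(25):
                    p = expit(eta + u_hat)
                    g = (y - p).sum() - u_hat * inv_s2
                    hess = -(p * (1 - p)).sum() - inv_s2
                    step = g / hess
                    u_hat -= step
                    if abs(step) < 1e-10:
                        break
                tau = 1.0 / np.sqrt(-hess)
            else:
                u_hat, tau = 0.0, sigma
            u_k = u_hat + np.sqrt(2.0) * tau * self._nodes
            # joint log density at every node: Bernoulli loglik + prior
            hk = (log_expit(sgn[None, :] * (eta[None, :] + u_k[:, None]))
                  .sum(axis=1) + log_norm - 0.5 * u_k * u_k * inv_s2)
            total += (np.log(np.sqrt(2.0) * tau)
                      + logsumexp(self._logw + hk))
        return float(total)

    def _loglike_stacked(self, eta_all, sigma, inv_s2, log_norm) -> float:
        # identical math to the per-group loop, vectorized over participants
        eta = eta_all[self._stack_idx]          # (P, T)
        y = self._y_all[self._stack_idx]
        sgn = 2.0 * y - 1.0
        P = eta.shape[0]
        if self.adaptive:
            u_hat = np.zeros(P)
            hess = np.full(P, -inv_s2)
            for _ in range(25):
                p = expit(eta + u_hat[:, None])
                g = (y - p).sum(axis=1) - u_hat * inv_s2
                hess = -(p * (1 - p)).sum(axis=1) - inv_s2
                step = g / hess
                u_hat -= step
                if np.max(np.abs(step)) < 1e-10:
                    break
            tau = 1.0 / np.sqrt(-hess)
        else:
            u_hat, tau = np.zeros(P), np.full(P, sigma)
        u_k = u_hat[:, None] + np.sqrt(2.0) * tau[:, None] * self._nodes
        hk = (log_expit(sgn[:, None, :] * (eta[:, None, :]
                                           + u_k[:, :, None])).sum(axis=2)
              + log_norm - 0.5 * u_k * u_k * inv_s2)
        per = (np.log(np.sqrt(2.0) * tau)
               + logsumexp(self._logw[None, :] + hk, axis=1))
        return float(per.sum())

    def _start_params(self) -> np.ndarray:
        import statsmodels.api as sm
        try:
            with np.errstate(all="ignore"):
                pooled = sm.Logit(self._y_all, self._X_all).fit(
                    disp=0, maxiter=200)
            beta0 = pooled.params
            if not np.all(np.isfinite(beta0)) or np.max(np.abs(beta0)) > 50:
                raise SeparationError(
                    "complete or quasi-complete separation in the data")
        except np.linalg.LinAlgError as exc:
            raise SeparationError(str(exc)) from exc
        return np.concatenate([beta0, [np.log(0.5)]])

    def fit(self, start_params: np.ndarray | None = None,
            maxiter: int = 500, gtol: float = 1e-5,
            ) -> "HierarchicalLogitResults":
        """Maximize the quadrature marginal likelihood (BFGS)."""
        x0 = self._start_params() if start_params is None else start_params
        res = minimize(lambda p: -self.loglike(p), x0, method="BFGS",
                       options={"maxiter": maxiter, "gtol": gtol})
        return HierarchicalLogitResults(self, res.x, -res.fun,
                                        converged=bool(res.success),
                                        optimizer_message=res.message,
                                        hess_inv=res.hess_inv)


class HierarchicalLogitResults:
    """Fitted random-intercept logistic model."""

    def __init__(self, model: HierarchicalLogit, params: np.ndarray,
                 llf: float, converged: bool, optimizer_message: str = "",
                 hess_inv=None):
        self.model = model
        self._params_full = np.asarray(params)
        self.llf = float(llf)
        self.converged = converged
        self.optimizer_message = optimizer_message
        self._hess_inv = hess_inv

    @property
    def fe_params(self) -> pd.Series:
        return pd.Series(self._params_full[:-1], index=self.model.exog_names)

    @property
    def sigma_u(self) -> float:
        """Random-intercept standard deviation."""
        return float(np.exp(self._params_full[-1]))

    @property
    def deviance(self) -> float:
        return -2.0 * self.llf

    @property
    def df_model(self) -> int:
        """Number of fixed-effect parameters (incl. intercept)."""
        return self.model.k_fe

    @property
    def bse(self) -> pd.Series:
        if self._hess_inv is None:
            return pd.Series(np.nan, index=self.model.exog_names)
        se = np.sqrt(np.clip(np.diag(np.asarray(self._hess_inv)), 0, None))
        return pd.Series(se[:-1], index=self.model.exog_names)

    def summary(self) -> str:
        lines = [
            "Random-intercept logistic regression "
            f"({self.model.n_nodes}-node "
            f"{'adaptive ' if self.model.adaptive else ''}Gauss-Hermite)",
            f"  formula: {self.model.spec.formula}",
            f"  groups: {self.model.spec.groups} "
            f"({len(self.model.group_labels)})   obs: {self.model.nobs}",
            f"  logLik: {self.llf:.3f}   deviance: {self.deviance:.3f}   "
            f"converged: {self.converged}",
            f"  sigma_u: {self.sigma_u:.4f}",
            f"  {'term':<28}{'coef':>10}{'std err':>10}",
        ]
        for name, est, se in zip(self.model.exog_names, self.fe_params,
                                 self.bse):
            lines.append(f"  {name:<28}{est:>10.4f}{se:>10.4f}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.fe_params, "bse": self.bse})


def fit_hierarchical_logistic(data: pd.DataFrame,
                              spec: LogisticSpec | None = None,
                              n_nodes: int = 15, adaptive: bool = True,
                              **fit_kwargs) -> HierarchicalLogitResults:
    """Convenience wrapper: build and fit a `HierarchicalLogit`."""
    return HierarchicalLogit(data, spec=spec, n_nodes=n_nodes,
                             adaptive=adaptive).fit(**fit_kwargs)


def lrt_compare(full: HierarchicalLogitResults,
                reduced: HierarchicalLogitResults) -> LrtResult:
    """Chi-square LRT: deviance(reduced) - deviance(full), df = parameter
    difference; requires the reduced fixed-effect spec nested in the full."""
    if not reduced.model.spec.is_nested_in(full.model.spec):
        raise ValueError("reduced model terms are not a subset of the full "
                         "model terms")
    if reduced.model.nobs != full.model.nobs:
        raise ValueError("fits use different data")
    df = full.df_model - reduced.df_model
    if df <= 0:
        raise ValueError("full model has no extra parameters")
    stat = max(reduced.deviance - full.deviance, 0.0)
    return LrtResult(chi_sq=stat, df=df, p_value=float(chi2.sf(stat, df)))
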