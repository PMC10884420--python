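"""Cause-specific and transition-specific Cox proportional-hazards regression.

The cause-specific hazard for event type k is

    h_k(t | z) = h_k0(t) * exp(beta_k' z),

fitted by Newton-Raphson maximisation of the Breslow partial likelihood in
which events of the other cause are treated as censored at their observed
times. The cumulative baseline hazard is the Nelson-Aalen / Breslow step
function

    H_k0(t) = sum_{t_j <= t} d_j / sum_{l in R(t_j)} exp(beta' z_l).

No intercept is included (it is not estimable in the partial likelihood).
Standard errors come from the inverse observed information at the maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datasets import CompetingRisksDataset

__all__ = [
    "StepFunction",
    "CoxFit",
    "CauseSpecificCoxPH",
    "fit_cause_specific_cox",
    "log_partial_likelihood",
    "nelson_aalen_baseline",
    "fit_transition_cox",
    "ConvergenceWarning",
]


class ConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class StepFunction:
    """Right-continuous non-decreasing step function, 0 before the first jump."""

    times: np.ndarray
    values: np.ndarray

    def __call__(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        padded = np.concatenate([[0.0], self.values])
        out = padded[idx]
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class CoxFit:
    """Result of a cause- or transition-specific Cox fit."""

    beta_hat: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    baseline: StepFunction
    cause: int | tuple[int, int]
    n_events: int
    converged: bool
    iterations: int
    names: list[str]

    def summary(self) -> pd.DataFrame:
        """Per-covariate beta, hazard ratio, se, Wald z and p."""
        from scipy import stats

        z = self.beta_hat / self.se
        return pd.DataFrame(
            {
                "beta": self.beta_hat,
                "exp(beta)": np.exp(self.beta_hat),
                "se(beta)": self.se,
                "z": z,
                "p": 2.0 * stats.norm.sf(np.abs(z)),
            },
            index=self.names,
        )


def _prepare(times: np.ndarray, events: np.ndarray, X: np.ndarray):
    """Sort ascending by time; return sorted arrays and tie-group start index."""
    order = np.argsort(times, kind="stable")
    t = times[order]
    d = events[order]
    Xs = X[order]
    # first index of each tie block: risk set at t_i is rows tie_start[i]..n-1
    tie_start = np.searchsorted(t, t, side="left")
    return t, d, Xs, tie_start


def _loglik_grad_hess(t, d, Xs, tie_start, beta, want_derivs=True):
    n, m = Xs.shape
    eta = Xs @ beta
    eta_max = eta.max()
    r = np.exp(eta - eta_max)  # stabilised relative risks
    # suffix sums over the ascending order: S0[i] = sum_{j >= i} r_j, etc.
    s0 = np.cumsum(r[::-1])[::-1]
    s1 = np.cumsum((r[:, None] * Xs)[::-1], axis=0)[::-1]
    ev = np.flatnonzero(d)
    ts = tie_start[ev]
    with np.errstate(divide="ignore"):
        log_s0 = np.log(s0[ts]) + eta_max
    if not np.all(np.isfinite(log_s0)):
        # risk-set sum underflowed: the likelihood is effectively zero here
        return -np.inf, None, None
    ll = float(np.sum(eta[ev]) - np.sum(log_s0))
    if not want_derivs:
        return ll, None, None
    xbar = s1[ts] / s0[ts, None]
    grad = Xs[ev].sum(axis=0) - xbar.sum(axis=0)
    s2 = np.cumsum((r[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]))[::-1], axis=0)[::-1]
    hess = -(s2[ts] / s0[ts, None, None] - xbar[:, :, None] * xbar[:, None, :]).sum(axis=0)
    return ll, grad, hess


def _fit_cox(
    times: np.ndarray,
    events: np.ndarray,
    X: np.ndarray,
    names: list[str],
    cause,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxFit:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    X = np.asarray(X, dtype=float)
    n_events = int(events.sum())
    if n_events < 1:
        raise ValueError(f"no events for cause {cause}: cannot fit Cox model")
    const = np.ptp(X, axis=0) == 0
    if np.any(const):
        raise ValueError(
            f"covariate {names[int(np.flatnonzero(const)[0])]!r} is constant; "
            "its coefficient is not identifiable"
        )
    t, d, Xs, tie_start = _prepare(times, events, X)
    m = X.shape[1]
    beta = np.zeros(m)
    ll, grad, hess = _loglik_grad_hess(t, d, Xs, tie_start, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        step = np.linalg.solve(-hess, grad)
        # step-halving if the likelihood does not improve
        factor = 1.0
        improved = False
        for _ in range(40):
            cand = beta + factor * step
            ll_new, g_new, h_new = _loglik_grad_hess(t, d, Xs, tie_start, cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                beta, ll, grad, hess = cand, ll_new, g_new, h_new
                improved = True
                break
            factor *= 0.5
        if not improved:
            break
    else:
        it = max_iter
    if not converged and np.max(np.abs(grad)) < tol:
        converged = True
    # a huge coefficient with a flat score is monotone likelihood, not a maximum
    if not converged or np.max(np.abs(beta)) > 15:
        converged = converged and np.max(np.abs(beta)) <= 15
        warnings.warn(
            f"Cox fit for cause {cause} did not converge after {it} iterations "
            "(possible monotone likelihood)",
            ConvergenceWarning,
            stacklevel=2,
        )
    info = -hess
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    baseline = _baseline_from_sorted(t, d, Xs, beta)
    return CoxFit(
        beta_hat=beta,
        se=se,
        cov=cov,
        loglik=ll,
        baseline=baseline,
        cause=cause,
        n_events=n_events,
        converged=converged,
        iterations=it,
        names=list(names),
    )


def _baseline_from_sorted(t, d, Xs, beta) -> StepFunction:
    r = np.exp(Xs @ beta)
    s0 = np.cumsum(r[::-1])[::-1]
    tie_start = np.searchsorted(t, t, side="left")
    ev = np.flatnonzero(d)
    if len(ev) == 0:
        return StepFunction(times=np.array([]), values=np.array([]))
    increments = 1.0 / s0[tie_start[ev]]
    event_times = t[ev]
    uniq, inv = np.unique(event_times, return_inverse=True)
    jump = np.zeros(len(uniq))
    np.add.at(jump, inv, increments)
    return StepFunction(times=uniq, values=np.cumsum(jump))


class CauseSpecificCoxPH(BaseEstimator):
    """Cause-specific Cox proportional-hazards model (scikit-learn style).

    Events of the other cause are treated as censored at their observed
    times; the Breslow partial likelihood is maximised by Newton-Raphson
    with step-halving.

    Parameters
    ----------
    cause : int, default 1
        Event code whose cause-specific hazard is modelled.
    tol : float, default 1e-8
        Convergence tolerance on the max-norm of the score vector.
    max_iter : int, default 100
        Newton-Raphson iteration cap.

    Attributes
    ----------
    coef_ : ndarray of shape (m,)
        Maximum partial-likelihood estimates.
    se_ : ndarray of shape (m,)
        Standard errors from the inverse observed information.
    loglik_ : float
        Maximised log partial likelihood.
    baseline_hazard_ : StepFunction
        Nelson-Aalen cumulative baseline hazard H0(t).
    """

    def __init__(self, cause: int = 1, tol: float = 1e-8, max_iter: int = 100):
        self.cause = cause
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, feature_names=None):
        """Fit on covariates ``X`` (n x m) and ``y`` = (time, status) pairs.

        ``y`` may be an (n, 2) array, a DataFrame with ``time``/``status``
        columns, or a tuple ``(times, statuses)``.
        """
        times, statuses = _unpack_y(y)
        X = np.asarray(X, dtype=float)
        if feature_names is None:
            feature_names = [f"x{j + 1}" for j in range(X.shape[1])]
        fit = _fit_cox(
            times,
            (statuses == self.cause).astype(int),
            X,
            list(feature_names),
            cause=self.cause,
            tol=self.tol,
            max_iter=self.max_iter,
        )
        self.result_ = fit
        self.coef_ = fit.beta_hat
        self.se_ = fit.se
        self.cov_ = fit.cov
        self.loglik_ = fit.loglik
        self.baseline_hazard_ = fit.baseline
        self.n_events_ = fit.n_events
        self.converged_ = fit.converged
        self.n_iter_ = fit.iterations
        self.feature_names_in_ = np.asarray(feature_names, dtype=object)
        return self

    def predict(self, X):
        """Linear predictor (log relative hazard) for each row of ``X``."""
        return np.asarray(X, dtype=float) @ self.coef_

    def predict_cumulative_hazard(self, X, times):
        """H(t | x) = H0(t) exp(x' beta) evaluated at ``times`` (rows = times)."""
        base = self.baseline_hazard_(np.asarray(times, dtype=float))
        return np.outer(base, np.exp(self.predict(X)))


def _unpack_y(y):
    if isinstance(y, CompetingRisksDataset):
        return y.times, y.statuses
    if isinstance(y, pd.DataFrame):
        return y["time"].to_numpy(dtype=float), y["status"].to_numpy(dtype=int)
    if isinstance(y, tuple) and len(y) == 2:
        return np.asarray(y[0], dtype=float), np.asarray(y[1], dtype=int)
    y = np.asarray(y)
    if y.ndim != 2 or y.shape[1] != 2:
        raise ValueError("y must be (n, 2) [time, status], a DataFrame, or a tuple")
    return y[:, 0].astype(float), y[:, 1].astype(int)


def fit_cause_specific_cox(
    dataset: CompetingRisksDataset,
    cause: int,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxFit:
    """Fit the cause-specific Cox model for one competing event."""
    model = CauseSpecificCoxPH(cause=cause, tol=tol, max_iter=max_iter)
    model.fit(dataset.X, dataset, feature_names=dataset.covariate_names)
    return model.result_


def log_partial_likelihood(dataset: CompetingRisksDataset, cause: int, beta) -> float:
    """Breslow log partial likelihood at ``beta`` for the given cause."""
    events = (dataset.statuses == cause).astype(int)
    t, d, Xs, tie_start = _prepare(dataset.times, events, dataset.X)
    ll, _, _ = _loglik_grad_hess(t, d, Xs, tie_start, np.asarray(beta, dtype=float), want_derivs=False)
    return ll


def nelson_aalen_baseline(dataset: CompetingRisksDataset, cause: int, beta) -> StepFunction:
    """Nelson-Aalen cumulative baseline hazard at the supplied coefficients."""
    events = (dataset.statuses == cause).astype(int)
    t, d, Xs, _ = _prepare(dataset.times, events, dataset.X)
    return _baseline_from_sorted(t, d, Xs, np.asarray(beta, dtype=float))


def fit_transition_cox(
    long_records: pd.DataFrame,
    transition: tuple[int, int],
    covariate_cols: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxFit:
    """Transition-specific Cox fit on mstate-style long records.

    The joint partial likelihood over all transitions factorises by
    transition, so each i -> j is fitted on its own rows. Sojourn durations
    (exit - entry) form the time scale (clock reset at state entry).
    """
    i, j = transition
    rows = long_records[(long_records["from_state"] == i) & (long_records["to_state"] == j)]
    if len(rows) == 0:
        raise ValueError(f"no at-risk records for transition {i}->{j}")
    if int(rows["event"].sum()) < 1:
        raise ValueError(f"no events for transition {i}->{j}: cannot fit Cox model")
    if covariate_cols is None:
        reserved = {"id", "from_state", "to_state", "entry_time", "exit_time", "event", "cause"}
        covariate_cols = [c for c in long_records.columns if c not in reserved]
    durations = (rows["exit_time"] - rows["entry_time"]).to_numpy(dtype=float)
    return _fit_cox(
        durations,
        rows["event"].to_numpy(dtype=int),
        rows[covariate_cols].to_numpy(dtype=float),
        list(covariate_cols),
        cause=(i, j),
        tol=tol,
        max_iter=max_iter,
    )
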