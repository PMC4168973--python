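"""Cox proportional hazards: partial likelihood, L1 (LASSO) fitting, and
repeated cross-validated lambda selection.

The hazard is h0(t)·exp(X beta); the baseline h0 cancels from the partial
likelihood and is never estimated.  Ties are handled with the Breslow
approximation by default (Efron available for likelihood evaluation and the
unpenalized Newton fit).  The penalized fit maximizes

    log partial likelihood  -  lambda * sum_i |beta_i|

by iteratively reweighted least squares on the quadratic approximation of the
partial likelihood, with cyclic coordinate descent and soft-thresholding in
the inner loop (the inner solver is JIT-compiled).  Lambda is chosen by
repeated K-fold cross-validated partial likelihood (Verweij & van
Houwelingen construction: loglik(full, beta_train) - loglik(train,
beta_train)), maximizing the mean across repeats.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import optimize, stats

from .io import SurvivalOutcome

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "PenalizedCoxFit",
    "UnivariateCoxResult",
    "LambdaSelection",
    "cox_partial_loglik",
    "fit_penalized_cox",
    "fit_cox_path",
    "select_lambda",
    "fit_univariate_cox",
    "fit_cox_newton",
    "lambda_max",
    "default_lambda_grid",
]


@dataclass
class FeatureMatrix:
    """Features x samples with optional per-feature block labels.

    ``allow_missing`` admits NaN cells (e.g. raw clinical covariates before
    complete-case filtering); model-fitting entry points require finite data.
    """

    data: pd.DataFrame
    standardized: bool = False
    blocks: dict[str, str] = field(default_factory=dict)
    allow_missing: bool = False

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate feature names")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        vals = self.data.to_numpy(dtype=float)
        if vals.size and not self.allow_missing and not np.isfinite(vals).all():
            raise ValueError("feature matrix contains non-finite values")
        self.data = self.data.astype(float)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def design(self) -> np.ndarray:
        """Samples x features array for model fitting."""
        return self.data.to_numpy().T

    def align(self, survival: SurvivalOutcome) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ids = self.sample_ids
        surv = survival.data.loc[ids]
        return self.design(), surv["time"].to_numpy(), surv["event"].to_numpy().astype(int)


@dataclass
class PenalizedCoxFit:
    coefficients: pd.Series
    lam: float
    objective_trace: list[float]
    converged: bool
    n_iterations: int

    @property
    def selected_features(self) -> list[str]:
        return list(self.coefficients.index[self.coefficients != 0.0])


@dataclass
class UnivariateCoxResult:
    feature: str
    coefficient: float
    hazard_ratio: float
    standard_error: float
    p_value: float


@dataclass
class LambdaSelection:
    lambdas: np.ndarray
    cv_loglik: np.ndarray  # (n_repeats, n_lambdas) held-out partial loglik sums
    chosen_lambda: float
    chosen_index: int
    n_repeats: int
    n_folds: int
    seed: int | None

    @property
    def mean_cv_loglik(self) -> np.ndarray:
        return self.cv_loglik.mean(axis=0)


# ---------------------------------------------------------------------------
# partial likelihood


def _sorted_views(time: np.ndarray, event: np.ndarray, eta: np.ndarray):
    order = np.argsort(time, kind="stable")
    return order, time[order], event[order].astype(int), eta[order]


def _breslow_blocks(t: np.ndarray, d: np.ndarray, e: np.ndarray):
    """Risk-set sums per distinct event time (ascending).

    Returns (unique event times, events per block, risk-set exp(eta) sums,
    suffix sums rev with rev[i] = sum_{j >= i} e[j], first index of each tie
    block for every subject).
    """
    rev = np.cumsum(e[::-1])[::-1]
    first = np.searchsorted(t, t, side="left")
    ev_mask = d == 1
    ev_times = t[ev_mask]
    ut, ut_first = np.unique(ev_times, return_index=True)
    d_block = np.diff(np.searchsorted(ev_times, ut, side="right"), prepend=0)
    # risk-set sum at each distinct event time: suffix starting at the first
    # subject (event or censored) with that time
    block_start = np.searchsorted(t, ut, side="left")
    S_block = rev[block_start]
    return ut, d_block.astype(float), S_block, rev, first


def cox_partial_loglik(
    beta: np.ndarray | Sequence[float],
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    ties: str = "breslow",
) -> float:
    """Log partial likelihood at ``beta`` (samples x features X).

    The baseline hazard cancels and is never estimated.  With no events the
    partial likelihood is an empty product: returns 0 with a warning.
    """
    beta = np.asarray(beta, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    event = np.asarray(event).astype(int)
    if event.sum() == 0:
        warnings.warn("no events: partial log-likelihood is 0", stacklevel=2)
        return 0.0
    eta = X @ beta
    _, t, d, eta_s = _sorted_views(np.asarray(time, dtype=float), event, eta)
    e = np.exp(eta_s)
    if ties == "breslow":
        ut, d_block, S_block, _, _ = _breslow_blocks(t, d, e)
        return float(eta_s[d == 1].sum() - (d_block * np.log(S_block)).sum())
    if ties == "efron":
        ll = float(eta_s[d == 1].sum())
        rev = np.cumsum(e[::-1])[::-1]
        ut = np.unique(t[d == 1])
        for u in ut:
            tie = (t == u) & (d == 1)
            m = int(tie.sum())
            S = rev[np.searchsorted(t, u, side="left")]
            tie_sum = e[tie].sum()
            for l in range(m):
                ll -= np.log(S - (l / m) * tie_sum)
        return float(ll)
    raise ValueError(f"unknown ties method {ties!r}")


def _breslow_grad_diag(eta: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Per-subject gradient and positive diagonal-Hessian weights (Breslow).

    grad_k = delta_k - e^eta_k * r_k  with r_k = sum over event blocks at or
    before t_k of d_b / S_b;  w_k = e^eta_k r_k - e^{2 eta_k} q_k with q the
    analogous sum of d_b / S_b^2.
    """
    order, t, d, eta_s = _sorted_views(time, event.astype(int), eta)
    e = np.exp(eta_s)
    ut, d_block, S_block, _, _ = _breslow_blocks(t, d, e)
    c1 = np.concatenate([[0.0], np.cumsum(d_block / S_block)])
    c2 = np.concatenate([[0.0], np.cumsum(d_block / S_block**2)])
    pos = np.searchsorted(ut, t, side="right")
    r = c1[pos]
    q = c2[pos]
    grad_s = d - e * r
    w_s = e * r - e**2 * q
    grad = np.empty_like(grad_s)
    w = np.empty_like(w_s)
    grad[order] = grad_s
    w[order] = w_s
    return grad, w


def _breslow_grad_hess(beta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Full gradient and negative-Hessian of the Breslow partial loglik."""
    order = np.argsort(time, kind="stable")
    t = time[order]
    d = event[order].astype(int)
    Xs = X[order]
    e = np.exp(Xs @ beta)
    ut, d_block, S_block, rev, _ = _breslow_blocks(t, d, e)
    ex = e[:, None] * Xs
    exx = np.einsum("k,kp,kq->kpq", e, Xs, Xs)
    U = np.cumsum(ex[::-1], axis=0)[::-1]
    V = np.cumsum(exx[::-1], axis=0)[::-1]
    block_start = np.searchsorted(t, ut, side="left")
    Ub = U[block_start]
    Vb = V[block_start]
    grad = Xs[d == 1].sum(axis=0) - np.einsum("b,bp->p", d_block / S_block, Ub)
    hess = np.einsum("b,bpq->pq", d_block / S_block, Vb) - np.einsum(
        "b,bp,bq->pq", d_block / S_block**2, Ub, Ub
    )
    return grad, hess


# ---------------------------------------------------------------------------
# unpenalized Newton fit


@dataclass
class NewtonCoxFit:
    coefficients: np.ndarray
    covariance: np.ndarray
    loglik: float
    converged: bool
    n_iterations: int


def fit_cox_newton(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    ties: str = "breslow",
    max_iter: int = 100,
    tol: float = 1e-9,
) -> NewtonCoxFit:
    """Unpenalized Cox MLE by Newton-Raphson with step-halving.

    For ``ties='efron'`` the fit falls back to quasi-Newton optimization of
    the Efron likelihood (numeric gradient; intended for small p).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    n, p = X.shape
    if ties == "efron":
        res = optimize.minimize(
            lambda b: -cox_partial_loglik(b, X, time, event, ties="efron"),
            x0=np.zeros(p),
            method="BFGS",
        )
        _, hess = _breslow_grad_hess(res.x, X, time, event)
        return NewtonCoxFit(res.x, np.linalg.inv(hess), -res.fun, res.success, res.nit)
    beta = np.zeros(p)
    ll = cox_partial_loglik(beta, X, time, event)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad, hess = _breslow_grad_hess(beta, X, time, event)
        step = np.linalg.solve(hess + 1e-12 * np.eye(p), grad)
        alpha = 1.0
        for _ in range(30):
            cand = beta + alpha * step
            ll_new = cox_partial_loglik(cand, X, time, event)
            if ll_new >= ll - 1e-14:
                break
            alpha /= 2
        if np.max(np.abs(alpha * step)) < tol:
            beta, ll = cand, ll_new
            converged = True
            break
        beta, ll = cand, ll_new
    _, hess = _breslow_grad_hess(beta, X, time, event)
    cov = np.linalg.inv(hess + 1e-12 * np.eye(p))
    return NewtonCoxFit(beta, cov, ll, converged, it)


def fit_univariate_cox(
    feature: np.ndarray | pd.Series,
    survival: SurvivalOutcome | None = None,
    time: np.ndarray | None = None,
    event: np.ndarray | None = None,
    name: str = "",
) -> UnivariateCoxResult:
    """Single-feature Cox fit: HR = exp(coef), Wald p from coef/se vs N(0,1)."""
    if isinstance(feature, pd.Series):
        name = name or str(feature.name)
        x = feature.to_numpy(dtype=float)
        if survival is not None:
            surv = survival.data.loc[feature.index]
            time, event = surv["time"].to_numpy(), surv["event"].to_numpy().astype(int)
    else:
        x = np.asarray(feature, dtype=float)
        if survival is not None:
            time, event = survival.time, survival.event
    if time is None or event is None:
        raise ValueError("survival information required")
    if np.std(x) == 0:
        raise ValueError(f"feature {name!r} has zero variance")
    fit = fit_cox_newton(x[:, None], np.asarray(time, float), np.asarray(event))
    coef = float(fit.coefficients[0])
    se = float(np.sqrt(fit.covariance[0, 0]))
    z = coef / se if se > 0 else 0.0
    p = float(2 * stats.norm.sf(abs(z)))
    return UnivariateCoxResult(name, coef, float(np.exp(coef)), se, max(p, np.finfo(float).tiny))


# ---------------------------------------------------------------------------
# penalized fit (IRLS + coordinate descent)


@njit(cache=False)
def _cd_wls_lasso(X, w, z, lam, beta, max_sweeps, tol):  # pragma: no cover - jitted
    """Cyclic coordinate descent with soft-thresholding on the weighted
    least-squares surrogate 0.5 * sum w (z - X beta)^2 + lam * sum |beta|."""
    n, p = X.shape
    denom = np.zeros(p)
    for j in range(p):
        s = 0.0
        for k in range(n):
            s += w[k] * X[k, j] * X[k, j]
        denom[j] = s
    r = z - X @ beta
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        max_delta = 0.0
        for j in range(p):
            bj = beta[j]
            rho = 0.0
            for k in range(n):
                rho += w[k] * X[k, j] * r[k]
            rho += denom[j] * bj
            if denom[j] <= 0.0:
                new = 0.0
            elif rho > lam:
                new = (rho - lam) / denom[j]
            elif rho < -lam:
                new = (rho + lam) / denom[j]
            else:
                new = 0.0
            d = new - bj
            if d != 0.0:
                for k in range(n):
                    r[k] -= X[k, j] * d
                beta[j] = new
                if abs(d) > max_delta:
                    max_delta = abs(d)
        if max_delta < tol:
            break
    return sweeps


def lambda_max(X: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Smallest lambda at which the all-zero coefficient vector is optimal
    (KKT: max absolute score of the partial likelihood at beta = 0)."""
    grad, _ = _breslow_grad_diag(np.zeros(len(time)), np.asarray(time, float), np.asarray(event))
    return float(np.max(np.abs(np.asarray(X, float).T @ grad)))


def default_lambda_grid(lam_max: float, n: int = 50, ratio: float = 1e-3) -> np.ndarray:
    """Log-spaced grid of n values strictly decreasing from lambda_max."""
    return lam_max * np.logspace(0, np.log10(ratio), n)


def _penalized_objective(beta, X, time, event, lam) -> float:
    return cox_partial_loglik(beta, X, time, event) - lam * np.abs(beta).sum()


def fit_penalized_cox(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    lam: float,
    beta0: np.ndarray | None = None,
    max_irls: int = 50,
    cd_tol: float = 1e-6,
    max_sweeps: int = 1000,
    feature_names: Sequence[str] | None = None,
) -> PenalizedCoxFit:
    """L1-penalized Cox fit at one lambda (features should be standardized).

    IRLS outer loop with the jitted soft-threshold coordinate-descent inner
    solver; a step that would worsen the penalized objective is backtracked,
    so the objective trace is non-decreasing (the recorded negative-objective
    trace is non-increasing).  Non-convergence flags the result rather than
    raising.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    obj = _penalized_objective(beta, X, time, event, lam)
    trace = [obj]
    converged = False
    it = 0
    for it in range(1, max_irls + 1):
        eta = X @ beta
        grad, w = _breslow_grad_diag(eta, time, event)
        w = np.maximum(w, 1e-10)
        z = eta + grad / w
        beta_new = beta.copy()
        _cd_wls_lasso(X, w, z, lam, beta_new, max_sweeps, cd_tol)
        obj_new = _penalized_objective(beta_new, X, time, event, lam)
        if obj_new < obj - 1e-12:
            # backtrack toward the previous iterate
            ok = False
            for _ in range(20):
                beta_new = 0.5 * (beta_new + beta)
                obj_new = _penalized_objective(beta_new, X, time, event, lam)
                if obj_new >= obj - 1e-12:
                    ok = True
                    break
            if not ok:
                converged = True  # no improving step exists at this resolution
                break
        delta = np.max(np.abs(beta_new - beta)) if p else 0.0
        beta = beta_new
        obj = max(obj_new, obj)
        trace.append(obj)
        if delta < cd_tol:
            converged = True
            break
    if not converged:
        logger.warning("fit_penalized_cox: IRLS did not converge in %d iterations", max_irls)
    names = list(feature_names) if feature_names is not None else [f"x{j}" for j in range(p)]
    coefs = pd.Series(beta, index=names)
    return PenalizedCoxFit(coefs, float(lam), trace, converged, it)


def fit_cox_path(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    lambdas: np.ndarray,
    feature_names: Sequence[str] | None = None,
    **kwargs,
) -> list[PenalizedCoxFit]:
    """Fit the LASSO path over a decreasing lambda grid with warm starts."""
    fits: list[PenalizedCoxFit] = []
    beta = None
    for lam in lambdas:
        fit = fit_penalized_cox(
            X, time, event, float(lam), beta0=beta, feature_names=feature_names, **kwargs
        )
        beta = fit.coefficients.to_numpy().copy()
        fits.append(fit)
    return fits


# ---------------------------------------------------------------------------
# lambda selection by repeated cross-validated partial likelihood


def _stratified_folds(event: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Event-stratified fold labels (events and censored spread evenly)."""
    n = len(event)
    labels = np.empty(n, dtype=np.int64)
    for cls in (1, 0):
        idx = np.flatnonzero(event == cls)
        idx = rng.permutation(idx)
        labels[idx] = np.arange(len(idx)) % n_folds
    return labels


def select_lambda(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    n_repeats: int = 250,
    n_folds: int = 5,
    seed: int | None = None,
    lambdas: np.ndarray | None = None,
    max_fold_retries: int = 20,
) -> LambdaSelection:
    """Choose lambda maximizing the mean cross-validated partial likelihood.

    Each repeat draws a fresh event-stratified K-fold split; the held-out
    contribution of a fold is loglik(full data, beta_train) - loglik(train,
    beta_train).  A split leaving any training part without events is redrawn
    (up to ``max_fold_retries``).  Fully reproducible from ``seed``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if event.sum() < n_folds:
        raise ValueError(f"need at least {n_folds} events for {n_folds}-fold selection")
    if lambdas is None:
        lambdas = default_lambda_grid(lambda_max(X, time, event))
    lambdas = np.asarray(lambdas, dtype=float)
    rng = np.random.default_rng(seed)
    cv = np.zeros((n_repeats, len(lambdas)))
    for rep in range(n_repeats):
        for _ in range(max_fold_retries):
            labels = _stratified_folds(event, n_folds, rng)
            ok = all(event[labels != f].sum() > 0 for f in range(n_folds))
            if ok:
                break
            logger.info("select_lambda: redrawing split with an event-free training part")
        for f in range(n_folds):
            train = labels != f
            fits = fit_cox_path(X[train], time[train], event[train], lambdas)
            for li, fit in enumerate(fits):
                beta = fit.coefficients.to_numpy()
                full = cox_partial_loglik(beta, X, time, event)
                tr = cox_partial_loglik(beta, X[train], time[train], event[train])
                cv[rep, li] += full - tr
    mean_cv = cv.mean(axis=0)
    chosen = int(np.argmax(mean_cv))
    return LambdaSelection(
        lambdas=lambdas,
        cv_loglik=cv,
        chosen_lambda=float(lambdas[chosen]),
        chosen_index=chosen,
        n_repeats=n_repeats,
        n_folds=n_folds,
        seed=seed,
    )
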