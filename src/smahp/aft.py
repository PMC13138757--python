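"""Parametric accelerated failure time (AFT) models by censored maximum likelihood.

The AFT model is log T = x'beta + b*eps, with eps standard normal
(log-normal T), standard minimum Gumbel (Weibull T) or standard logistic
(log-logistic T) and scale parameter b.  Fitting maximizes the censored
log-likelihood

    sum_i  delta_i * [log f(r_i) - log b] + (1 - delta_i) * log S(r_i),

with standardized residuals r_i = (log t_i - x_i'beta)/b, by Newton
iterations on (beta, log b).  Standard errors come from the observed
information matrix.

Two entry points:

* :func:`fit_aft` - one model, arbitrary design.
* :func:`batch_univariate_aft` - many single-feature models fitted
  simultaneously (vectorized over features), used by the marginal
  screens where one model per gene or protein is required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, log_ndtr
from scipy.stats import norm

__all__ = [
    "AFTFit",
    "AFTError",
    "fit_aft",
    "batch_univariate_aft",
    "ERROR_FAMILIES",
]

ERROR_FAMILIES = ("log_normal", "weibull", "log_logistic")

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class AFTError(RuntimeError):
    """Raised when an AFT fit is infeasible (no events, singular design, ...)."""


def _clip_exp(r):
    return np.exp(np.minimum(r, 50.0))


def _family_terms(family: str, r: np.ndarray):
    """Return (A, A', A'', B, B', B'') at r.

    A = log density of the standardized error, B = log survival; primes
    are derivatives in r.  All arrays share r's shape.
    """
    if family == "log_normal":
        A = -0.5 * r * r - _LOG_SQRT_2PI
        dA = -r
        ddA = np.full_like(r, -1.0)
        B = log_ndtr(-r)
        lam = np.exp(A - B)  # normal hazard phi(r)/Phi(-r)
        dB = -lam
        ddB = -lam * (lam - r)
    elif family == "weibull":
        er = _clip_exp(r)
        A = r - er
        dA = 1.0 - er
        ddA = -er
        B = -er
        dB = -er
        ddB = -er
    elif family == "log_logistic":
        sig = expit(r)
        sp = np.logaddexp(0.0, r)  # softplus
        A = r - 2.0 * sp
        dA = 1.0 - 2.0 * sig
        ddA = -2.0 * sig * (1.0 - sig)
        B = -sp
        dB = -sig
        ddB = -sig * (1.0 - sig)
    else:
        raise ValueError(f"unknown error family {family!r}; choose from {ERROR_FAMILIES}")
    return A, dA, ddA, B, dB, ddB


@dataclass
class AFTFit:
    """A fitted parametric AFT model.

    Coefficients are on the log-time scale; ``scale`` is the error scale b.
    """

    names: list
    coefficients: np.ndarray
    standard_errors: np.ndarray
    scale: float
    log_likelihood: float
    error_family: str
    converged: bool = True
    n: int = 0

    def coef(self, name: str) -> float:
        return float(self.coefficients[self.names.index(name)])

    def se(self, name: str) -> float:
        return float(self.standard_errors[self.names.index(name)])

    def zvalues(self) -> np.ndarray:
        return self.coefficients / self.standard_errors

    def pvalues(self) -> np.ndarray:
        return 2.0 * norm.sf(np.abs(self.zvalues()))

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "se": self.standard_errors,
                "z": self.zvalues(),
                "p": self.pvalues(),
            },
            index=self.names,
        )


def _ascent_direction(H, g):
    """Damped Newton ascent direction solve((-H + tau*I), g).

    tau shifts the spectrum just enough to make the information matrix
    positive definite when the Hessian is indefinite far from the optimum.
    Works on a single (m, m) Hessian or a (k, m, m) stack.
    """
    info = -np.asarray(H)
    eigs = np.linalg.eigvalsh(info)
    min_eig = eigs[..., 0]
    tau = np.maximum(0.0, 1e-6 - min_eig)
    if info.ndim == 2:
        info = info + tau * np.eye(info.shape[-1])
        return np.linalg.solve(info, g)
    info = info + tau[:, None, None] * np.eye(info.shape[-1])[None]
    return np.linalg.solve(info, g[..., None])[..., 0]


def _loglik_grad_hess(theta, X, y, delta, family):
    """Censored log-likelihood, gradient and Hessian at theta = (beta, log b)."""
    n, m = X.shape
    beta = theta[:m]
    s = float(np.clip(theta[m], -20.0, 20.0))
    b = np.exp(s)
    with np.errstate(all="ignore"):
        r = (y - X @ beta) / b
        A, dA, ddA, B, dB, ddB = _family_terms(family, r)
        ll = float(np.sum(delta * (A - s) + (1.0 - delta) * B))
        U = delta * dA + (1.0 - delta) * dB
        W = delta * ddA + (1.0 - delta) * ddB
        grad = np.empty(m + 1)
        grad[:m] = -(X.T @ U) / b
        grad[m] = -np.sum(U * r) - np.sum(delta)
        H = np.empty((m + 1, m + 1))
        H[:m, :m] = (X.T * W) @ X / (b * b)
        hbs = X.T @ (W * r + U) / b
        H[:m, m] = hbs
        H[m, :m] = hbs
        H[m, m] = np.sum(r * r * W + r * U)
    return ll, grad, H


def fit_aft(
    X: np.ndarray,
    y: np.ndarray,
    delta: np.ndarray,
    names=None,
    family: str = "log_normal",
    add_intercept: bool = True,
    max_iter: int = 100,
    tol: float = 1e-9,
    strict: bool = True,
) -> AFTFit:
    """Fit one parametric AFT model of log-time ``y`` on design ``X``.

    Parameters
    ----------
    X : (n, m) design matrix (without intercept unless add_intercept=False).
    y : (n,) log event/censoring times.
    delta : (n,) event indicator, 1 = event observed, 0 = censored.
    names : feature names for the columns of X.
    family : error family, one of ``log_normal``, ``weibull``, ``log_logistic``.
    strict : raise on non-convergence / singular information; with
        strict=False the best iterate is returned (converged=False) with
        standard errors from a ridge-damped information matrix.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    delta = np.asarray(delta, dtype=float)
    n = y.shape[0]
    if X.shape[0] != n:
        raise ValueError("X and y have incompatible shapes")
    if delta.sum() < 1:
        raise AFTError("no events: AFT likelihood is unbounded with all-censored data")
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    names = list(names)
    if add_intercept:
        X = np.column_stack([X, np.ones(n)])
        names = names + ["intercept"]
    m = X.shape[1]
    if m + 1 >= n:
        raise AFTError(f"design with {m} columns is too large for n={n} samples")
    if np.linalg.matrix_rank(X) < m:
        raise AFTError("singular design matrix in AFT fit")

    theta = np.zeros(m + 1)
    # start from the least-squares fit on log-times, a good basin for all families
    theta[:m], *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ theta[:m]
    theta[m] = np.log(max(np.std(resid), 1e-3))

    ll, grad, H = _loglik_grad_hess(theta, X, y, delta, family)
    converged = False
    for _ in range(max_iter):
        step = -_ascent_direction(H, grad)
        # Newton direction for a maximum: theta - H^{-1} g (H negative definite)
        new = theta - step
        ll_new, grad_new, H_new = _loglik_grad_hess(new, X, y, delta, family)
        halvings = 0
        while not np.isfinite(ll_new) or ll_new < ll - 1e-10:
            halvings += 1
            if halvings > 30:
                break
            new = theta - step / (2.0**halvings)
            ll_new, grad_new, H_new = _loglik_grad_hess(new, X, y, delta, family)
        delta_theta = np.max(np.abs(new - theta))
        theta, ll, grad, H = new, ll_new, grad_new, H_new
        if delta_theta < tol * (1.0 + np.max(np.abs(theta))):
            converged = True
            break
    if not converged and np.max(np.abs(grad)) > 1e-4 * (1.0 + abs(ll)):
        if strict:
            raise AFTError("AFT maximum-likelihood fit did not converge")
        converged = False

    info = -H
    try:
        cov = np.linalg.inv(info)
        if np.any(np.diag(cov)[:m] <= 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        if strict:
            raise AFTError("observed information is singular; standard errors unavailable")
        eigs = np.linalg.eigvalsh(info)
        tau = max(0.0, 1e-6 - eigs[0])
        cov = np.linalg.inv(info + tau * np.eye(info.shape[0]))
        converged = False
    se = np.sqrt(np.clip(np.diag(cov)[:m], 0.0, np.inf))
    return AFTFit(
        names=names,
        coefficients=theta[:m],
        standard_errors=se,
        scale=float(np.exp(np.clip(theta[m], -20.0, 20.0))),
        log_likelihood=ll,
        error_family=family,
        converged=converged,
        n=n,
    )


def batch_univariate_aft(
    features: np.ndarray,
    y: np.ndarray,
    delta: np.ndarray,
    Z: np.ndarray | None = None,
    family: str = "log_normal",
    max_iter: int = 60,
    tol: float = 1e-8,
    chunk: int = 512,
) -> pd.DataFrame:
    """Fit one AFT model per feature column: log T ~ feature (+ Z) + intercept.

    Returns a DataFrame with one row per feature: the feature coefficient,
    its standard error, the Wald z and the two-sided normal p-value.
    Constant features are assigned p = 1 (coefficient undefined), as are
    the rare fits that fail to converge.
    """
    F = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(y, dtype=float)
    delta = np.asarray(delta, dtype=float)
    n, k = F.shape
    if delta.sum() < 1:
        raise AFTError("no events: AFT likelihood is unbounded with all-censored data")
    q = 0 if Z is None else np.atleast_2d(Z).shape[1]
    m = 2 + q  # intercept + feature + covariates

    coef = np.full(k, np.nan)
    se = np.full(k, np.nan)
    ok = np.zeros(k, dtype=bool)
    const = F.std(axis=0) < 1e-12

    for lo in range(0, k, chunk):
        hi = min(lo + chunk, k)
        idx = [j for j in range(lo, hi) if not const[j]]
        if not idx:
            continue
        kb = len(idx)
        D = np.empty((kb, n, m))
        D[:, :, 0] = 1.0
        D[:, :, 1] = F[:, idx].T
        if Z is not None:
            D[:, :, 2:] = np.broadcast_to(np.atleast_2d(Z), (kb, n, q))
        c, s, good = _batch_newton(D, y, delta, family, max_iter, tol)
        coef[idx] = c
        se[idx] = s
        ok[idx] = good

    z = np.where(ok, coef / se, 0.0)
    p = np.where(ok, 2.0 * norm.sf(np.abs(z)), 1.0)
    return pd.DataFrame({"coef": coef, "se": se, "z": z, "p": p})


def _batch_newton(D, y, delta, family, max_iter, tol):
    """Vectorized Newton over a stack of small designs D (k, n, m).

    The feature coefficient sits in column 1 of each design.  Returns its
    estimate, standard error and a convergence flag per feature.
    """
    kb, n, m = D.shape
    theta = np.zeros((kb, m + 1))
    # shared least-squares warm start per feature
    for j in range(kb):
        theta[j, :m], *_ = np.linalg.lstsq(D[j], y, rcond=None)
    resid_sd = np.maximum(
        np.std(y[None, :] - np.einsum("knm,km->kn", D, theta[:, :m]), axis=1), 1e-3
    )
    theta[:, m] = np.log(resid_sd)
    active = np.ones(kb, dtype=bool)
    dvec = delta[None, :]

    def _llgh(th, mask):
        with np.errstate(all="ignore"):
            b = np.exp(np.clip(th[mask, m], -20.0, 20.0))[:, None]
            eta = np.einsum("knm,km->kn", D[mask], th[mask, :m])
            r = (y[None, :] - eta) / b
            A, dA, ddA, B, dB, ddB = _family_terms(family, r)
            ll = np.sum(dvec * (A - th[mask, m][:, None]) + (1 - dvec) * B, axis=1)
            U = dvec * dA + (1 - dvec) * dB
            W = dvec * ddA + (1 - dvec) * ddB
            g = np.empty((mask.sum(), m + 1))
            g[:, :m] = -np.einsum("knm,kn->km", D[mask], U) / b
            g[:, m] = -np.sum(U * r, axis=1) - delta.sum()
            H = np.empty((mask.sum(), m + 1, m + 1))
            H[:, :m, :m] = np.einsum("kni,kn,knj->kij", D[mask], W, D[mask]) / (b * b)[:, :, None]
            hbs = np.einsum("knm,kn->km", D[mask], W * r + U) / b
            H[:, :m, m] = hbs
            H[:, m, :m] = hbs
            H[:, m, m] = np.sum(r * r * W + r * U, axis=1)
        return ll, g, H

    ll, g, H = _llgh(theta, active)
    ll_full = ll.copy()
    converged = np.zeros(kb, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        step = -_ascent_direction(H, g)
        th_act = theta[active]
        frac = np.ones(len(step))
        for _half in range(31):
            cand = th_act - step * frac[:, None]
            full_cand = theta.copy()
            full_cand[active] = cand
            ll_new, g_new, H_new = _llgh(full_cand, active)
            bad = ~np.isfinite(ll_new) | (ll_new < ll_full[active] - 1e-10)
            if not bad.any():
                break
            frac[bad] *= 0.5
        moved = np.max(np.abs(cand - th_act), axis=1)
        theta[active] = cand
        ll_full[active] = ll_new
        done = moved < tol * (1.0 + np.max(np.abs(cand), axis=1))
        converged[np.flatnonzero(active)[done]] = True
        active[np.flatnonzero(active)[done]] = False
        if active.any():
            ll, g, H = _llgh(theta, active)

    # standard errors from the observed information of each final fit
    ses = np.full(kb, np.nan)
    mask_all = np.ones(kb, dtype=bool)
    _, _, Hf = _llgh(theta, mask_all)
    for j in range(kb):
        try:
            cov = np.linalg.inv(-Hf[j])
            if cov[1, 1] > 0:
                ses[j] = np.sqrt(cov[1, 1])
            else:
                converged[j] = False
        except np.linalg.LinAlgError:
            converged[j] = False
    return theta[:, 1], ses, converged & np.isfinite(ses)
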