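"""Step 1: penalized screening of mediators and exposures.

Two penalized outcome fits (rank-based Gehan AFT with an elastic-net
penalty) reduce the mediator and exposure layers to their active sets,

    log T ~ M   ->  S1  (candidate mediator proteins),
    log T ~ X   ->  A_T (candidate exposure genes),

and one MCP-penalized linear regression per selected mediator

    M_k ~ X     ->  J1k (candidate exposures upstream of mediator k).

The Gehan loss is the normalized pairwise hinge

    L(beta) = (1/n^2) sum_i sum_j delta_i * max(0, e_j - e_i),
    e_i = log t_i - x_i' beta,

a convex rank-based criterion for censored AFT estimation: a comparison
enters only when subject i's event was observed (delta_i = 1), in which
case any subject j with a larger residual contributes.  Because only
residual differences appear, the loss is intercept-free and scale
parameters drop out.  Covariates Z are deliberately absent from this
step; they re-enter in the final inference models.

Lambda is selected by k-fold cross-validation with the one-standard-
error rule on a 50-point log-spaced path, unless given explicitly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._solvers import FAMILY_ENET, FAMILY_MCP, cd_ls_path, fista_gehan_path
from .data_io import MediationDataset, SurvivalOutcome

logger = logging.getLogger(__name__)

__all__ = [
    "PenaltySpec",
    "SparseAFTFit",
    "SparseMediatorFit",
    "ActiveSets",
    "ConvergenceError",
    "gehan_loss",
    "mcp_penalty",
    "fit_penalized_aft",
    "fit_penalized_mediator",
    "step1",
]


class ConvergenceError(RuntimeError):
    pass


@dataclass
class PenaltySpec:
    """Penalty configuration for a sparse fit.

    family: "mcp", "elastic_net" or "lasso" (elastic net at alpha_mix=1).
    lam: a nonnegative value, or "cv" for cross-validated selection.
    gamma: MCP concavity (> 1); 3.0 is the conventional default.
    alpha_mix: elastic-net mixing in [0, 1]; 1 is the pure l1 penalty.
    """

    family: str = "mcp"
    lam: object = "cv"
    gamma: float = 3.0
    alpha_mix: float = 1.0
    cv_folds: int = 5
    n_lambda: int = 50
    lambda_min_ratio: float = 0.01
    max_iter: int = 5000
    tol: float = 1e-5
    cv_rule: str = "1se"  # "1se" (default) or "min"

    def __post_init__(self):
        if self.family not in ("mcp", "elastic_net", "lasso"):
            raise ValueError(f"unknown penalty family {self.family!r}")
        if self.family == "mcp" and self.gamma <= 1:
            raise ValueError("MCP requires gamma > 1")
        if not (0.0 <= self.alpha_mix <= 1.0):
            raise ValueError("alpha_mix must be in [0, 1]")
        if self.family == "lasso":
            self.alpha_mix = 1.0
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.cv_rule not in ("min", "1se"):
            raise ValueError("cv_rule must be 'min' or '1se'")


@dataclass
class SparseAFTFit:
    coefficients: np.ndarray
    active_set: list
    lambda_selected: float
    loss_value: float
    n_iter: int = 0


@dataclass
class SparseMediatorFit:
    coefficients: np.ndarray
    active_set: list
    lambda_selected: float


@dataclass
class ActiveSets:
    """Step-1 survivors: mediators S1, exposures A_T, per-mediator J1k."""

    S1: list = field(default_factory=list)
    A_T: list = field(default_factory=list)
    J1: dict = field(default_factory=dict)

    @property
    def n_pairs(self) -> int:
        return sum(len(v) for v in self.J1.values())


def gehan_loss(coefficients, features, outcome: SurvivalOutcome) -> float:
    """Exact Gehan loss (1/n^2) sum_i delta_i sum_j max(0, e_j - e_i)."""
    if outcome.n_events < 1:
        raise ValueError("no events: Gehan loss undefined")
    X = np.atleast_2d(np.asarray(features, dtype=float))
    beta = np.asarray(coefficients, dtype=float)
    e = outcome.log_time - X @ beta
    n = e.shape[0]
    diffs = np.maximum(e[None, :] - e[:, None], 0.0)
    return float(np.sum(diffs[outcome.event > 0, :]) / (n * n))


def mcp_penalty(beta, lam: float, gamma: float = 3.0):
    """Minimax concave penalty: lam|b| - b^2/(2 gamma) below the kink gamma*lam,
    constant gamma*lam^2/2 beyond it."""
    if gamma <= 1:
        raise ValueError("MCP requires gamma > 1")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    b = np.abs(np.asarray(beta, dtype=float))
    val = np.where(b <= gamma * lam, lam * b - b * b / (2.0 * gamma), 0.5 * gamma * lam * lam)
    return float(val) if val.ndim == 0 else val


def _standardize(A):
    mu = A.mean(axis=0)
    sd = A.std(axis=0)
    keep = sd > 1e-12
    return (A[:, keep] - mu[keep]) / sd[keep], sd, keep


def _cv_folds(n, n_folds, event, seed):
    """Event-stratified fold assignment so every fold sees events."""
    rng = np.random.default_rng(seed)
    fold = np.empty(n, dtype=np.int64)
    for group in (np.flatnonzero(event > 0), np.flatnonzero(event == 0)):
        perm = rng.permutation(group)
        fold[perm] = np.arange(len(perm)) % n_folds
    return fold

def _cv_pick(cv_mean, cv_se, rule):
    best = int(np.nanargmin(cv_mean))
    if rule == "min":
        return best
    cutoff = cv_mean[best] + cv_se[best]
    ok = np.flatnonzero(cv_mean <= cutoff)
    return int(ok[0])  # lambdas descend, so the first qualifying index is the largest lambda


def fit_penalized_aft(
    features,
    outcome: SurvivalOutcome,
    penalty: PenaltySpec = None,
    seed: int = 0,
) -> SparseAFTFit:
    """Sparse rank-based AFT fit: smoothed Gehan loss + elastic-net penalty.

    Features are centered and standardized internally; returned
    coefficients are on the original scale.  MCP is not offered for the
    outcome loss; the rank-based estimator is paired with its elastic-net
    penalty (lasso at alpha_mix = 1, the default).
    """
    penalty = penalty or PenaltySpec(family="elastic_net", alpha_mix=1.0)
    if penalty.family == "mcp":
        raise ValueError("the Gehan outcome loss supports elastic_net/lasso penalties only")
    if outcome.n_events < 1:
        raise ValueError("no events: Gehan loss undefined")
    X = np.atleast_2d(np.asarray(features, dtype=float))
    n, d = X.shape
    y = outcome.log_time
    delta = outcome.event.astype(float)
    Xs, sd, keep = _standardize(X)
    if keep.sum() < d:
        warnings.warn(f"dropping {d - int(keep.sum())} constant features before the fit")
    ds = Xs.shape[1]
    if ds == 0:
        raise ValueError("all features constant")

    # induced-smoothing-scale bandwidth: vanishes at the root-n rate
    h = max(float(np.std(y)) / np.sqrt(n), 1e-6)
    alpha = max(penalty.alpha_mix, 1e-4)

    def _lip(A):
        return 2.0 / h * float(np.linalg.eigvalsh(A.T @ A / A.shape[0])[-1])

    c0 = _grad_weights(y, delta, h)
    grad0 = np.abs(Xs.T @ c0) / (n * n)
    lam_max = float(grad0.max()) / alpha
    if lam_max <= 0:
        lam_max = 1e-8

    if penalty.lam == "cv":
        lambdas = np.geomspace(lam_max, penalty.lambda_min_ratio * lam_max, penalty.n_lambda)
        fold = _cv_folds(n, penalty.cv_folds, delta, seed)
        cv_loss = np.full((penalty.cv_folds, len(lambdas)), np.nan)
        for f in range(penalty.cv_folds):
            tr, va = fold != f, fold == f
            if delta[va].sum() < 1 or delta[tr].sum() < 1:
                continue
            Xtr = Xs[tr]
            betas, _, _ = fista_gehan_path(
                np.ascontiguousarray(Xtr),
                y[tr],
                delta[tr],
                lambdas,
                alpha,
                h,
                _lip(Xtr),
                penalty.tol,
                penalty.max_iter,
                np.zeros(ds),
            )
            va_out = SurvivalOutcome(np.exp(y[va]), delta[va])
            for li in range(len(lambdas)):
                cv_loss[f, li] = gehan_loss(betas[li], Xs[va], va_out)
        cv_mean = np.nanmean(cv_loss, axis=0)
        cv_se = np.nanstd(cv_loss, axis=0, ddof=1) / np.sqrt(np.sum(~np.isnan(cv_loss), axis=0))
        pick = _cv_pick(cv_mean, cv_se, penalty.cv_rule)
        lambdas_fit = lambdas[: pick + 1]
    else:
        lam = float(penalty.lam)
        # warm-start down the path to the requested lambda for stability
        lambdas_fit = (
            np.geomspace(lam_max, lam, 10) if 0 < lam < lam_max else np.array([max(lam, 0.0)])
        )
        pick = len(lambdas_fit) - 1

    betas, iters, conv = fista_gehan_path(
        np.ascontiguousarray(Xs),
        y,
        delta,
        lambdas_fit,
        alpha,
        h,
        _lip(Xs),
        penalty.tol,
        penalty.max_iter,
        np.zeros(ds),
    )
    if not conv[pick]:
        raise ConvergenceError(
            f"penalized AFT fit did not converge in {penalty.max_iter} iterations "
            f"at lambda={lambdas_fit[pick]:.4g}"
        )
    beta_std = betas[pick]
    beta = np.zeros(d)
    beta[keep] = beta_std / sd[keep]
    lam_sel = float(lambdas_fit[pick])
    pen_val = lam_sel * (
        alpha * np.abs(beta_std).sum() + 0.5 * (1 - alpha) * float(beta_std @ beta_std)
    )
    loss = gehan_loss(beta, X, outcome) + pen_val
    active = np.flatnonzero(beta != 0.0).tolist()
    return SparseAFTFit(
        coefficients=beta,
        active_set=active,
        lambda_selected=lam_sel,
        loss_value=float(loss),
        n_iter=int(iters[pick]),
    )


def _grad_weights(y, delta, h):
    from ._solvers import _smoothed_gehan_grad

    return _smoothed_gehan_grad(y.astype(float), delta.astype(float), h, len(y))


def fit_penalized_mediator(
    X, m_k, penalty: PenaltySpec = None, seed: int = 0
) -> SparseMediatorFit:
    """Penalized least squares of one mediator on all exposures (MCP default)."""
    penalty = penalty or PenaltySpec(family="mcp")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(m_k, dtype=float)
    n, d = X.shape
    Xs, sd, keep = _standardize(X)
    if keep.sum() < d:
        warnings.warn(f"dropping {d - int(keep.sum())} constant exposures before the fit")
    ds = Xs.shape[1]
    if ds == 0:
        raise ValueError("all exposures constant")
    yc = y - y.mean()
    fam = FAMILY_MCP if penalty.family == "mcp" else FAMILY_ENET
    alpha = max(penalty.alpha_mix, 1e-4)
    lam_max = float(np.abs(Xs.T @ yc).max()) / n / (alpha if fam == FAMILY_ENET else 1.0)
    if lam_max <= 0:
        lam_max = 1e-8

    if penalty.lam == "cv":
        lambdas = np.geomspace(lam_max, penalty.lambda_min_ratio * lam_max, penalty.n_lambda)
        rng_fold = _cv_folds(n, penalty.cv_folds, np.ones(n), seed)
        cv_loss = np.full((penalty.cv_folds, len(lambdas)), np.nan)
        for f in range(penalty.cv_folds):
            tr, va = rng_fold != f, rng_fold == f
            mu_tr = Xs[tr].mean(axis=0)
            sd_tr = np.maximum(Xs[tr].std(axis=0), 1e-12)
            Xtr = (Xs[tr] - mu_tr) / sd_tr
            ytr = yc[tr] - yc[tr].mean()
            betas, _ = cd_ls_path(
                np.ascontiguousarray(Xtr),
                ytr,
                lambdas,
                penalty.gamma,
                alpha,
                fam,
                penalty.tol,
                penalty.max_iter,
                np.zeros(ds),
            )
            Xva = (Xs[va] - mu_tr) / sd_tr
            yva = yc[va] - yc[tr].mean()
            resid = yva[None, :] - betas @ Xva.T
            cv_loss[f] = np.mean(resid * resid, axis=1)
        cv_mean = np.nanmean(cv_loss, axis=0)
        cv_se = np.nanstd(cv_loss, axis=0, ddof=1) / np.sqrt(np.sum(~np.isnan(cv_loss), axis=0))
        pick = _cv_pick(cv_mean, cv_se, penalty.cv_rule)
        lambdas_fit = lambdas[: pick + 1]
    else:
        lam = float(penalty.lam)
        lambdas_fit = (
            np.geomspace(lam_max, lam, 10) if 0 < lam < lam_max else np.array([max(lam, 0.0)])
        )
        pick = len(lambdas_fit) - 1

    betas, conv = cd_ls_path(
        np.ascontiguousarray(Xs),
        yc,
        lambdas_fit,
        penalty.gamma,
        alpha,
        fam,
        penalty.tol,
        penalty.max_iter,
        np.zeros(ds),
    )
    if not conv[pick]:
        raise ConvergenceError(
            f"penalized mediator fit did not converge at lambda={lambdas_fit[pick]:.4g}"
        )
    beta = np.zeros(d)
    beta[keep] = betas[pick] / sd[keep]
    return SparseMediatorFit(
        coefficients=beta,
        active_set=np.flatnonzero(beta != 0.0).tolist(),
        lambda_selected=float(lambdas_fit[pick]),
    )


def step1(
    dataset: MediationDataset,
    penalty_outcome: PenaltySpec = None,
    penalty_mediation: PenaltySpec = None,
    seed: int = 0,
) -> ActiveSets:
    """Run the three Step-1 screens and collect the active sets.

    Mediator-model fits are performed only for mediators surviving the
    outcome screen (k in S1).  An empty S1 short-circuits the pipeline.
    """
    penalty_outcome = penalty_outcome or PenaltySpec(family="elastic_net", alpha_mix=1.0)
    penalty_mediation = penalty_mediation or PenaltySpec(family="mcp")

    fit_m = fit_penalized_aft(dataset.M.values, dataset.outcome, penalty_outcome, seed=seed)
    S1 = fit_m.active_set
    fit_x = fit_penalized_aft(dataset.X.values, dataset.outcome, penalty_outcome, seed=seed + 1)
    A_T = fit_x.active_set
    logger.info("step 1: |S1|=%d |A_T|=%d", len(S1), len(A_T))
    if not S1:
        warnings.warn("no mediators selected in Step 1; pipeline terminates")
        return ActiveSets(S1=[], A_T=A_T, J1={})

    J1 = {}
    for i, k in enumerate(S1):
        fit_k = fit_penalized_mediator(
            dataset.X.values, dataset.M.values[:, k], penalty_mediation, seed=seed + 2 + i
        )
        J1[k] = fit_k.active_set
    logger.info("step 1: total candidate pairs %d", sum(len(v) for v in J1.values()))
    return ActiveSets(S1=S1, A_T=A_T, J1=J1)
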