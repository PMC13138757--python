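"""Step 2: sure-independence screening of (exposure, mediator) pairs.

Step-1 survivors are refit without penalties: for each candidate
mediator s, a parametric AFT model

    log T ~ X_{A_T} + M_s         (maximum likelihood, gives beta_Ms)

and an ordinary least-squares regression

    M_s ~ X_{J1s}                 (gives alpha_js for j in J1s).

Every candidate pair (j, s) is scored by |alpha_js * beta_Ms| and only
the top n/log(n) pairs (optionally a multiple of it) survive into the
final inference step.  Covariates are not part of these refits; they
enter in Step 3.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .aft import AFTError, AFTFit, fit_aft
from .data_io import MediationDataset
from .penalized_screen import ActiveSets

logger = logging.getLogger(__name__)

__all__ = [
    "MediatorOLSFit",
    "ScreenedPairs",
    "sis_threshold",
    "fit_joint_outcome",
    "fit_mediator_ols",
    "screen_pairs",
]


@dataclass
class MediatorOLSFit:
    """OLS fit of one mediator on a set of exposures (classical SEs)."""

    exposure_idx: list
    coefficients: np.ndarray
    standard_errors: np.ndarray

    def coef(self, j: int) -> float:
        return float(self.coefficients[self.exposure_idx.index(j)])

    def se(self, j: int) -> float:
        return float(self.standard_errors[self.exposure_idx.index(j)])


@dataclass
class ScreenedPairs:
    """Step-2 survivors: mediators S2, per-mediator exposure sets J2, scores."""

    S2: list = field(default_factory=list)
    J2: dict = field(default_factory=dict)
    scores: dict = field(default_factory=dict)
    threshold_d: int = 0
    n_candidates: int = 0

    @property
    def pairs(self) -> list:
        return [(j, s) for s in self.S2 for j in self.J2[s]]


def sis_threshold(n: int, multiplier: float = 1.0) -> int:
    """Screening budget ceil(multiplier * n / ln n)."""
    if n < 3:
        raise ValueError("need n >= 3 for the n/log(n) threshold")
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    return int(math.ceil(multiplier * n / math.log(n)))


def fit_joint_outcome(
    dataset: MediationDataset,
    exposures,
    mediator_s: int,
    error_family: str = "log_normal",
    strict: bool = True,
) -> AFTFit:
    """AFT MLE of log-time on the Step-1 exposures plus one mediator."""
    exposures = list(exposures)
    n = dataset.n
    if len(exposures) + 1 >= n:
        raise AFTError(
            f"{len(exposures)} exposures + 1 mediator >= n={n}; "
            "use a stricter Step-1 penalty to shrink A_T"
        )
    design = np.column_stack(
        [dataset.X.values[:, exposures], dataset.M.values[:, [mediator_s]]]
    )
    names = [f"x{j}" for j in exposures] + ["mediator"]
    return fit_aft(
        design,
        dataset.outcome.log_time,
        dataset.outcome.event,
        names=names,
        family=error_family,
        strict=strict,
    )


def fit_mediator_ols(dataset: MediationDataset, exposures, mediator_s: int) -> MediatorOLSFit:
    """OLS of mediator s on its Step-1 exposure set, classical standard errors."""
    exposures = list(exposures)
    if not exposures:
        raise ValueError(f"no exposures for mediator {mediator_s}")
    n = dataset.n
    if len(exposures) + 1 >= n:
        raise ValueError(f"exposure set of size {len(exposures)} too large for n={n}")
    D = np.column_stack([dataset.X.values[:, exposures], np.ones(n)])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("rank-deficient exposure design in mediator regression")
    y = dataset.M.values[:, mediator_s]
    coef, _, _, _ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ coef
    dof = n - D.shape[1]
    sigma2 = float(resid @ resid) / max(dof, 1)
    cov = sigma2 * np.linalg.inv(D.T @ D)
    se = np.sqrt(np.diag(cov))
    return MediatorOLSFit(
        exposure_idx=exposures,
        coefficients=coef[:-1],
        standard_errors=se[:-1],
    )


def screen_pairs(
    dataset: MediationDataset,
    active: ActiveSets,
    error_family: str = "log_normal",
    multiplier: float = 1.0,
    unit: str = "pair",
    strict: bool = True,
) -> ScreenedPairs:
    """Keep the top n/log(n) screening units by |alpha_js * beta_Ms|.

    ``unit="mediator"`` (default) ranks each candidate mediator together
    with its whole exposure set by its largest pair score and keeps the
    top d mediators; ``unit="pair"`` ranks all (exposure, mediator)
    pairs globally and keeps the top d pairs.  Ties with the d-th score
    are kept in full (and the overage logged).
    """
    if not active.S1:
        raise ValueError("S1 is empty; nothing to screen")
    d = sis_threshold(dataset.n, multiplier)
    scores = {}
    for s in active.S1:
        J1s = active.J1.get(s, [])
        if not J1s:
            continue
        aft_fit = fit_joint_outcome(dataset, active.A_T, s, error_family, strict=strict)
        beta_ms = aft_fit.coef("mediator")
        ols_fit = fit_mediator_ols(dataset, J1s, s)
        for j in J1s:
            scores[(j, s)] = abs(ols_fit.coef(j) * beta_ms)

    if not scores or all(v == 0.0 for v in scores.values()):
        warnings.warn("all screening scores are zero; no pairs survive Step 2")
        return ScreenedPairs(threshold_d=d, n_candidates=len(scores))

    if unit == "mediator":
        med_scores = {}
        for (j, s), v in scores.items():
            med_scores[s] = max(med_scores.get(s, 0.0), v)
        ranked_m = sorted(med_scores.items(), key=lambda kv: -kv[1])
        if len(ranked_m) > d:
            cut = ranked_m[d - 1][1]
            keep_m = {s for s, v in ranked_m if v >= cut}
        else:
            keep_m = set(med_scores)
        kept = [(j, s) for (j, s) in scores if s in keep_m]
    elif unit == "pair":
        ranked = sorted(scores.items(), key=lambda kv: -kv[1])
        if len(ranked) > d:
            cut = ranked[d - 1][1]
            kept = [pair for pair, v in ranked if v >= cut]
            if len(kept) > d:
                logger.info("kept %d pairs (%d tied at the threshold)", len(kept), len(kept) - d)
        else:
            kept = [pair for pair, _ in ranked]
    else:
        raise ValueError("unit must be 'mediator' or 'pair'")

    J2 = {}
    for j, s in kept:
        J2.setdefault(s, []).append(j)
    S2 = sorted(J2)
    J2 = {s: sorted(J2[s]) for s in S2}
    logger.info(
        "step 2: %d candidates -> %d pairs (d=%d), |S2|=%d", len(scores), len(kept), d, len(S2)
    )
    return ScreenedPairs(
        S2=S2,
        J2=J2,
        scores={pair: scores[pair] for pair in kept},
        threshold_d=d,
        n_candidates=len(scores),
    )
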