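"""Step 3: final models, joint-significance testing and effect estimates.

With the screened sets fixed, the final outcome model includes all
Step-1 exposures, all screened mediators and the covariates,

    log T ~ X_{A_T} + M_{S2} + Z      (AFT maximum likelihood),

and each screened mediator gets its own covariate-adjusted regression

    M_s ~ X_{J2s} + Z                 (OLS).

For every screened pair (j, s) the composite null "alpha_js = 0 or
beta_Ms = 0" is tested with the joint-significance statistic
Pmax_{j,s} = max(P_alpha_js, P_beta_Ms); Benjamini-Hochberg adjustment
over all tested entries controls the FDR of the discovered pathways.

Effect estimates: the interventional direct effect (IDE) of exposure j
is beta_Xj from the final outcome model; the interventional indirect
effect (IIE) through mediator s is the product alpha_js * beta_Ms with
a delta-method (Sobel) standard error.  Both live on the log-survival-
time scale; by default they are reported per one standard deviation of
the exposure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .aft import AFTError, AFTFit, fit_aft
from .data_io import MediationDataset
from .penalized_screen import ActiveSets, PenaltySpec, step1
from .sis_screen import MediatorOLSFit, ScreenedPairs, fit_mediator_ols, screen_pairs

logger = logging.getLogger(__name__)

__all__ = [
    "SmahpConfig",
    "PmaxMatrix",
    "EffectEstimates",
    "MediationTestResult",
    "wald_pvalue",
    "pmax_combine",
    "bh_adjust",
    "fit_final_models",
    "estimate_effects",
    "run_smahp",
]

Z_95 = float(norm.ppf(0.975))


@dataclass
class SmahpConfig:
    """End-to-end pipeline settings with the method's defaults."""

    penalty_outcome: PenaltySpec = None
    penalty_mediation: PenaltySpec = None
    error_family: str = "log_normal"
    sis_multiplier: float = 1.0
    screen_unit: str = "pair"  # "pair" (global pair ranking) or "mediator"
    bh_family: str = "all_pairs"  # "all_pairs": m = p*k; "matrix": m = u*r
    q: float = 0.05
    effect_scale: str = "sd"  # "sd": per 1-SD exposure increase; "unit": per unit
    seed: int = 0

    def __post_init__(self):
        if self.penalty_outcome is None:
            self.penalty_outcome = PenaltySpec(family="elastic_net", alpha_mix=1.0)
        if self.penalty_mediation is None:
            self.penalty_mediation = PenaltySpec(family="mcp")
        if not (0.0 < self.q < 1.0):
            raise ValueError("q must be in (0, 1)")
        if self.effect_scale not in ("sd", "unit"):
            raise ValueError("effect_scale must be 'sd' or 'unit'")
        if self.bh_family not in ("all_pairs", "matrix"):
            raise ValueError("bh_family must be 'all_pairs' or 'matrix'")


@dataclass
class PmaxMatrix:
    """Joint-significance p-values for screened (exposure, mediator) pairs.

    Rows index the exposures appearing in any J2s, columns the mediators
    in S2.  Entries for pairs that were not screened carry no evidence
    (Pmax = 1); the BH adjustment runs over the full u x r matrix.
    """

    exposure_idx: list
    mediator_idx: list
    values: np.ndarray
    adjusted: np.ndarray
    tested: np.ndarray

    def entry(self, j: int, s: int):
        r = self.exposure_idx.index(j)
        c = self.mediator_idx.index(s)
        return self.values[r, c], self.adjusted[r, c]


@dataclass
class EffectEstimates:
    """IDE per exposure and IIE per screened pair, log-time scale, 95% CIs."""

    ide: pd.DataFrame
    iie: pd.DataFrame
    scale_note: str = "effects on the log survival-time scale"


@dataclass
class MediationTestResult:
    pmax: PmaxMatrix = None
    effects: EffectEstimates = None
    discoveries: list = field(default_factory=list)
    outcome_fit: AFTFit = None
    mediator_fits: dict = field(default_factory=dict)
    active: ActiveSets = None
    screened: ScreenedPairs = None
    stage: str = "complete"
    q: float = 0.05

    @property
    def empty(self) -> bool:
        return self.pmax is None

    def pair_table(self, dataset: MediationDataset = None) -> pd.DataFrame:
        """One row per tested pair, ids resolved against the dataset."""
        if self.empty:
            return pd.DataFrame(
                columns=["exposure", "mediator", "alpha", "alpha_se", "beta", "beta_se",
                         "iie", "iie_lo", "iie_hi", "pmax", "pmax_bh", "discovery"]
            )
        rows = []
        iie = self.effects.iie.set_index(["exposure_idx", "mediator_idx"])
        for s in self.screened.S2:
            for j in self.screened.J2[s]:
                raw, adj = self.pmax.entry(j, s)
                r = iie.loc[(j, s)]
                rows.append(
                    {
                        "exposure": dataset.X.feature_ids[j] if dataset else j,
                        "mediator": dataset.M.feature_ids[s] if dataset else s,
                        "alpha": r["alpha"],
                        "alpha_se": r["alpha_se"],
                        "beta": r["beta"],
                        "beta_se": r["beta_se"],
                        "iie": r["iie"],
                        "iie_lo": r["ci_lo"],
                        "iie_hi": r["ci_hi"],
                        "pmax": raw,
                        "pmax_bh": adj,
                        "discovery": (j, s) in set(self.discoveries),
                    }
                )
        return pd.DataFrame(rows)

    def ide_table(self, dataset: MediationDataset = None) -> pd.DataFrame:
        if self.empty or self.effects is None:
            return pd.DataFrame(columns=["exposure", "ide", "se", "ci_lo", "ci_hi", "p"])
        t = self.effects.ide.copy()
        if dataset is not None:
            t.insert(0, "exposure", [dataset.X.feature_ids[j] for j in t["exposure_idx"]])
        return t


def wald_pvalue(estimate: float, se: float) -> float:
    """Two-sided normal-reference p-value 2(1 - Phi(|estimate|/se))."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    return float(2.0 * norm.sf(abs(estimate) / se))


def pmax_combine(p_alpha: np.ndarray, p_beta: np.ndarray) -> np.ndarray:
    """Elementwise max of the exposure-side matrix and mediator-side vector."""
    p_alpha = np.asarray(p_alpha, dtype=float)
    p_beta = np.asarray(p_beta, dtype=float)
    if p_alpha.ndim != 2 or p_beta.ndim != 1 or p_alpha.shape[1] != p_beta.shape[0]:
        raise ValueError("p_alpha must be u x r and p_beta length r")
    for arr in (p_alpha, p_beta):
        vals = arr[np.isfinite(arr)]
        if np.any(vals < 0) or np.any(vals > 1):
            raise ValueError("p-values must lie in [0, 1]")
    return np.maximum(p_alpha, p_beta[None, :])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fit_final_models(
    dataset: MediationDataset,
    screened: ScreenedPairs,
    active: ActiveSets,
    error_family: str = "log_normal",
    strict: bool = True,
):
    """Fit the covariate-adjusted final outcome AFT and per-mediator OLS models."""
    if not screened.S2:
        raise ValueError("nothing to test: no screened mediators")
    n, q = dataset.n, dataset.Z.shape[1]
    n_terms = len(active.A_T) + len(screened.S2) + q + 1
    if n_terms + 1 >= n:
        raise AFTError(
            f"final design has {n_terms} terms for n={n}; "
            "reduce the SIS multiplier or tighten Step 1"
        )
    design = np.column_stack(
        [
            dataset.X.values[:, active.A_T],
            dataset.M.values[:, screened.S2],
            dataset.Z,
        ]
    )
    names = (
        [f"x{j}" for j in active.A_T]
        + [f"m{s}" for s in screened.S2]
        + [f"z{i}" for i in range(q)]
    )
    outcome_fit = fit_aft(
        design, dataset.outcome.log_time, dataset.outcome.event, names=names,
        family=error_family, strict=strict,
    )
    mediator_fits = {}
    for s in screened.S2:
        D = np.column_stack([dataset.X.values[:, screened.J2[s]], dataset.Z])
        Dn = np.column_stack([D, np.ones(n)])
        coef, _, _, _ = np.linalg.lstsq(Dn, dataset.M.values[:, s], rcond=None)
        resid = dataset.M.values[:, s] - Dn @ coef
        dof = n - Dn.shape[1]
        sigma2 = float(resid @ resid) / max(dof, 1)
        cov = sigma2 * np.linalg.inv(Dn.T @ Dn)
        se = np.sqrt(np.diag(cov))
        mediator_fits[s] = MediatorOLSFit(
            exposure_idx=list(screened.J2[s]),
            coefficients=coef[: len(screened.J2[s])],
            standard_errors=se[: len(screened.J2[s])],
        )
    return outcome_fit, mediator_fits


def _pmax_matrix(
    screened: ScreenedPairs, outcome_fit: AFTFit, mediator_fits, n_total_tests: int = None
) -> PmaxMatrix:
    exposures = sorted({j for s in screened.S2 for j in screened.J2[s]})
    mediators = list(screened.S2)
    u, r = len(exposures), len(mediators)
    p_alpha = np.full((u, r), np.nan)
    p_beta = np.empty(r)
    tested = np.zeros((u, r), dtype=bool)
    for c, s in enumerate(mediators):
        p_beta[c] = wald_pvalue(outcome_fit.coef(f"m{s}"), outcome_fit.se(f"m{s}"))
        fit_s = mediator_fits[s]
        for j in screened.J2[s]:
            rr = exposures.index(j)
            p_alpha[rr, c] = wald_pvalue(fit_s.coef(j), fit_s.se(j))
            tested[rr, c] = True
    values = pmax_combine(p_alpha, p_beta)
    # BH runs over the full hypothesis family: every candidate pair belongs
    # to it, and pairs that were screened out carry no evidence (Pmax = 1).
    full = np.where(tested, values, 1.0).ravel()
    m_total = max(int(n_total_tests or full.size), full.size)
    padded = np.concatenate([full, np.ones(m_total - full.size)])
    adjusted = bh_adjust(padded)[: full.size].reshape(values.shape)
    return PmaxMatrix(
        exposure_idx=exposures,
        mediator_idx=mediators,
        values=values,
        adjusted=adjusted,
        tested=tested,
    )


def estimate_effects(
    outcome_fit: AFTFit,
    mediator_fits: dict,
    screened: ScreenedPairs,
    active: ActiveSets,
    exposure_sds: np.ndarray = None,
    effect_scale: str = "sd",
) -> EffectEstimates:
    """IDE per Step-1 exposure and delta-method IIE per screened pair.

    IIE_(j,s) = alpha_js * beta_Ms with Sobel standard error
    sqrt(alpha^2 se_beta^2 + beta^2 se_alpha^2).  With
    ``effect_scale="sd"`` both effects are rescaled to a one-standard-
    deviation increase of the exposure.
    """
    def _scale(j):
        if effect_scale == "sd" and exposure_sds is not None:
            return float(exposure_sds[j])
        return 1.0

    ide_rows = []
    for j in active.A_T:
        est, se = outcome_fit.coef(f"x{j}"), outcome_fit.se(f"x{j}")
        c = _scale(j)
        est_s, se_s = est * c, se * c
        ide_rows.append(
            {
                "exposure_idx": j,
                "ide": est_s,
                "se": se_s,
                "ci_lo": est_s - Z_95 * se_s,
                "ci_hi": est_s + Z_95 * se_s,
                "p": wald_pvalue(est, se),
            }
        )
    iie_rows = []
    for s in screened.S2:
        beta, se_b = outcome_fit.coef(f"m{s}"), outcome_fit.se(f"m{s}")
        fit_s = mediator_fits[s]
        for j in screened.J2[s]:
            alpha, se_a = fit_s.coef(j), fit_s.se(j)
            c = _scale(j)
            est = alpha * beta * c
            se = float(np.sqrt(alpha**2 * se_b**2 + beta**2 * se_a**2)) * c
            iie_rows.append(
                {
                    "exposure_idx": j,
                    "mediator_idx": s,
                    "alpha": alpha * c,
                    "alpha_se": se_a * c,
                    "beta": beta,
                    "beta_se": se_b,
                    "iie": est,
                    "iie_se": se,
                    "ci_lo": est - Z_95 * se,
                    "ci_hi": est + Z_95 * se,
                }
            )
    cols_ide = ["exposure_idx", "ide", "se", "ci_lo", "ci_hi", "p"]
    cols_iie = ["exposure_idx", "mediator_idx", "alpha", "alpha_se", "beta", "beta_se",
                "iie", "iie_se", "ci_lo", "ci_hi"]
    return EffectEstimates(
        ide=pd.DataFrame(ide_rows, columns=cols_ide),
        iie=pd.DataFrame(iie_rows, columns=cols_iie),
    )


def bootstrap_iie(
    dataset: MediationDataset,
    screened: ScreenedPairs,
    active: ActiveSets,
    error_family: str = "log_normal",
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Nonparametric-bootstrap percentile CIs for the indirect effects.

    Resamples subjects with replacement, refits the final models with the
    selected sets held fixed, and returns per-pair percentile intervals —
    an alternative to the closed-form delta-method interval when the
    product's sampling distribution is visibly skewed.
    """
    rng = np.random.default_rng(seed)
    pairs = screened.pairs
    draws = np.full((n_boot, len(pairs)), np.nan)
    n = dataset.n
    from dataclasses import replace as _replace

    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if dataset.outcome.event[idx].sum() < 1:
            continue
        boot = MediationDataset(
            X=type(dataset.X)(dataset.X.values[idx], dataset.X.feature_ids,
                              [f"b{i}" for i in range(n)], dataset.X.layer),
            M=type(dataset.M)(dataset.M.values[idx], dataset.M.feature_ids,
                              [f"b{i}" for i in range(n)], dataset.M.layer),
            Z=dataset.Z[idx],
            covariate_names=dataset.covariate_names,
            outcome=dataset.outcome.subset(idx),
        )
        try:
            fit, med_fits = fit_final_models(boot, screened, active, error_family)
        except Exception:  # noqa: BLE001 - degenerate resample, skipped
            continue
        for c, (j, s) in enumerate(pairs):
            draws[b, c] = med_fits[s].coef(j) * fit.coef(f"m{s}")
    lo, hi = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
    rows = []
    for c, (j, s) in enumerate(pairs):
        ok = draws[~np.isnan(draws[:, c]), c]
        rows.append({
            "exposure_idx": j, "mediator_idx": s,
            "ci_lo": float(np.quantile(ok, lo)) if len(ok) else np.nan,
            "ci_hi": float(np.quantile(ok, hi)) if len(ok) else np.nan,
            "n_boot_ok": len(ok),
        })
    return pd.DataFrame(rows)


def run_smahp(dataset: MediationDataset, config: SmahpConfig = None) -> MediationTestResult:
    """Execute the full three-step pipeline on an assembled dataset."""
    config = config or SmahpConfig()
    active = step1(
        dataset,
        penalty_outcome=config.penalty_outcome,
        penalty_mediation=config.penalty_mediation,
        seed=config.seed,
    )
    if not active.S1 or active.n_pairs == 0:
        logger.info("pipeline stopped: no Step-1 candidates")
        return MediationTestResult(active=active, stage="step1_empty", q=config.q)

    screened = screen_pairs(
        dataset,
        active,
        error_family=config.error_family,
        multiplier=config.sis_multiplier,
        unit=config.screen_unit,
    )
    if not screened.S2:
        return MediationTestResult(active=active, screened=screened, stage="step2_empty",
                                   q=config.q)

    outcome_fit, mediator_fits = fit_final_models(
        dataset, screened, active, error_family=config.error_family
    )
    m_total = dataset.p * dataset.k if config.bh_family == "all_pairs" else None
    pmax = _pmax_matrix(screened, outcome_fit, mediator_fits, n_total_tests=m_total)
    discoveries = [
        (pmax.exposure_idx[r], pmax.mediator_idx[c])
        for r, c in np.argwhere(pmax.tested & (pmax.adjusted < config.q))
    ]
    effects = estimate_effects(
        outcome_fit,
        mediator_fits,
        screened,
        active,
        exposure_sds=dataset.X.values.std(axis=0),
        effect_scale=config.effect_scale,
    )
    logger.info(
        "step 3: tested %d pairs, %d discoveries at q=%.3g",
        int(pmax.tested.sum()),
        len(discoveries),
        config.q,
    )
    return MediationTestResult(
        pmax=pmax,
        effects=effects,
        discoveries=discoveries,
        outcome_fit=outcome_fit,
        mediator_fits=mediator_fits,
        active=active,
        screened=screened,
        stage="complete",
        q=config.q,
    )
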