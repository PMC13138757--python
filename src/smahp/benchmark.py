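"""Comparator methods and the replication harness for power/FDR studies.

Two baselines accompany the main pipeline:

* SIS + SIS: Step 1 is replaced by univariate marginal screens — one
  single-feature AFT model per mediator and per exposure (ranked by the
  Wald statistic, top n/log(n) kept per role), and one univariate
  exposure-mediator regression per candidate (top n/log(n) exposures per
  mediator).  Steps 2 and 3 then run unchanged.
* naive: every (gene, protein) pair is tested directly with marginal
  models (mediator ~ gene + Z, log T ~ protein + Z), joint-significance
  Pmax and BH across all p*k pairs — no penalization, no screening.

The replication harness runs each method over independently seeded
replicates of a simulation configuration and aggregates mean power and
FDR with Monte-Carlo standard errors.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aft import batch_univariate_aft
from .data_io import MediationDataset
from .js_inference import (
    MediationTestResult,
    SmahpConfig,
    bh_adjust,
    fit_final_models,
    _pmax_matrix,
    estimate_effects,
    run_smahp,
)
from .penalized_screen import ActiveSets
from .simulate import GroundTruth, SimulationConfig, simulate_dataset
from .sis_screen import screen_pairs, sis_threshold

logger = logging.getLogger(__name__)

__all__ = [
    "MethodResult",
    "BenchmarkSummary",
    "run_sis_sis",
    "run_naive",
    "evaluate_discoveries",
    "replicate_experiment",
]

METHODS = ("smahp", "sis_sis", "naive")


@dataclass
class MethodResult:
    discovered_pairs: set
    method: str
    runtime_seconds: float = 0.0
    detail: object = None


@dataclass
class BenchmarkSummary:
    table: pd.DataFrame
    n_reps: int
    seeds: list
    config: SimulationConfig
    failures: dict = field(default_factory=dict)


def run_smahp_method(dataset: MediationDataset, config: SmahpConfig = None) -> MethodResult:
    t0 = time.perf_counter()
    res = run_smahp(dataset, config)
    return MethodResult(
        discovered_pairs=set(res.discoveries),
        method="smahp",
        runtime_seconds=time.perf_counter() - t0,
        detail=res,
    )


def run_sis_sis(dataset: MediationDataset, config: SmahpConfig = None) -> MethodResult:
    """Marginal screens in place of Step 1, then the shared Steps 2-3."""
    config = config or SmahpConfig()
    t0 = time.perf_counter()
    n = dataset.n
    d = sis_threshold(n, config.sis_multiplier)
    y, ev = dataset.outcome.log_time, dataset.outcome.event

    med_scan = batch_univariate_aft(dataset.M.values, y, ev, family=config.error_family)
    S1 = _top_by_abs_z(med_scan, min(d, dataset.k))
    exp_scan = batch_univariate_aft(dataset.X.values, y, ev, family=config.error_family)
    A_T = _top_by_abs_z(exp_scan, min(d, dataset.p))

    # univariate exposure->mediator screen per selected mediator
    Xc = dataset.X.values - dataset.X.values.mean(axis=0)
    sx2 = np.sum(Xc * Xc, axis=0)
    J1 = {}
    for s in S1:
        m = dataset.M.values[:, s]
        mc = m - m.mean()
        with np.errstate(invalid="ignore", divide="ignore"):
            slopes = (Xc.T @ mc) / sx2
        slopes = np.nan_to_num(slopes)
        order = np.argsort(-np.abs(slopes), kind="stable")
        J1[s] = np.sort(order[: min(d, dataset.p)]).tolist()
    active = ActiveSets(S1=S1, A_T=A_T, J1=J1)

    # marginal screens keep n/log(n) features per role, so downstream designs
    # can be huge relative to the event count; accept non-converged refits the
    # way R's survreg would rather than abort the comparator
    screened = screen_pairs(
        dataset, active, error_family=config.error_family,
        multiplier=config.sis_multiplier, strict=False,
    )
    if not screened.S2:
        return MethodResult(set(), "sis_sis", time.perf_counter() - t0)
    outcome_fit, mediator_fits = fit_final_models(
        dataset, screened, active, error_family=config.error_family, strict=False
    )
    m_total = dataset.p * dataset.k if config.bh_family == "all_pairs" else None
    pmax = _pmax_matrix(screened, outcome_fit, mediator_fits, n_total_tests=m_total)
    discoveries = {
        (pmax.exposure_idx[r], pmax.mediator_idx[c])
        for r, c in np.argwhere(pmax.tested & (pmax.adjusted < config.q))
    }
    return MethodResult(discoveries, "sis_sis", time.perf_counter() - t0)


def _top_by_abs_z(scan: pd.DataFrame, d: int) -> list:
    order = np.argsort(-np.abs(scan["z"].to_numpy()), kind="stable")
    return np.sort(order[:d]).tolist()


def run_naive(dataset: MediationDataset, config: SmahpConfig = None) -> MethodResult:
    """All-pairs marginal joint-significance test, BH over p*k pairs."""
    config = config or SmahpConfig()
    t0 = time.perf_counter()
    n, p, k = dataset.n, dataset.p, dataset.k
    y, ev, Z = dataset.outcome.log_time, dataset.outcome.event, dataset.Z

    med_scan = batch_univariate_aft(dataset.M.values, y, ev, Z=Z, family=config.error_family)
    p_beta = med_scan["p"].to_numpy()

    # mediator ~ exposure + Z, solved for all mediators at once per exposure
    p_alpha = np.ones((p, k))
    M = dataset.M.values
    q = Z.shape[1]
    dof = n - (q + 2)
    for j in range(p):
        D = np.column_stack([dataset.X.values[:, j], Z, np.ones(n)])
        gram = D.T @ D
        try:
            gram_inv = np.linalg.inv(gram)
        except np.linalg.LinAlgError:
            continue  # constant exposure: pairs stay untested at p=1
        coefs = gram_inv @ (D.T @ M)  # (q+2, k)
        resid = M - D @ coefs
        sigma2 = np.sum(resid * resid, axis=0) / dof
        se = np.sqrt(np.maximum(gram_inv[0, 0] * sigma2, 1e-300))
        z = coefs[0] / se
        from scipy.stats import norm

        p_alpha[j] = 2.0 * norm.sf(np.abs(z))

    pmax = np.maximum(p_alpha, p_beta[None, :])
    adj = bh_adjust(pmax.ravel()).reshape(p, k)
    discoveries = {(int(j), int(s)) for j, s in np.argwhere(adj < config.q)}
    return MethodResult(discoveries, "naive", time.perf_counter() - t0)


def evaluate_discoveries(result: MethodResult, truth: GroundTruth):
    """(power, fdr) of a discovery set against the generating truth."""
    if not truth.true_pairs:
        raise ValueError("empty ground truth")
    disc = result.discovered_pairs
    power = len(disc & truth.true_pairs) / len(truth.true_pairs)
    fdr = len(disc - truth.true_pairs) / max(1, len(disc))
    return power, fdr


_RUNNERS = {
    "smahp": run_smahp_method,
    "sis_sis": run_sis_sis,
    "naive": run_naive,
}


def replicate_experiment(
    config: SimulationConfig,
    methods=("smahp", "sis_sis", "naive"),
    n_reps: int = 30,
    master_seed: int = 0,
    method_config: SmahpConfig = None,
) -> BenchmarkSummary:
    """Run each method on independently seeded replicates and aggregate.

    Replicate r uses dataset seed master_seed*100000 + r, so different
    master seeds give non-overlapping replicate streams while every
    method sees the same datasets.
    """
    for m in methods:
        if m not in _RUNNERS:
            raise ValueError(f"unknown method {m!r}; choose from {sorted(_RUNNERS)}")
    seeds = [int(master_seed) * 100_000 + r for r in range(n_reps)]
    records = {m: {"power": [], "fdr": [], "runtime": []} for m in methods}
    failures = {m: 0 for m in methods}
    for seed in seeds:
        from dataclasses import replace

        ds, truth = simulate_dataset(replace(config, seed=seed))
        for m in methods:
            try:
                mc = method_config or SmahpConfig(seed=seed)
                res = _RUNNERS[m](ds, mc)
                power, fdr = evaluate_discoveries(res, truth)
                records[m]["power"].append(power)
                records[m]["fdr"].append(fdr)
                records[m]["runtime"].append(res.runtime_seconds)
            except Exception:  # noqa: BLE001 - a failed replicate is recorded, not fatal
                logger.exception("method %s failed on seed %d", m, seed)
                failures[m] += 1
    rows = []
    for m in methods:
        pw = np.asarray(records[m]["power"])
        fd = np.asarray(records[m]["fdr"])
        rows.append(
            {
                "p": config.p,
                "k": config.k,
                "n": config.n,
                "censoring": config.censoring_target,
                "method": m,
                "power": pw.mean() if len(pw) else np.nan,
                "fdr": fd.mean() if len(fd) else np.nan,
                "mc_se_power": pw.std(ddof=1) / np.sqrt(len(pw)) if len(pw) > 1 else np.nan,
                "mc_se_fdr": fd.std(ddof=1) / np.sqrt(len(fd)) if len(fd) > 1 else np.nan,
                "mean_runtime_s": float(np.mean(records[m]["runtime"])) if records[m]["runtime"] else np.nan,
                "n_reps": len(pw),
                "failures": failures[m],
            }
        )
    return BenchmarkSummary(
        table=pd.DataFrame(rows), n_reps=n_reps, seeds=seeds, config=config,
        failures=failures,
    )
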