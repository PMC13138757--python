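"""Synthetic proteogenomic survival datasets with known mediation structure.

The generator emulates a proteogenomic study: gene-expression exposures
X (multivariate normal, mean 0.4, sd 0.5), two clinical covariates
(Z1 ~ N(0.12, 0.75^2), Z2 ~ Bernoulli(0.3)), and protein mediators M in
four blocks:

    A: 40% of proteins, driven by a 10% exposure subset (effect 0.8)
       plus both covariates (0.2 each), noise sd 0.5;
    B: 40%, driven by its own 10% exposure subset (effect 0.8), noise
       sd 0.3;
    C: 10%, covariates only (0.2 and 0.3), noise sd 0.5;
    D: 10%, pure noise, sd 0.3.

Survival times follow a log-linear AFT model
log T = beta_X'X + beta_M'M + beta_Z'Z + eps with effects 0.8 on a
small set of exposures, 4.0 on a small set of block-A/B mediators and
0.12 on both covariates; censoring times are exponential with the rate
calibrated by Monte Carlo to hit the requested censoring fraction.
Sensitivity variants: exchangeable exposure/mediator correlation,
negative-binomial exposures (dispersion 3), 2% uniform outliers, and
Gamma or logistic AFT errors (standardized to mean 0, sd 1 so effect
sizes stay comparable).

The ground truth (which (gene, protein) pairs carry a real mediated
path) is returned alongside the dataset for power/FDR scoring.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .data_io import MediationDataset, OmicsMatrix, SurvivalOutcome

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "gen_exposures",
    "gen_covariates",
    "gen_mediators",
    "calibrate_censoring",
    "gen_survival",
    "simulate_dataset",
]

_BLOCK_PROPS = (0.4, 0.4, 0.1)  # A, B, C; D takes the remainder


@dataclass
class SimulationConfig:
    """Generative settings; the defaults are the primary study conditions."""

    n: int = 200
    p: int = 50
    k: int = 100
    censoring_target: float = 0.25
    exposure_dist: str = "mvnormal"  # or "neg_binomial"
    exposure_mean: float = 0.4
    exposure_sd: float = 0.5
    exposure_corr: float = 0.0
    nb_dispersion: float = 3.0
    mediator_corr: float = 0.0
    outlier_fraction: float = 0.0
    error_family: str = "normal"  # "normal", "gamma", "logistic"
    effect_x_on_m: float = 0.8
    effect_z_on_m_a: tuple = (0.2, 0.2)
    effect_z_on_m_c: tuple = (0.2, 0.3)
    effect_x_on_t: float = 0.8
    effect_m_on_t: float = 4.0
    effect_z_on_t: float = 0.12
    n_true_x_on_t: int = 2
    n_true_m_on_t: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.k < 10:
            raise ValueError("need k >= 10 so the mediator blocks are non-degenerate")
        if self.p < 10:
            raise ValueError("need p >= 10 so the 10% exposure subsets are nonempty")
        if not (0.0 < self.censoring_target < 1.0):
            raise ValueError("censoring_target must be in (0, 1)")
        if self.exposure_dist not in ("mvnormal", "neg_binomial"):
            raise ValueError(f"unknown exposure_dist {self.exposure_dist!r}")
        if self.error_family not in ("normal", "gamma", "logistic"):
            raise ValueError(f"unknown error_family {self.error_family!r}")

    def block_sizes(self) -> tuple:
        a = round(_BLOCK_PROPS[0] * self.k)
        b = round(_BLOCK_PROPS[1] * self.k)
        c = round(_BLOCK_PROPS[2] * self.k)
        return a, b, c, self.k - a - b - c


@dataclass
class GroundTruth:
    """Generating coefficients and the set of genuinely mediated pairs."""

    true_pairs: set
    true_direct: set
    alpha_matrix: np.ndarray  # p x k exposure->mediator coefficients
    beta_m: np.ndarray  # k mediator->outcome coefficients
    beta_x: np.ndarray  # p exposure->outcome (direct) coefficients
    beta_z: np.ndarray
    blocks: dict = field(default_factory=dict)
    censoring_rate_realized: float = np.nan


def _rng_streams(seed, names):
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def gen_exposures(config: SimulationConfig, rng=None) -> np.ndarray:
    """Draw the n x p exposure matrix under the configured distribution."""
    rng = rng or np.random.default_rng(config.seed)
    n, p = config.n, config.p
    mu, sd, rho = config.exposure_mean, config.exposure_sd, config.exposure_corr
    if config.exposure_dist == "mvnormal":
        if rho > 0:
            shared = rng.normal(size=(n, 1))
            own = rng.normal(size=(n, p))
            X = mu + sd * (np.sqrt(rho) * shared + np.sqrt(1 - rho) * own)
        else:
            X = rng.normal(mu, sd, size=(n, p))
    else:
        disp = config.nb_dispersion
        prob = disp / (disp + mu)
        X = rng.negative_binomial(disp, prob, size=(n, p)).astype(float)
    if config.outlier_fraction > 0:
        n_out = round(config.outlier_fraction * n * p)
        flat = rng.choice(n * p, size=n_out, replace=False)
        lo = mu + 3 * sd
        X.flat[flat] = rng.uniform(lo, lo + 5.0, size=n_out)
    return X


def gen_covariates(n: int, seed=None, rng=None) -> np.ndarray:
    """Two covariates: Z1 ~ N(0.12, 0.75^2), Z2 ~ Bernoulli(0.3)."""
    rng = rng or np.random.default_rng(seed)
    z1 = rng.normal(0.12, 0.75, size=n)
    z2 = rng.binomial(1, 0.3, size=n).astype(float)
    return np.column_stack([z1, z2])


def gen_mediators(X: np.ndarray, Z: np.ndarray, config: SimulationConfig, rng=None):
    """Draw mediators in the four-block structure; returns (M, alpha, block map)."""
    rng = rng or np.random.default_rng(config.seed + 1)
    n, p = X.shape
    a, b, c, d = config.block_sizes()
    k = config.k
    n_hub = max(1, round(0.1 * p))
    hub_a = np.sort(rng.choice(p, size=n_hub, replace=False))
    hub_b = np.sort(rng.choice(p, size=n_hub, replace=False))

    alpha = np.zeros((p, k))
    zeta = np.zeros((Z.shape[1], k))
    noise_sd = np.empty(k)
    blocks = {}
    idx = 0
    for name, size in zip("ABCD", (a, b, c, d)):
        blocks[name] = list(range(idx, idx + size))
        idx += size
    alpha[np.ix_(hub_a, blocks["A"])] = config.effect_x_on_m
    alpha[np.ix_(hub_b, blocks["B"])] = config.effect_x_on_m
    zeta[:, blocks["A"]] = np.asarray(config.effect_z_on_m_a)[:, None]
    zeta[:, blocks["C"]] = np.asarray(config.effect_z_on_m_c)[:, None]
    noise_sd[blocks["A"]] = 0.5
    noise_sd[blocks["B"]] = 0.3
    noise_sd[blocks["C"]] = 0.5
    noise_sd[blocks["D"]] = 0.3

    rho = config.mediator_corr
    if rho > 0:
        shared = rng.normal(size=(n, 1))
        own = rng.normal(size=(n, k))
        noise = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
    else:
        noise = rng.normal(size=(n, k))
    M = X @ alpha + Z @ zeta + noise * noise_sd[None, :]
    blocks["hub_a"] = hub_a.tolist()
    blocks["hub_b"] = hub_b.tolist()
    return M, alpha, blocks


def _standardized_error(family: str, rng, size):
    """AFT error draws standardized to mean 0, sd 1."""
    if family == "normal":
        return rng.normal(size=size)
    if family == "gamma":
        shape = 2.0
        g = rng.gamma(shape, 1.0, size=size)
        return (g - shape) / np.sqrt(shape)
    if family == "logistic":
        return rng.logistic(0.0, np.sqrt(3.0) / np.pi, size=size)
    raise ValueError(f"unknown error family {family!r}")


def calibrate_censoring(
    latent_time_sampler,
    target: float,
    tol: float = 0.01,
    n_draws: int = 100_000,
    seed: int = 12345,
) -> float:
    """Exponential censoring rate hitting the target censoring fraction.

    With C ~ Exp(rate), P(censored | T) = 1 - exp(-rate * T), so the
    expected censoring fraction is a monotone function of the rate;
    we root-find it on a Monte-Carlo sample of latent event times.
    """
    rng = np.random.default_rng(seed)
    times = np.asarray(latent_time_sampler(rng, n_draws), dtype=float)
    if np.any(times <= 0):
        raise ValueError("latent time sampler produced non-positive times")
    logt = np.log(times)

    def frac(log_rate):
        # censoring probability per draw, computed on the log scale for range safety
        x = np.clip(log_rate + logt, -700, 700)
        return float(np.mean(-np.expm1(-np.exp(x)))) - target

    lo, hi = -80.0, 80.0
    if frac(lo) > 0 or frac(hi) < 0:
        raise ValueError(f"censoring target {target} unreachable for these times")
    log_rate = brentq(frac, lo, hi, xtol=1e-10)
    realized = frac(log_rate) + target
    if abs(realized - target) > tol:
        raise RuntimeError("censoring calibration did not reach the target tolerance")
    return float(np.exp(log_rate))


def _latent_log_time(X, M, Z, truth: GroundTruth, eps):
    return X @ truth.beta_x + M @ truth.beta_m + Z @ truth.beta_z + eps


_rate_cache: dict = {}


def _config_rate_key(config: SimulationConfig):
    fields = (
        config.p, config.k, config.censoring_target, config.exposure_dist,
        config.exposure_mean, config.exposure_sd, config.exposure_corr,
        config.nb_dispersion, config.mediator_corr, config.outlier_fraction,
        config.error_family, config.effect_x_on_m, tuple(config.effect_z_on_m_a),
        tuple(config.effect_z_on_m_c), config.effect_x_on_t, config.effect_m_on_t,
        config.effect_z_on_t, config.n_true_x_on_t, config.n_true_m_on_t,
    )
    return fields


def gen_survival(X, M, Z, config: SimulationConfig, alpha=None, blocks=None, rng=None):
    """Draw the censored survival outcome; returns (outcome, truth).

    The outcome-associated exposures and mediators are drawn at random
    (mediators from blocks A and B, so every selected mediator carries a
    real upstream path and the mediated pairs exist by construction).
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    n, p = X.shape
    k = M.shape[1]
    if alpha is None:
        alpha = np.zeros((p, k))
    if blocks is None:
        blocks = {"A": list(range(k)), "B": []}

    beta_x = np.zeros(p)
    true_x = np.sort(rng.choice(p, size=config.n_true_x_on_t, replace=False))
    beta_x[true_x] = config.effect_x_on_t
    ab = np.asarray(blocks["A"] + blocks["B"])
    beta_m = np.zeros(k)
    true_m = np.sort(rng.choice(ab, size=config.n_true_m_on_t, replace=False))
    beta_m[true_m] = config.effect_m_on_t
    beta_z = np.full(Z.shape[1], config.effect_z_on_t)

    true_pairs = {
        (j, int(s))
        for s in true_m
        if beta_m[s] != 0.0
        for j in np.flatnonzero(alpha[:, s] != 0.0)
    }
    truth = GroundTruth(
        true_pairs=true_pairs,
        true_direct=set(int(j) for j in true_x if beta_x[j] != 0.0),
        alpha_matrix=alpha,
        beta_m=beta_m,
        beta_x=beta_x,
        beta_z=beta_z,
        blocks=dict(blocks),
    )

    eps = _standardized_error(config.error_family, rng, n)
    log_t = _latent_log_time(X, M, Z, truth, eps)

    key = _config_rate_key(config) + (tuple(true_m.tolist()), tuple(true_x.tolist()))
    rate = _rate_cache.get(key)
    if rate is None:
        cal_seed = int(
            np.frombuffer(
                hashlib.sha256(repr(key).encode()).digest()[:4], dtype=np.uint32
            )[0]
            % (2**31)
        )

        def sampler(cal_rng, size):
            out = np.empty(size)
            done = 0
            sub = replace(config, n=min(size, 20_000))
            while done < size:
                m_draw = min(20_000, size - done)
                sub_c = replace(sub, n=m_draw)
                Xs = gen_exposures(sub_c, rng=cal_rng)
                Zs = gen_covariates(m_draw, rng=cal_rng)
                Ms = Xs @ alpha + Zs @ _zeta_from(blocks, config, k) + _mediator_noise(
                    sub_c, cal_rng, m_draw, k, blocks
                )
                e = _standardized_error(config.error_family, cal_rng, m_draw)
                out[done : done + m_draw] = np.exp(
                    np.clip(_latent_log_time(Xs, Ms, Zs, truth, e), -700, 700)
                )
                done += m_draw
            return out

        rate = calibrate_censoring(sampler, config.censoring_target, seed=cal_seed)
        _rate_cache[key] = rate

    censor = rng.exponential(1.0 / rate, size=n)
    t_event = np.exp(np.clip(log_t, -700, 700))
    time = np.minimum(t_event, censor)
    event = (t_event <= censor).astype(float)
    outcome = SurvivalOutcome(time=time, event=event)
    truth.censoring_rate_realized = outcome.censoring_rate
    return outcome, truth


def _zeta_from(blocks, config, k):
    zeta = np.zeros((2, k))
    zeta[:, blocks.get("A", [])] = np.asarray(config.effect_z_on_m_a)[:, None]
    zeta[:, blocks.get("C", [])] = np.asarray(config.effect_z_on_m_c)[:, None]
    return zeta


def _mediator_noise(config, rng, n, k, blocks):
    sd = np.empty(k)
    sd[blocks.get("A", [])] = 0.5
    sd[blocks.get("B", [])] = 0.3
    sd[blocks.get("C", [])] = 0.5
    sd[blocks.get("D", [])] = 0.3
    rho = config.mediator_corr
    if rho > 0:
        noise = np.sqrt(rho) * rng.normal(size=(n, 1)) + np.sqrt(1 - rho) * rng.normal(
            size=(n, k)
        )
    else:
        noise = rng.normal(size=(n, k))
    return noise * sd[None, :]


def simulate_dataset(config: SimulationConfig):
    """Generate a full dataset + ground truth from one master seed."""
    streams = _rng_streams(config.seed, ("exposures", "covariates", "mediators", "survival"))
    X = gen_exposures(config, rng=streams["exposures"])
    Z = gen_covariates(config.n, rng=streams["covariates"])
    M, alpha, blocks = gen_mediators(X, Z, config, rng=streams["mediators"])
    outcome, truth = gen_survival(
        X, M, Z, config, alpha=alpha, blocks=blocks, rng=streams["survival"]
    )
    samples = [f"S{i:05d}" for i in range(config.n)]
    dataset = MediationDataset(
        X=OmicsMatrix(X, [f"G{j:05d}" for j in range(config.p)], samples, "exposure"),
        M=OmicsMatrix(M, [f"P{s:05d}" for s in range(config.k)], samples, "mediator"),
        Z=Z,
        covariate_names=["Z1", "Z2"],
        outcome=outcome,
    )
    logger.info(
        "simulated n=%d p=%d k=%d censoring %.3f (target %.2f), %d true pairs",
        config.n, config.p, config.k, outcome.censoring_rate,
        config.censoring_target, len(truth.true_pairs),
    )
    return dataset, truth
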