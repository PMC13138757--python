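import numpy as np
import pytest

from smahp.data_io import MediationDataset, OmicsMatrix, SurvivalOutcome


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def censored_outcome(rng):
    """A small censored survival outcome with a known linear signal."""
    n = 120
    X = rng.normal(size=(n, 4))
    log_t = X @ np.array([0.8, -0.5, 0.0, 0.0]) + rng.normal(size=n)
    t = np.exp(log_t)
    c = rng.exponential(np.median(t) * 2.0, size=n)
    time = np.minimum(t, c)
    event = (t <= c).astype(float)
    return X, SurvivalOutcome(time, event)


def make_dataset(X, M, Z, outcome) -> MediationDataset:
    n = outcome.n
    samples = [f"s{i}" for i in range(n)]
    return MediationDataset(
        X=OmicsMatrix(X, [f"g{j}" for j in range(X.shape[1])], samples, "exposure"),
        M=OmicsMatrix(M, [f"p{j}" for j in range(M.shape[1])], samples, "mediator"),
        Z=Z,
        covariate_names=[f"z{q}" for q in range(np.atleast_2d(Z).shape[1] if Z.size else 0)],
        outcome=outcome,
    )


@pytest.fixture
def single_pathway_dataset(rng):
    """One dominant noiseless-ish pathway g0 -> p0 -> T among noise features."""
    n, p, k = 150, 8, 6
    X = rng.normal(size=(n, p))
    M = rng.normal(size=(n, k)) * 0.5
    M[:, 0] = 1.2 * X[:, 0] + 0.05 * rng.normal(size=n)
    log_t = 2.0 * M[:, 0] + 0.3 * rng.normal(size=n)
    t = np.exp(log_t)
    c = rng.exponential(np.quantile(t, 0.9) * 3.0, size=n)
    outcome = SurvivalOutcome(np.minimum(t, c), (t <= c).astype(float))
    Z = np.column_stack([rng.normal(size=n), rng.binomial(1, 0.3, size=n).astype(float)])
    return make_dataset(X, M, Z, outcome)
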