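"""Reading omics matrices and clinical tables, and dataset assembly.

The analysis-ready container is :class:`MediationDataset`: exposures X
(n x P genes), mediators M (n x K proteins), covariates Z (n x Q) and a
censored survival outcome, all aligned on a shared sample ordering.

Also provides :func:`marginal_prescreen`, the univariate-AFT ranking
used to cut ultra-high-dimensional inputs (tens of thousands of genes)
down to a workable feature set before the mediation pipeline runs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aft import AFTError, batch_univariate_aft

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalOutcome",
    "OmicsMatrix",
    "MediationDataset",
    "read_expression_matrix",
    "write_expression_matrix",
    "assemble_dataset",
    "marginal_prescreen",
]


@dataclass
class SurvivalOutcome:
    """Per-sample follow-up time and event indicator.

    ``event`` is 1 when the event was observed and 0 when censored;
    ``log_time`` is the natural log of ``time``.
    """

    time: np.ndarray
    event: np.ndarray
    log_time: np.ndarray = field(init=False)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=float)
        if np.any(self.time <= 0):
            raise ValueError("survival times must be positive")
        if not np.all(np.isin(self.event, (0.0, 1.0))):
            raise ValueError("event indicator must be 0 or 1")
        if self.time.shape != self.event.shape:
            raise ValueError("time and event must have the same length")
        self.log_time = np.log(self.time)

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def censoring_rate(self) -> float:
        return 1.0 - float(self.event.mean())

    def subset(self, idx) -> "SurvivalOutcome":
        return SurvivalOutcome(self.time[idx], self.event[idx])


@dataclass
class OmicsMatrix:
    """A samples x features numeric matrix with identifiers.

    ``layer`` labels the role of the matrix: "exposure" (genes) or
    "mediator" (proteins).
    """

    values: np.ndarray
    feature_ids: list
    sample_ids: list
    layer: str = "exposure"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = list(self.feature_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, d = self.values.shape
        if len(self.sample_ids) != n or len(self.feature_ids) != d:
            raise ValueError("id lengths do not match matrix shape")
        dupes = _duplicates(self.feature_ids)
        if dupes:
            raise ValueError(f"duplicate feature ids: {sorted(dupes)}")
        if len(set(self.sample_ids)) != n:
            raise ValueError(f"duplicate sample ids: {sorted(_duplicates(self.sample_ids))}")
        if n < 2:
            raise ValueError("need at least 2 samples")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)


@dataclass
class MediationDataset:
    """Aligned exposures, mediators, covariates and survival outcome."""

    X: OmicsMatrix
    M: OmicsMatrix
    Z: np.ndarray
    covariate_names: list
    outcome: SurvivalOutcome
    sample_ids: list = None

    def __post_init__(self):
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim == 1:
            self.Z = self.Z[:, None]
        n = self.outcome.n
        if not (self.X.n == self.M.n == self.Z.shape[0] == n):
            raise ValueError("all components must share the same number of samples")
        if self.sample_ids is None:
            self.sample_ids = list(self.X.sample_ids)
        if list(self.X.sample_ids) != list(self.M.sample_ids):
            raise ValueError("X and M sample orderings differ")

    @property
    def n(self) -> int:
        return self.outcome.n

    @property
    def p(self) -> int:
        return self.X.n_features

    @property
    def k(self) -> int:
        return self.M.n_features


def _duplicates(items):
    seen, dup = set(), set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def read_expression_matrix(
    path, orientation: str = "features_in_rows", layer: str = "exposure", sep: str = None
) -> OmicsMatrix:
    """Read a delimited expression matrix into samples x features orientation.

    ``orientation`` declares the layout of the file; the returned matrix
    is always samples x features.  The first column holds row ids and the
    header holds column ids.
    """
    if orientation not in ("features_in_rows", "samples_in_rows"):
        raise ValueError("orientation must be 'features_in_rows' or 'samples_in_rows'")
    df = pd.read_csv(path, sep=sep, index_col=0, engine="python")
    bad = df.map(lambda v: not _is_number(v))
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at row {df.index[i]!r}, column {df.columns[j]!r} in {path}"
        )
    df = df.astype(float)
    if orientation == "features_in_rows":
        df = df.T
    return OmicsMatrix(
        values=df.to_numpy(),
        feature_ids=list(df.columns),
        sample_ids=list(df.index),
        layer=layer,
    )


def write_expression_matrix(matrix: OmicsMatrix, path, orientation: str = "features_in_rows"):
    """Write an OmicsMatrix as TSV in the requested orientation."""
    df = matrix.to_frame()
    if orientation == "features_in_rows":
        df = df.T
    df.to_csv(path, sep="\t")


def _is_number(v):
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def assemble_dataset(
    X: OmicsMatrix,
    M: OmicsMatrix,
    clinical: pd.DataFrame,
    time_col: str,
    event_col: str,
    covariate_cols=(),
    sample_col: str = None,
) -> MediationDataset:
    """Intersect samples across the three sources and build the dataset.

    Samples missing time or event are dropped (with a logged count), as
    are features containing missing values.  Sample ids are matched by
    exact string equality and the result uses the sorted common ids as
    its canonical ordering.
    """
    clin = clinical.copy()
    if sample_col is not None:
        clin = clin.set_index(sample_col)
    clin.index = clin.index.astype(str)

    common = sorted(set(map(str, X.sample_ids)) & set(map(str, M.sample_ids)) & set(clin.index))
    if not common:
        raise ValueError("no samples shared between expression matrices and clinical table")

    clin = clin.loc[common]
    with_outcome = clin[[time_col, event_col]].notna().all(axis=1)
    n_dropped = int((~with_outcome).sum())
    if n_dropped:
        logger.info("excluded %d samples with missing survival time/event", n_dropped)
    keep = [s for s, ok in zip(common, with_outcome) if ok]
    if len(keep) < 2:
        raise ValueError("fewer than 2 samples with complete outcome data")
    clin = clin.loc[keep]

    def _slice(mat: OmicsMatrix) -> OmicsMatrix:
        frame = mat.to_frame()
        frame.index = frame.index.astype(str)
        frame = frame.loc[keep]
        na_features = frame.columns[frame.isna().any(axis=0)]
        if len(na_features):
            warnings.warn(
                f"dropping {len(na_features)} {mat.layer} features with missing values",
                stacklevel=3,
            )
            frame = frame.drop(columns=na_features)
        return OmicsMatrix(frame.to_numpy(), list(frame.columns), list(frame.index), mat.layer)

    Xs, Ms = _slice(X), _slice(M)
    covariate_cols = list(covariate_cols)
    Z = clin[covariate_cols].to_numpy(dtype=float) if covariate_cols else np.empty((len(keep), 0))
    outcome = SurvivalOutcome(
        time=clin[time_col].to_numpy(dtype=float),
        event=clin[event_col].to_numpy(dtype=float),
    )
    ds = MediationDataset(
        X=Xs, M=Ms, Z=Z, covariate_names=covariate_cols, outcome=outcome, sample_ids=keep
    )
    ds.n_excluded = n_dropped
    return ds


def marginal_prescreen(
    features: OmicsMatrix,
    outcome: SurvivalOutcome,
    top_m: int,
    error_family: str = "log_normal",
) -> list:
    """Rank features by the Wald p-value of a single-feature AFT model.

    Fits one univariate parametric AFT model (log T ~ feature) per
    feature and returns the ``top_m`` ids with the smallest p-values.
    Constant features get p = 1, so they can never outrank an informative
    feature.  Ties are broken by lexicographic feature id.
    """
    if top_m > features.n_features:
        raise ValueError(f"top_m={top_m} exceeds number of features {features.n_features}")
    sds = features.values.std(axis=0)
    if np.all(sds < 1e-12):
        raise AFTError("all features are constant; nothing to pre-screen")
    res = batch_univariate_aft(features.values, outcome.log_time, outcome.event, family=error_family)
    order = pd.DataFrame({"id": features.feature_ids, "p": res["p"].to_numpy()})
    order = order.sort_values(["p", "id"], kind="mergesort")
    return order["id"].head(top_m).tolist()
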