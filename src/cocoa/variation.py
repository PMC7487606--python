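"""Step 1: feature contribution scores (FCS) and unsupervised targets.

Each locus gets a score per target variable quantifying how strongly its
signal covaries with that target across samples — covariance, Pearson, or
Spearman correlation. Missing cells are handled pairwise-complete; loci
with fewer than three complete pairs get a missing FCS. When no target is
supplied, per-sample principal component scores stand in as targets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.decomposition import PCA

from .io import SignalMatrix, TargetVariableSet

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureContributionScores",
    "compute_fcs",
    "fcs_matrix",
    "pca_targets",
    "recommend_metric",
]

METRICS = ("covariance", "pearson", "spearman")
MIN_COMPLETE_PAIRS = 3


@dataclass
class FeatureContributionScores:
    """Per-locus, per-target association scores aligned to a SignalMatrix."""

    values: np.ndarray  # (n_loci, n_targets)
    target_names: list[str]
    metric: str
    abs_applied: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        if self.values.shape[1] != len(self.target_names):
            raise ValueError("target_names must match value columns")
        if self.metric in ("pearson", "spearman"):
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
                raise ValueError("correlation FCS must lie in [-1, 1]")


def _pairwise_stats(
    X: np.ndarray, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise-complete (n, cov, var_x, var_t) for every row of X vs t.

    All sums run over each row's complete pairs only; rows with fewer than
    MIN_COMPLETE_PAIRS pairs yield NaN moments.
    """
    tmask = np.isfinite(t)
    M = np.isfinite(X) & tmask[None, :]
    n = M.sum(axis=1).astype(float)
    X0 = np.where(M, X, 0.0)
    t0 = np.where(tmask, t, 0.0)
    Sx = X0.sum(axis=1)
    Sxx = (X0 * X0).sum(axis=1)
    St = M @ t0
    Stt = M @ (t0 * t0)
    Sxy = X0 @ t0
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = (Sxy - Sx * St / n) / (n - 1)
        var_x = (Sxx - Sx * Sx / n) / (n - 1)
        var_t = (Stt - St * St / n) / (n - 1)
    bad = n < MIN_COMPLETE_PAIRS
    for arr in (cov, var_x, var_t):
        arr[bad] = np.nan
    # tiny negative variances are rounding noise
    var_x = np.maximum(var_x, 0.0)
    var_t = np.maximum(var_t, 0.0)
    return n, cov, var_x, var_t


def _pairwise_stats_multi(
    X: np.ndarray, T: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (n, cov, var_x, var_t) for every row of X against every
    column of T, valid when T contains no missing values (each row's
    complete-pair set is then independent of the target column)."""
    M = np.isfinite(X)
    n = M.sum(axis=1).astype(float)[:, None]
    X0 = np.where(M, X, 0.0)
    Sx = X0.sum(axis=1)[:, None]
    Sxx = (X0 * X0).sum(axis=1)[:, None]
    Mf = M.astype(float)
    St = Mf @ T
    Stt = Mf @ (T * T)
    Sxy = X0 @ T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = (Sxy - Sx * St / n) / (n - 1)
        var_x = (Sxx - Sx * Sx / n) / (n - 1)
        var_t = (Stt - St * St / n) / (n - 1)
    bad = (n < MIN_COMPLETE_PAIRS).ravel()
    for arr in (cov, var_x, var_t):
        arr[bad, :] = np.nan
    var_x = np.maximum(var_x, 0.0)
    var_t = np.maximum(var_t, 0.0)
    return n, cov, var_x, var_t


def fcs_matrix(X: np.ndarray, T: np.ndarray, metric: str) -> np.ndarray:
    """FCS of every locus (row of X) against every target (column of T).

    The covariance/Pearson path is fully vectorized when T is complete;
    otherwise each target column falls back to the single-target path.
    Spearman is computed column by column (ranks depend on the column).
    """
    X = np.asarray(X, float)
    T = np.asarray(T, float)
    if T.ndim == 1:
        T = T[:, None]
    if metric == "spearman" or not np.isfinite(T).all():
        return np.column_stack(
            [_fcs_one_target(X, T[:, j], metric) for j in range(T.shape[1])]
        )
    _, cov, var_x, var_t = _pairwise_stats_multi(X, T)
    if metric == "covariance":
        return cov
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(var_x * var_t)
    r[(var_x == 0) | (var_t == 0)] = np.nan
    return np.clip(r, -1.0, 1.0)


def _fcs_one_target(X: np.ndarray, t: np.ndarray, metric: str) -> np.ndarray:
    if metric == "spearman":
        return _spearman_column(X, t)
    n, cov, var_x, var_t = _pairwise_stats(X, t)
    if metric == "covariance":
        return cov
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(var_x * var_t)
    r[(var_x == 0) | (var_t == 0)] = np.nan
    return np.clip(r, -1.0, 1.0)


def _spearman_column(X: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Pairwise-complete Spearman: Pearson on average ranks.

    Rows with no missing signal share one complete-sample subset, so the
    target is ranked once and those rows go through the vectorized path.
    Rows with missing cells need the target re-ranked on their own subset.
    """
    tmask = np.isfinite(t)
    out = np.full(X.shape[0], np.nan)
    row_complete = np.isfinite(X[:, tmask]).all(axis=1)
    if row_complete.any():
        sub = X[np.ix_(row_complete, tmask)]
        rx = rankdata(sub, axis=1)
        rt = rankdata(t[tmask])
        out[row_complete] = _fcs_one_target(rx, rt, "pearson")
    for i in np.flatnonzero(~row_complete):
        m = np.isfinite(X[i]) & tmask
        if m.sum() < MIN_COMPLETE_PAIRS:
            continue
        rx = rankdata(X[i, m])
        rt = rankdata(t[m])
        out[i] = _fcs_one_target(rx[None, :], rt, "pearson")[0]
    return out


def compute_fcs(
    signal: SignalMatrix | np.ndarray,
    targets: TargetVariableSet | np.ndarray,
    metric: str = "covariance",
) -> FeatureContributionScores:
    """Associate every locus with every target variable.

    Covariance uses the unbiased (n-1) denominator; Spearman uses average
    ranks for ties. A target constant across samples is an error for the
    correlation metrics (undefined) and yields zero FCS with a warning for
    covariance, so degenerate permutation shuffles cannot crash a run.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    X = signal.values if isinstance(signal, SignalMatrix) else np.asarray(signal, float)
    if isinstance(targets, TargetVariableSet):
        if isinstance(signal, SignalMatrix):
            targets = targets.aligned_to(signal.sample_ids)
        T = targets.values
        names = list(targets.target_names)
    else:
        T = np.asarray(targets, float)
        if T.ndim == 1:
            T = T[:, None]
        names = [f"target{j + 1}" for j in range(T.shape[1])]
    if X.shape[1] != T.shape[0]:
        raise ValueError(
            f"signal has {X.shape[1]} samples but targets have {T.shape[0]}"
        )
    if X.shape[1] < MIN_COMPLETE_PAIRS:
        raise ValueError(f"need at least {MIN_COMPLETE_PAIRS} samples")
    out = np.empty((X.shape[0], T.shape[1]))
    for j in range(T.shape[1]):
        t = T[:, j]
        finite = t[np.isfinite(t)]
        if finite.size and np.ptp(finite) == 0:
            if metric == "covariance":
                warnings.warn(
                    f"target {names[j]!r} is constant; covariance FCS set to 0",
                    stacklevel=2,
                )
                out[:, j] = 0.0
                continue
            raise ValueError(
                f"target {names[j]!r} is constant; {metric} is undefined"
            )
        out[:, j] = _fcs_one_target(X, t, metric)
    n_missing = int(np.isnan(out).any(axis=1).sum())
    if n_missing:
        logger.info(
            "%d loci have missing FCS (insufficient complete pairs or zero variance)",
            n_missing,
        )
    return FeatureContributionScores(
        values=out, target_names=names, metric=metric
    )


def pca_targets(
    signal: SignalMatrix,
    n_components: int = 2,
    center: bool = True,
    scale: bool = False,
) -> TargetVariableSet:
    """Per-sample principal component scores of the signal matrix.

    Samples are observations, loci are variables. Loci with any missing
    value are dropped before the decomposition (count logged). ``scale``
    divides each locus by its standard deviation, making the decomposition
    equivalent to one on the correlation matrix — recommended for
    count-like data, off for bounded methylation data. Component sign is
    fixed so each component's largest-magnitude loading is positive.
    """
    X = signal.values.T  # samples x loci
    complete = np.isfinite(X).all(axis=0)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("dropping %d loci with missing values before PCA", n_dropped)
        X = X[:, complete]
    if X.shape[1] == 0:
        raise ValueError("no complete loci available for PCA")
    max_comp = min(X.shape)
    if n_components > max_comp:
        raise ValueError(
            f"n_components={n_components} exceeds min(samples, loci)={max_comp}"
        )
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            logger.warning(
                "dropping %d zero-variance loci before scaled PCA",
                int((~keep).sum()),
            )
            X = X[:, keep]
            sd = sd[keep]
        X = X / sd
    # sklearn's PCA centers internally either way, so rank is judged on
    # the column-centered matrix
    rank = np.linalg.matrix_rank(X - X.mean(axis=0))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds data rank {rank}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_
    for k in range(n_components):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            scores[:, k] = -scores[:, k]
            loadings[k] = -loadings[k]
    return TargetVariableSet(
        values=scores,
        target_names=[f"PC{k + 1}" for k in range(n_components)],
        sample_ids=list(signal.sample_ids),
    )


def recommend_metric(resolution: str, target_kind: str = "latent_factor") -> str:
    """Advisory metric choice by data type and target kind.

    Bounded nucleotide-resolution signal (methylation beta values) favours
    covariance, weighting loci by their dynamic range; region/count-like
    signal favours Pearson so peaks score comparably regardless of range;
    ordinal targets favour Spearman (monotone, not necessarily linear).
    Never overrides an explicit user choice.
    """
    if resolution not in ("nucleotide", "region"):
        raise ValueError(f"unknown resolution {resolution!r}")
    if target_kind not in ("continuous", "ordinal", "latent_factor"):
        raise ValueError(f"unknown target kind {target_kind!r}")
    if target_kind == "ordinal":
        return "spearman"
    return "covariance" if resolution == "nucleotide" else "pearson"
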