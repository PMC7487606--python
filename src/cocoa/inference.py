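"""Permutation significance for region-set scores.

For each permutation the samples' target values are shuffled jointly across
all target columns (one shared label permutation), the feature contribution
scores are recomputed, and every surviving region set is rescored. The
epigenetic matrix itself is never shuffled, so each region set's null
distribution preserves the inter-locus correlation structure and the set's
own coverage profile.

Tail p-values come from a gamma distribution fit to each null by the method
of moments (shape = mean^2/var, scale = var/mean), which extrapolates beyond
the permutation count; the approximation is accurate for high p-values but
can overestimate the significance of very low ones, so the conservative
add-one empirical p-value remains available and is the automatic fallback
whenever the gamma fit is refused (negative scores or degenerate nulls).
Benjamini-Hochberg FDR correction is applied per target across all scored
region sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import RegionSetDatabase
from .io import SignalMatrix, TargetVariableSet
from .scoring import RegionSetIndex, build_indexes
from .variation import fcs_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "NullDistribution",
    "build_null",
    "fit_gamma_mom",
    "gamma_pvalue",
    "empirical_pvalue",
    "adjust_fdr",
    "attach_significance",
]

DEFAULT_N_PERM = 300
_PERM_CHUNK = 1024  # columns of the permuted-target matrix per FCS pass


@dataclass
class NullDistribution:
    """Region-set-specific null: permuted scores plus optional gamma fit."""

    region_set: str
    target: str
    scores: np.ndarray
    gamma_shape: float | None = None
    gamma_scale: float | None = None

    @property
    def has_gamma(self) -> bool:
        return self.gamma_shape is not None and self.gamma_scale is not None


def fit_gamma_mom(scores: np.ndarray) -> tuple[float, float]:
    """Method-of-moments gamma fit: shape = mean^2/var, scale = var/mean.

    Uses the unbiased sample variance. The fit is refused (ValueError) for
    negative scores, zero variance, or nonpositive mean — callers fall back
    to the empirical p-value.
    """
    scores = np.asarray(scores, float)
    scores = scores[np.isfinite(scores)]
    if scores.size < 2:
        raise ValueError("need at least 2 finite null scores for a gamma fit")
    if (scores < 0).any():
        raise ValueError("gamma fit refused: negative null scores")
    mean = scores.mean()
    var = scores.var(ddof=1)
    if var <= 0 or mean <= 0:
        raise ValueError("gamma fit refused: degenerate null distribution")
    return mean * mean / var, var / mean


def gamma_pvalue(
    shape: float, scale: float, observed: float
) -> float:
    """Upper-tail probability of the fitted gamma at the observed score.

    Accurate for high p-values; may overestimate the significance of very
    low ones. A negative observed score yields p = 1 by convention.
    """
    if not (np.isfinite(shape) and np.isfinite(scale) and shape > 0 and scale > 0):
        raise ValueError("invalid gamma parameters")
    if not np.isfinite(observed):
        return np.nan
    if observed < 0:
        warnings.warn("negative observed score; p = 1 by convention", stacklevel=2)
        return 1.0
    p = float(stats.gamma.sf(observed, a=shape, scale=scale))
    return min(max(p, np.finfo(float).tiny), 1.0)


def empirical_pvalue(null_scores: np.ndarray, observed: float) -> float:
    """Add-one permutation p: (1 + #{null >= observed}) / (1 + n_perm).

    Ties count toward the numerator; p is never 0, reflecting that a finite
    permutation count cannot resolve smaller tails.
    """
    null_scores = np.asarray(null_scores, float)
    null_scores = null_scores[np.isfinite(null_scores)]
    if null_scores.size == 0:
        raise ValueError("need at least one finite null score")
    if not np.isfinite(observed):
        return np.nan
    return (1.0 + (null_scores >= observed).sum()) / (1.0 + null_scores.size)


def adjust_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1.

    Missing p-values propagate to missing q-values and do not count toward
    the number of tests.
    """
    p = np.asarray(p_values, float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        if (p[ok] < 0).any() or (p[ok] > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def build_null(
    signal: SignalMatrix | np.ndarray,
    targets: TargetVariableSet | np.ndarray,
    db: RegionSetDatabase | None = None,
    *,
    resolution: str = "nucleotide",
    metric: str = "covariance",
    stat: str = "mean",
    use_abs: bool = True,
    min_covered_regions: int = 100,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    indexes: list[RegionSetIndex] | None = None,
) -> dict[tuple[str, str], NullDistribution]:
    """Region-set-specific null distributions from sample-label permutation.

    Each permutation applies one shared shuffle of sample labels to all
    target columns jointly, recomputes the FCS matrix, and rescores every
    surviving region set. Fully reproducible given ``seed``. Precomputed
    ``indexes`` (from :func:`cocoa.scoring.build_indexes`) skip the overlap
    search.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = signal.values if isinstance(signal, SignalMatrix) else np.asarray(signal, float)
    if isinstance(targets, TargetVariableSet):
        if isinstance(signal, SignalMatrix):
            targets = targets.aligned_to(signal.sample_ids)
        T = targets.values
        target_names = list(targets.target_names)
    else:
        T = np.asarray(targets, float)
        if T.ndim == 1:
            T = T[:, None]
        target_names = [f"target{j + 1}" for j in range(T.shape[1])]
    n_samples, n_targets = T.shape
    if indexes is None:
        if db is None:
            raise ValueError("either db or precomputed indexes are required")
        coords = signal.coords  # type: ignore[union-attr]
        indexes = build_indexes(coords, db, resolution, min_covered_regions)
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n_samples) for _ in range(n_perm)])
    null_scores = {
        idx.name: np.empty((n_perm, n_targets)) for idx in indexes
    }
    per_chunk = max(1, _PERM_CHUNK // max(n_targets, 1))
    for lo in range(0, n_perm, per_chunk):
        hi = min(lo + per_chunk, n_perm)
        # (samples, chunk*targets): permutation b occupies a block of columns
        bigT = np.concatenate([T[perms[b]] for b in range(lo, hi)], axis=1)
        F = fcs_matrix(X, bigT, metric)
        for idx in indexes:
            s = idx.score(F, resolution, stat=stat, use_abs=use_abs)
            null_scores[idx.name][lo:hi, :] = s.reshape(hi - lo, n_targets)
    nulls: dict[tuple[str, str], NullDistribution] = {}
    for idx in indexes:
        for j, target in enumerate(target_names):
            scores = null_scores[idx.name][:, j]
            nd = NullDistribution(
                region_set=idx.name, target=target, scores=scores
            )
            try:
                nd.gamma_shape, nd.gamma_scale = fit_gamma_mom(scores)
            except ValueError:
                logger.info(
                    "gamma fit refused for (%s, %s); empirical p will be used",
                    idx.name,
                    target,
                )
            nulls[(idx.name, target)] = nd
    return nulls


def attach_significance(
    results: pd.DataFrame,
    nulls: dict[tuple[str, str], NullDistribution],
    pval_method: str = "auto",
) -> pd.DataFrame:
    """Add p_value, q_value, p_source columns to a ranked result table.

    ``pval_method``: 'gamma' forces the gamma approximation (error when the
    fit was refused), 'empirical' forces the add-one permutation p, 'auto'
    uses gamma whenever the fit succeeded. BH correction is applied per
    target across region sets.
    """
    if pval_method not in ("auto", "gamma", "empirical"):
        raise ValueError(f"unknown pval_method {pval_method!r}")
    out = results.copy()
    p_values = np.full(len(out), np.nan)
    p_source = np.array(["none"] * len(out), dtype=object)
    for i, row in enumerate(out.itertuples(index=False)):
        key = (row.region_set, row.target)
        if key not in nulls:
            continue
        nd = nulls[key]
        observed = row.score
        use_gamma = nd.has_gamma if pval_method == "auto" else pval_method == "gamma"
        if use_gamma:
            if not nd.has_gamma:
                raise ValueError(
                    f"gamma fit unavailable for {key}; use empirical or auto"
                )
            p_values[i] = gamma_pvalue(nd.gamma_shape, nd.gamma_scale, observed)
            p_source[i] = "gamma"
        else:
            p_values[i] = empirical_pvalue(nd.scores, observed)
            p_source[i] = "empirical"
    out["p_value"] = p_values
    out["p_source"] = p_source
    out["q_value"] = np.nan
    for target, grp in out.groupby("target", sort=False):
        out.loc[grp.index, "q_value"] = adjust_fdr(grp["p_value"].to_numpy())
    return out
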