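"""Step 2: aggregate feature contribution scores over region sets.

Two scorers, matching the two signal resolutions:

* nucleotide — within each region of the set, average (or take the median
  of) the FCS of overlapping loci; then apply the same statistic across
  regions. Both levels use the same statistic.
* region (weighted) — one pooled weighted average over all (data region,
  set region) overlap pairs, each data region's FCS weighted by the
  proportion of the set region it covers.

Overlap structure is independent of the target variable, so it is computed
once per region set (`RegionSetIndex`) and reused across targets and
permutations; rescoring a permuted FCS matrix is then a sparse matmul.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .intervals import (
    GenomicInterval,
    RegionSet,
    RegionSetDatabase,
    intervals_to_arrays,
    overlap_pairs_arrays,
)
from .io import SignalMatrix
from .variation import FeatureContributionScores

logger = logging.getLogger(__name__)

__all__ = [
    "RegionSetIndex",
    "score_region_set_nucleotide",
    "score_region_set_weighted",
    "run_cocoa",
    "region_set_signal_average",
    "rank_results",
]


@dataclass
class RegionSetIndex:
    """Precomputed overlap structure between data loci and one region set.

    Attributes
    ----------
    locus_idx, region_idx : int arrays over overlap pairs
        ``locus_idx[p]`` is the data-locus row overlapping set region
        ``region_idx[p]``. A locus inside two regions appears in two pairs.
    weights : float array
        Region resolution only: overlap_length / set_region_length per pair.
    n_regions_covered : int
        Set regions containing at least one data locus.
    n_features : int
        Distinct data loci overlapping the set (each counted once).
    """

    name: str
    locus_idx: np.ndarray
    region_idx: np.ndarray
    weights: np.ndarray | None
    n_regions_covered: int
    n_features: int
    n_set_regions: int
    _pair_matrix: sparse.csr_matrix | None = None

    @classmethod
    def build(
        cls,
        coords: list[GenomicInterval],
        region_set: RegionSet,
        resolution: str,
    ) -> "RegionSetIndex":
        rc, rs, re = intervals_to_arrays(region_set.regions)
        lc, ls, le = intervals_to_arrays(coords)
        ri, li = overlap_pairs_arrays(rc, rs, re, lc, ls, le)
        weights = None
        if resolution == "region":
            ov = np.minimum(re[ri], le[li]) - np.maximum(rs[ri], ls[li])
            weights = ov / (re[ri] - rs[ri]).astype(float)
        return cls(
            name=region_set.name,
            locus_idx=li,
            region_idx=ri,
            weights=weights,
            n_regions_covered=int(np.unique(ri).size),
            n_features=int(np.unique(li).size),
            n_set_regions=len(region_set.regions),
        )

    @property
    def pair_matrix(self) -> sparse.csr_matrix:
        """Sparse (covered regions x pairs) incidence matrix."""
        if self._pair_matrix is None:
            _, dense_region = np.unique(self.region_idx, return_inverse=True)
            n_pairs = self.locus_idx.size
            self._pair_matrix = sparse.csr_matrix(
                (
                    np.ones(n_pairs),
                    (dense_region, np.arange(n_pairs)),
                ),
                shape=(self.n_regions_covered, n_pairs),
            )
        return self._pair_matrix

    def score_nucleotide(
        self, fcs: np.ndarray, stat: str = "mean", use_abs: bool = True
    ) -> np.ndarray:
        """Nested-stat scores for an (n_loci, k) FCS matrix -> (k,) scores.

        Missing-FCS loci are excluded; regions whose overlapping loci are
        all missing drop out of the outer statistic; a fully uncovered set
        scores NaN.
        """
        fcs = np.atleast_2d(np.asarray(fcs, float).T).T  # (n_loci, k)
        k = fcs.shape[1]
        if self.locus_idx.size == 0:
            return np.full(k, np.nan)
        F = fcs[self.locus_idx, :]
        if use_abs:
            F = np.abs(F)
        valid = np.isfinite(F)
        if stat == "mean":
            S = self.pair_matrix
            sums = S @ np.where(valid, F, 0.0)
            counts = S @ valid.astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                region_vals = sums / counts
            region_vals[counts == 0] = np.nan
        elif stat == "median":
            order = np.argsort(self.region_idx, kind="stable")
            bounds = np.flatnonzero(
                np.diff(self.region_idx[order], prepend=-1)
            )
            region_vals = np.full((self.n_regions_covered, k), np.nan)
            splits = np.append(bounds, order.size)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                for r in range(self.n_regions_covered):
                    block = F[order[splits[r] : splits[r + 1]], :]
                    region_vals[r] = np.nanmedian(block, axis=0)
        else:
            raise ValueError(f"stat must be 'mean' or 'median', got {stat!r}")
        with np.errstate(all="ignore"), warnings.catch_warnings():
            # sets whose covered loci all carry missing FCS produce
            # all-NaN region columns; a NaN score is the intended result
            warnings.simplefilter("ignore", RuntimeWarning)
            if stat == "mean":
                out = np.nanmean(region_vals, axis=0)
            else:
                out = np.nanmedian(region_vals, axis=0)
        return out

    def score_weighted(
        self, fcs: np.ndarray, use_abs: bool = True
    ) -> np.ndarray:
        """Overlap-proportion-weighted scores for an (n_loci, k) FCS matrix."""
        fcs = np.atleast_2d(np.asarray(fcs, float).T).T
        k = fcs.shape[1]
        if self.weights is None:
            raise ValueError("index was built without region-resolution weights")
        if self.locus_idx.size == 0:
            return np.full(k, np.nan)
        F = fcs[self.locus_idx, :]
        if use_abs:
            F = np.abs(F)
        valid = np.isfinite(F)
        w = self.weights[:, None]
        num = (np.where(valid, F, 0.0) * w).sum(axis=0)
        den = (valid * w).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = num / den
        out[den == 0] = np.nan
        return out

    def score(
        self,
        fcs: np.ndarray,
        resolution: str,
        stat: str = "mean",
        use_abs: bool = True,
    ) -> np.ndarray:
        if resolution == "nucleotide":
            return self.score_nucleotide(fcs, stat=stat, use_abs=use_abs)
        if resolution == "region":
            return self.score_weighted(fcs, use_abs=use_abs)
        raise ValueError(f"unknown resolution {resolution!r}")


def score_region_set_nucleotide(
    fcs: np.ndarray,
    coords: list[GenomicInterval],
    region_set: RegionSet,
    stat: str = "mean",
    use_abs: bool = True,
) -> tuple[float, int, int]:
    """Score one region set against one FCS vector at nucleotide resolution.

    Returns (score, n_regions_covered, n_features). With no covered region
    the score is NaN, not an error.
    """
    idx = RegionSetIndex.build(coords, region_set, "nucleotide")
    score = float(idx.score_nucleotide(fcs, stat=stat, use_abs=use_abs)[0])
    return score, idx.n_regions_covered, idx.n_features


def score_region_set_weighted(
    fcs: np.ndarray,
    coords: list[GenomicInterval],
    region_set: RegionSet,
    use_abs: bool = True,
) -> tuple[float, int, int]:
    """Score one region set against one FCS vector at region resolution."""
    idx = RegionSetIndex.build(coords, region_set, "region")
    score = float(idx.score_weighted(fcs, use_abs=use_abs)[0])
    return score, idx.n_regions_covered, idx.n_features


def build_indexes(
    coords: list[GenomicInterval],
    db: RegionSetDatabase,
    resolution: str,
    min_covered_regions: int = 100,
) -> list[RegionSetIndex]:
    """Index every set in the database, dropping under-covered sets."""
    indexes = []
    n_dropped = 0
    for rs in db:
        idx = RegionSetIndex.build(coords, rs, resolution)
        if idx.n_regions_covered < min_covered_regions:
            n_dropped += 1
            logger.info(
                "filtered %s: %d covered regions < %d",
                rs.name,
                idx.n_regions_covered,
                min_covered_regions,
            )
            continue
        indexes.append(idx)
    if n_dropped:
        logger.warning(
            "filtered %d/%d region sets below %d covered regions",
            n_dropped,
            len(db),
            min_covered_regions,
        )
    return indexes


def rank_results(results: pd.DataFrame) -> pd.DataFrame:
    """Assign per-target ranks by descending score, ties broken by name."""
    out = results.sort_values(
        ["target", "score", "region_set"],
        ascending=[True, False, True],
        kind="stable",
        na_position="last",
    ).reset_index(drop=True)
    out["rank"] = out.groupby("target", sort=False).cumcount() + 1
    return out


def run_cocoa(
    fcs: FeatureContributionScores,
    coords: list[GenomicInterval],
    db: RegionSetDatabase,
    resolution: str,
    stat: str = "mean",
    use_abs: bool = True,
    min_covered_regions: int = 100,
) -> pd.DataFrame:
    """Score every (region set, target) pair and rank sets per target.

    Region sets with fewer than ``min_covered_regions`` regions covered by
    the data are dropped. Returns a tidy frame with columns region_set,
    target, score, n_regions_covered, n_features, rank, ordered by target
    then rank.
    """
    if len(db) == 0:
        raise ValueError("region set database is empty")
    indexes = build_indexes(coords, db, resolution, min_covered_regions)
    return score_indexes(
        indexes, fcs.values, fcs.target_names, resolution, stat=stat, use_abs=use_abs
    )


def score_indexes(
    indexes: list[RegionSetIndex],
    fcs_values: np.ndarray,
    target_names: list[str],
    resolution: str,
    stat: str = "mean",
    use_abs: bool = True,
) -> pd.DataFrame:
    """Score prebuilt region-set indexes against an FCS matrix and rank."""
    columns = [
        "region_set",
        "target",
        "score",
        "n_regions_covered",
        "n_features",
        "rank",
    ]
    if not indexes:
        logger.warning("all region sets filtered out; empty result")
        return pd.DataFrame(columns=columns)
    rows = []
    for idx in indexes:
        scores = idx.score(fcs_values, resolution, stat=stat, use_abs=use_abs)
        for j, target in enumerate(target_names):
            rows.append(
                {
                    "region_set": idx.name,
                    "target": target,
                    "score": scores[j],
                    "n_regions_covered": idx.n_regions_covered,
                    "n_features": idx.n_features,
                }
            )
    return rank_results(pd.DataFrame(rows))


def region_set_signal_average(
    signal: SignalMatrix, region_set: RegionSet
) -> np.ndarray:
    """Per-sample region-set signal: mean over regions of per-region mean
    signal, giving each covered region equal weight regardless of how many
    loci it contains. Missing values are excluded pairwise; with no
    overlaps at all the vector is all-NaN.
    """
    idx = RegionSetIndex.build(signal.coords, region_set, signal.resolution)
    if idx.locus_idx.size == 0:
        return np.full(signal.n_samples, np.nan)
    X = signal.values[idx.locus_idx, :]
    valid = np.isfinite(X)
    S = idx.pair_matrix
    sums = S @ np.where(valid, X, 0.0)
    counts = S @ valid.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        region_means = sums / counts
    region_means[counts == 0] = np.nan
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(region_means, axis=0)
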