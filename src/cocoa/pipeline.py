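"""End-to-end analysis: Step 1 (or FCS pass-through), Step 2, inference.

This is the library entry point the CLI wraps: quantify per-locus
covariation with the targets, aggregate over every region set in the
database, and attach permutation significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import (
    DEFAULT_N_PERM,
    NullDistribution,
    attach_significance,
    build_null,
)
from .intervals import RegionSetDatabase
from .io import SignalMatrix, TargetVariableSet
from .scoring import build_indexes, score_indexes
from .variation import (
    FeatureContributionScores,
    compute_fcs,
    pca_targets,
    recommend_metric,
)

logger = logging.getLogger(__name__)

__all__ = ["AnalysisResult", "run_analysis"]


@dataclass
class AnalysisResult:
    """Everything a run produced: the ranked table plus intermediates."""

    results: pd.DataFrame
    fcs: FeatureContributionScores
    targets: TargetVariableSet | None
    nulls: dict[tuple[str, str], NullDistribution] = field(default_factory=dict)
    metric: str = ""


def run_analysis(
    signal: SignalMatrix,
    db: RegionSetDatabase,
    targets: TargetVariableSet | None = None,
    fcs: FeatureContributionScores | None = None,
    *,
    metric: str = "auto",
    target_kind: str = "continuous",
    n_pcs: int = 2,
    center: bool = True,
    scale: bool | None = None,
    stat: str = "mean",
    use_abs: bool = True,
    min_covered_regions: int = 100,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    pval_method: str = "auto",
) -> AnalysisResult:
    """Run the full analysis on a signal matrix and region-set database.

    Targets come from one of three places: an explicit ``targets`` table
    (supervised), internal PCA when ``targets`` is None (unsupervised,
    ``n_pcs`` components), or a precomputed ``fcs`` matrix that skips
    Step 1 entirely — in that last case no permutation test is possible
    (the per-sample data needed to re-shuffle labels is bypassed) and
    p-values stay missing.

    ``metric="auto"`` resolves via :func:`cocoa.variation.recommend_metric`
    from the signal resolution and target kind. ``scale=None`` follows the
    same convention for internal PCA: off for methylation-like data, on
    for count-like data.
    """
    resolution = signal.resolution
    if fcs is not None:
        if targets is not None:
            logger.warning(
                "precomputed FCS supplied; targets are ignored and no "
                "permutation test is run"
            )
            targets = None
        used_metric = fcs.metric
    else:
        if targets is None:
            if scale is None:
                scale = not signal.is_methylation and resolution == "region"
            targets = pca_targets(
                signal, n_components=n_pcs, center=center, scale=scale
            )
            target_kind = "latent_factor"
        if metric == "auto":
            metric = recommend_metric(resolution, target_kind)
        used_metric = metric
        fcs = compute_fcs(signal, targets, metric=used_metric)

    indexes = build_indexes(signal.coords, db, resolution, min_covered_regions)
    results = score_indexes(
        indexes,
        fcs.values,
        fcs.target_names,
        resolution,
        stat=stat,
        use_abs=use_abs,
    )
    nulls: dict[tuple[str, str], NullDistribution] = {}
    can_permute = targets is not None and n_perm >= 1 and len(results)
    if can_permute:
        nulls = build_null(
            signal,
            targets,
            resolution=resolution,
            metric=used_metric,
            stat=stat,
            use_abs=use_abs,
            n_perm=n_perm,
            seed=seed,
            indexes=indexes,
        )
        results = attach_significance(results, nulls, pval_method=pval_method)
    else:
        results["p_value"] = np.nan
        results["q_value"] = np.nan
        results["p_source"] = "none"
    return AnalysisResult(
        results=results,
        fcs=fcs,
        targets=targets,
        nulls=nulls,
        metric=used_metric,
    )
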