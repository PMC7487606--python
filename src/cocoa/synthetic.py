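"""Self-contained synthetic datasets with planted region-set covariation.

The generator emulates the structure the method assumes: a latent factor
varies across samples, and the epigenetic signal inside one "planted" set
of regions covaries with it, while background loci carry independent noise
and decoy region sets fall at random over the synthetic genome. Methylation
-like data are bounded in [0, 1] (logistic squashing of a Gaussian latent
signal around a 0.5 baseline); accessibility-like data are positive and
unbounded (exponentiated latent signal), carried at region resolution.
Everything is reproducible byte-for-byte from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.special import expit

from .intervals import GenomicInterval, RegionSet, RegionSetDatabase
from .io import (
    SignalMatrix,
    TargetVariableSet,
    write_signal_matrix,
    write_targets,
)

__all__ = [
    "SimulationConfig",
    "generate_dataset",
    "default_planted_config",
    "default_planted_fixture",
    "write_dataset",
]

PLANTED_SET_NAME = "planted"


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic generator.

    ``effect_size`` is in latent-signal units per unit latent factor, with
    sample-level noise of ``noise_sd`` added on the same scale before the
    squashing/exponentiation that maps latent signal to observed values.
    ``data_locus_width`` is the width of each data locus: 1 for
    nucleotide-resolution (CpG-like) data, wider for peak-like data.
    """

    n_samples: int = 100
    n_background_loci: int = 20_000
    n_planted_regions: int = 200
    loci_per_region: int = 3
    region_width: int = 500
    effect_size: float = 1.0
    noise_sd: float = 1.0
    signal_kind: str = "methylation"  # or "accessibility"
    n_decoy_sets: int = 100
    decoy_regions_per_set: int = 200
    genome_length: int = 20_000_000
    seed: int = 20_200_907
    data_locus_width: int | None = None

    def __post_init__(self) -> None:
        for name in (
            "n_samples",
            "n_background_loci",
            "n_planted_regions",
            "loci_per_region",
            "region_width",
            "n_decoy_sets",
            "decoy_regions_per_set",
            "genome_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.signal_kind not in ("methylation", "accessibility"):
            raise ValueError(f"unknown signal_kind {self.signal_kind!r}")

    @property
    def locus_width(self) -> int:
        if self.data_locus_width is not None:
            return self.data_locus_width
        return 1 if self.signal_kind == "methylation" else 200

    @property
    def resolution(self) -> str:
        return "nucleotide" if self.locus_width == 1 else "region"


def _disjoint_starts(
    rng: np.random.Generator, n: int, width: int, genome_length: int
) -> np.ndarray:
    """n sorted non-overlapping region starts, uniform over placements."""
    slack = genome_length - n * width
    if slack < 0:
        raise ValueError(
            f"genome of {genome_length} bp too short for {n} disjoint "
            f"{width} bp regions"
        )
    gaps = np.sort(rng.integers(0, slack + 1, size=n))
    return gaps + np.arange(n) * width


def generate_dataset(
    cfg: SimulationConfig,
) -> tuple[SignalMatrix, TargetVariableSet, RegionSet, RegionSetDatabase]:
    """Generate (signal, targets, planted set, database of planted+decoys).

    The latent factor z is standard normal per sample. Planted loci carry
    latent signal ``effect_size * z + N(0, noise_sd)``; background loci
    carry the noise term only. Decoy sets are placed uniformly at random
    and may by chance touch planted loci — that spatial coincidence is part
    of a realistic null.
    """
    rng = np.random.default_rng(cfg.seed)
    chrom = "chrS1"
    w = cfg.locus_width

    planted_starts = _disjoint_starts(
        rng, cfg.n_planted_regions, cfg.region_width, cfg.genome_length
    )
    planted_regions = [
        GenomicInterval(chrom, int(s), int(s + cfg.region_width))
        for s in planted_starts
    ]
    planted_set = RegionSet(
        name=PLANTED_SET_NAME,
        regions=planted_regions,
        metadata={"kind": "planted"},
    )  # planted_locus_indices added below, once row order is fixed

    # planted loci: loci_per_region distinct starts inside each region
    if cfg.region_width - w + 1 < cfg.loci_per_region:
        raise ValueError("region_width too small for loci_per_region loci")
    planted_locus_starts = np.concatenate(
        [
            s
            + rng.choice(
                cfg.region_width - w + 1, size=cfg.loci_per_region, replace=False
            )
            for s in planted_starts
        ]
    )
    background_starts = rng.integers(
        0, cfg.genome_length - w + 1, size=cfg.n_background_loci
    )
    starts = np.concatenate([planted_locus_starts, background_starts])
    is_planted = np.zeros(starts.size, dtype=bool)
    is_planted[: planted_locus_starts.size] = True
    order = np.argsort(starts, kind="stable")
    starts, is_planted = starts[order], is_planted[order]
    coords = [GenomicInterval(chrom, int(s), int(s + w)) for s in starts]
    # record which matrix rows carry the planted effect (background loci
    # may also fall inside planted regions by chance, so overlap alone
    # cannot recover this)
    planted_set.metadata["planted_locus_indices"] = np.flatnonzero(is_planted)

    z = rng.standard_normal(cfg.n_samples)
    latent = rng.normal(0.0, cfg.noise_sd, size=(starts.size, cfg.n_samples))
    latent[is_planted] += cfg.effect_size * z[None, :]
    if cfg.signal_kind == "methylation":
        values = np.clip(expit(latent), 0.0, 1.0)  # baseline expit(0) = 0.5
    else:
        values = np.exp(latent)

    sample_ids = [f"S{i + 1:03d}" for i in range(cfg.n_samples)]
    signal = SignalMatrix(
        coords=coords,
        values=values,
        sample_ids=sample_ids,
        resolution=cfg.resolution,
        is_methylation=cfg.signal_kind == "methylation",
    )
    targets = TargetVariableSet(
        values=z[:, None],
        target_names=["latent_factor"],
        sample_ids=sample_ids,
    )

    decoys = []
    n_digits = max(3, len(str(cfg.n_decoy_sets)))
    for d in range(cfg.n_decoy_sets):
        ds = rng.integers(
            0,
            cfg.genome_length - cfg.region_width + 1,
            size=cfg.decoy_regions_per_set,
        )
        ds.sort()
        decoys.append(
            RegionSet(
                name=f"decoy_{d:0{n_digits}d}",
                regions=[
                    GenomicInterval(chrom, int(s), int(s + cfg.region_width))
                    for s in ds
                ],
                metadata={"kind": "decoy"},
            )
        )
    db = RegionSetDatabase(
        sets=[planted_set] + decoys, genome_label="synthetic"
    )
    return signal, targets, planted_set, db


def default_planted_config(**overrides) -> SimulationConfig:
    """The canonical planted-signal configuration used across the tests."""
    return replace(SimulationConfig(), **overrides)


def default_planted_fixture():
    """Generate the canonical planted fixture (100 samples, 20,600 loci,
    200 planted regions, 100 decoy sets)."""
    return generate_dataset(default_planted_config())


def write_dataset(
    cfg: SimulationConfig, out_dir: str | Path
) -> Path:
    """Write a generated dataset as signal.tsv, targets.tsv and a
    directory of BED files loadable by :func:`cocoa.io.load_region_db`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    signal, targets, _, db = generate_dataset(cfg)
    write_signal_matrix(signal, out_dir / "signal.tsv")
    write_targets(targets, out_dir / "targets.tsv")
    region_dir = out_dir / "regions"
    region_dir.mkdir(exist_ok=True)
    for rs in db:
        with (region_dir / f"{rs.name}.bed").open("w") as fh:
            for r in rs.regions:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
    with (out_dir / "annotation.tsv").open("w") as fh:
        fh.write("filename\tkind\n")
        for rs in db:
            fh.write(f"{rs.name}.bed\t{rs.metadata.get('kind', '')}\n")
    return out_dir
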