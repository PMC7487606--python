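"""Shared fixtures: small synthetic datasets generated at test time."""

import numpy as np
import pytest

from cocoa import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_planted():
    """A fast planted dataset: 30 samples, ~1.5k loci, 5 decoy sets."""
    cfg = SimulationConfig(
        n_samples=30,
        n_background_loci=1500,
        n_planted_regions=30,
        loci_per_region=3,
        region_width=500,
        effect_size=1.5,
        noise_sd=1.0,
        n_decoy_sets=5,
        decoy_regions_per_set=30,
        genome_length=2_000_000,
        seed=11,
    )
    return generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_intervals(rng, n, max_coord=10_000, max_width=300, chroms=("chr1",)):
    """Random valid half-open intervals for oracle comparisons."""
    from cocoa import GenomicInterval

    starts = rng.integers(0, max_coord, size=n)
    widths = rng.integers(1, max_width, size=n)
    names = rng.choice(list(chroms), size=n)
    return [
        GenomicInterval(str(c), int(s), int(s + w))
        for c, s, w in zip(names, starts, widths)
    ]
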