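"""Shared fixtures: small seeded simulations reused across test modules."""

import numpy as np
import pytest

from nucorg.simulate import SimConfig, simulate_experiment


def frags_per_nuc_depth(n_genes: int, n_nucs: int = 8, per_nuc: int = 300,
                        background_frac: float = 0.05) -> int:
    """Depth giving ~per_nuc signal fragments per nucleosome."""
    return int(round(n_genes * n_nucs * per_nuc / (1 - background_frac)))


@pytest.fixture(scope="session")
def small_config():
    """20 genes, default noise (fuzziness 20 bp, 5% background), 24 bp
    downstream +1 shift injected at 5 genes."""
    effect = frozenset(f"gene_{i:04d}" for i in (1, 4, 9, 12, 17))
    return SimConfig(seed=11, n_genes=20, chrom_length=120_000,
                     depth=frags_per_nuc_depth(20), effect_genes=effect,
                     plus1_shift=24)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simulate_experiment(small_config, n_replicates=2)


@pytest.fixture(scope="session")
def clean_config():
    """Degenerate-noise config: fuzziness 0, no background."""
    return SimConfig(seed=5, n_genes=10, chrom_length=60_000,
                     fuzziness_sd=0.0, background_frac=0.0, depth=8_000)


@pytest.fixture(scope="session")
def clean_experiment(clean_config):
    return simulate_experiment(clean_config, conditions=("wt",), n_replicates=1)
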