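"""Shared fixtures: small synthetic configurations and generated datasets.

Everything is generated at test time from fixed seeds; no data files.
"""

import numpy as np
import pandas as pd
import pytest

from zgaprime.simulate import (SimulationConfig, generate_annotation,
                               generate_chip_and_sequence, generate_expression)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=11, n_chroms=2, chrom_length=1_500_000,
                            n_genes=30, n_regions=60, fragment_depth=30_000)


@pytest.fixture(scope="session")
def small_truth(small_config):
    truth = generate_annotation(small_config)
    generate_expression(small_config, truth)
    return truth


@pytest.fixture(scope="session")
def small_dataset(small_config, small_truth):
    chip, signal, seqs = generate_chip_and_sequence(small_config, small_truth)
    return {"chip": chip, "signal": signal, "seqs": seqs}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000,
                     max_len=300) -> pd.DataFrame:
    """Random interval fixture used by the brute-force oracle tests."""
    chrom = rng.choice(chroms, size=n)
    start = rng.integers(0, max_pos, size=n)
    length = rng.integers(1, max_len, size=n)
    df = pd.DataFrame({"chrom": chrom, "start": start, "end": start + length})
    df["name"] = [f"iv{i}" for i in range(n)]
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
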