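import numpy as np
import pytest

from btties.likelihood import ComparisonTable
from btties.polya_gamma import sample_pg


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session", autouse=True)
def warm_jit():
    """Compile the numba Polya-Gamma kernels once, outside any timed region."""
    sample_pg(1, 0.3, np.random.default_rng(0), size=4)


def random_table(n_wards: int, n_pairs: int, rng, max_count: int = 4) -> ComparisonTable:
    """Small random comparison table with wins both ways and symmetric ties."""
    wins = np.zeros((n_wards, n_wards), dtype=np.int64)
    ties = np.zeros((n_wards, n_wards), dtype=np.int64)
    for _ in range(n_pairs):
        i, j = rng.choice(n_wards, size=2, replace=False)
        wins[i, j] += rng.integers(0, max_count)
        wins[j, i] += rng.integers(0, max_count)
        t = rng.integers(0, max_count)
        ties[i, j] += t
        ties[j, i] += t
    labels = [f"W{k:03d}" for k in range(n_wards)]
    return ComparisonTable(ward_labels=labels, wins=wins, ties=ties)
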