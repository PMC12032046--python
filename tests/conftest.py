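import numpy as np
import pandas as pd
import pytest

from ilqtl.config import PipelineConfig, SimulationConfig


def make_marker_table(codes_by_line: dict, chrom=None, pos=None):
    """Build a small marker table from per-line code strings."""
    n = len(next(iter(codes_by_line.values())))
    df = pd.DataFrame({
        "marker_id": [f"SNP{i + 1}" for i in range(n)],
        "chrom": chrom if chrom is not None else [1] * n,
        "pos_bp": pos if pos is not None else [(i + 1) * 1_000_000
                                               for i in range(n)],
    })
    for line, codes in codes_by_line.items():
        df[line] = list(codes)
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """Reduced-scale study used where geometry does not matter."""
    return SimulationConfig(n_lines=20, n_chrom=4, chrom_length_mb=100.0,
                            markers_per_chrom=50, n_reps=4, grid_rows=14,
                            grid_cols=14, n_days=30, onset_day=12,
                            qtls=[], min_qtl_carriers=0, seed=11)


@pytest.fixture(scope="session")
def small_library(small_config):
    from ilqtl.simulate import simulate_library
    return simulate_library(small_config)
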