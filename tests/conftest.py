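import numpy as np
import pytest

from sclst import (
    SimConfig,
    annotate_gc_mappability,
    build_bin_grid,
    toy_genome,
)


@pytest.fixture(scope="session")
def genome3():
    """Three 100 Mb chromosomes — the desk-scale default genome."""
    return toy_genome()


@pytest.fixture(scope="session")
def grid3(genome3):
    """500 kb grid over the desk-scale genome with a smooth varying GC track
    so GC correction is exercised."""
    grid = build_bin_grid(genome3, 500_000)
    gc = 0.35 + 0.2 * np.abs(np.sin(np.arange(len(grid)) / 37))
    return annotate_gc_mappability(grid, gc_track=gc)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(n_cells=5, seed=1)


def make_call(chrom, start_mb, end_mb, state, mean=None, cell="c1"):
    """Convenience constructor for CNACall fixtures with Mb coordinates."""
    from sclst import CNACall

    default_mean = {"gain": 0.585, "loss": -1.0, "neutral": 0.0}[state]
    return CNACall(
        cell_id=cell, chrom=chrom, start=int(start_mb * 1e6),
        end=int(end_mb * 1e6), n_bins=max(1, int((end_mb - start_mb) * 2)),
        mean_log2=default_mean if mean is None else mean, state=state)
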