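import numpy as np
import pandas as pd
import pytest

from svcna.genome import GenomeLayout, Interval, build_bins


@pytest.fixture
def small_layout() -> GenomeLayout:
    return GenomeLayout(
        chrom_names=["chr1", "chr2"],
        chrom_lengths={"chr1": 10_000_000, "chr2": 8_000_000},
        arm_boundaries={"chr1": 4_000_000, "chr2": 3_000_000},
        mask=[Interval("chr1", 3_900_000, 4_100_000)],
    )


@pytest.fixture
def small_grid(small_layout):
    grid = build_bins(small_layout, bin_size=1_000_000)
    rng = np.random.default_rng(0)
    grid.set_covariates(pd.DataFrame({"x": rng.normal(size=len(grid)),
                                      "y": rng.normal(size=len(grid))}))
    return grid


@pytest.fixture
def uniform_grid(small_grid):
    small_grid.set_b(np.where(small_grid.callable_flags, 5.0, 0.0))
    return small_grid
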