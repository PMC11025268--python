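"""Shared fixtures: seeded synthetic datasets and analysis grids.

Two session-scoped datasets drive most tests: one with region-distinct gene
compositions (domains are recoverable from expression) and one where the
regions differ only in detections per cell (the pure library-size confound).
The analysis tessellation for clustering tests is coarser (30 bins per axis)
than the mapping tessellation so each bin holds enough counts to cluster.
"""

import numpy as np
import pandas as pd
import pytest

import spothex as sx


@pytest.fixture(scope="session")
def distinct_dataset():
    cfg = sx.SimConfig(seed=1, compositions="distinct")
    table, truth = sx.simulate_dataset(cfg)
    return table, truth


@pytest.fixture(scope="session")
def confound_dataset():
    cfg = sx.SimConfig(seed=2, compositions="identical")
    table, truth = sx.simulate_dataset(cfg)
    return table, truth


@pytest.fixture(scope="session")
def grid100():
    return sx.build_grid((0, 0, 1, 1), 100, "hex")


@pytest.fixture(scope="session")
def grid30():
    return sx.build_grid((0, 0, 1, 1), 30, "hex")


@pytest.fixture(scope="session")
def distinct_bins(grid30, distinct_dataset):
    table, _ = distinct_dataset
    return sx.filter_bins(sx.aggregate_bins(grid30, table))


@pytest.fixture(scope="session")
def confound_bins(grid30, confound_dataset):
    table, _ = confound_dataset
    return sx.filter_bins(sx.aggregate_bins(grid30, table))


def region_codes(bins) -> np.ndarray:
    """Integer truth labels from the majority-region column."""
    return pd.Categorical(bins.meta["region"].astype(str)).codes


@pytest.fixture(scope="session")
def tiny_transcripts():
    frame = pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g1", "g2", "g3"],
            "x": [0.1, 0.2, 0.8, 0.85, 0.5],
            "y": [0.1, 0.15, 0.8, 0.9, 0.5],
            "count": [2, 1, 4, 1, 1],
            "region": ["A", "A", "B", "B", "A"],
        }
    )
    return sx.TranscriptTable(frame=frame)
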