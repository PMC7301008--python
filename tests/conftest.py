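"""Shared fixtures: reference colony runs reused across the test modules.

The long-running fixtures simulate the default colony at a reduced
environment size (R = 14, M = 4 instead of the full R = 34, M = 6) so
the whole suite fits a single-CPU run; the growth benchmarks were
calibrated at this scale.
"""

import numpy as np
import pytest

from hextissue import load_snapshots
from hextissue.engine import PopulationSpec, SimulationSeries, run_series

REFERENCE_SEEDS = [0, 1, 2, 3, 4]


@pytest.fixture(scope="session")
def colony_paths(tmp_path_factory):
    """Five replicate 14-day default colony simulations (JSON outputs)."""
    outdir = tmp_path_factory.mktemp("colony14")
    series = SimulationSeries(
        name="colony14", radius=14, margin=4, days=14.0,
        snapshot_interval=720, seeds=list(REFERENCE_SEEDS),
        populations=[PopulationSpec(label="X", count=1)])
    return run_series(series, outdir=outdir)


@pytest.fixture(scope="session")
def colony_df(colony_paths):
    return load_snapshots(colony_paths)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def tiny_sim(radius=4, margin=1, n_cells=1, seed=0, days=0.01, **pop_kwargs):
    """Small simulation instance for unit-level agent tests."""
    from hextissue.engine import Simulation
    series = SimulationSeries(
        name="tiny", radius=radius, margin=margin, days=days,
        seeds=[seed],
        populations=[PopulationSpec(label="X", count=n_cells, **pop_kwargs)])
    return Simulation(series, seed)
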