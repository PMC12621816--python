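"""Shared fixtures.

The expensive simulation products (landscape subgrid sweeps, the default
genetic-mechanical run) are session-scoped so the behavioral tests and the
acceptance suite share one computation.
"""

import numpy as np
import pytest

from gastrosim.grn import default_network, run_grn_simulation
from gastrosim.landscape import SweepSpec, run_sweep

#: 5-value adhesion subgrid spanning the full sweep range
ALPHA_SUBGRID = (0.65, 0.725, 0.80, 0.875, 0.95)

#: reference adhesion triple used in the paired long-range comparison
ALPHA_REFERENCE = (0.750, 0.725, 0.800)

SUBGRID_N_CELLS = 300
SUBGRID_REPLICATES = 3
SUBGRID_BASE_SEED = 1

GRN_N_CELLS = 400
GRN_SEED = 0


@pytest.fixture(scope="session")
def adhesion_sweep():
    """5^3 adhesion-only sweep (all beta = 0), 300 cells, 3 seeds/point."""
    spec = SweepSpec(
        alpha_values=ALPHA_SUBGRID,
        beta_channels=(),
        include_baseline=True,
        n_replicates=SUBGRID_REPLICATES,
        n_cells=SUBGRID_N_CELLS,
        base_seed=SUBGRID_BASE_SEED,
    )
    return spec, run_sweep(spec)


@pytest.fixture(scope="session")
def peripheral_attraction_sweep():
    """Same 5^3 adhesion subgrid with the o->o attraction channel at the top
    default magnitude (and no baseline points)."""
    spec = SweepSpec(
        alpha_values=ALPHA_SUBGRID,
        beta_channels=(("o", "o"),),
        beta_signs=(1,),
        beta_magnitudes=(3.0,),
        include_baseline=False,
        n_replicates=SUBGRID_REPLICATES,
        n_cells=SUBGRID_N_CELLS,
        base_seed=SUBGRID_BASE_SEED,
    )
    return spec, run_sweep(spec)


@pytest.fixture(scope="session")
def grn_run():
    """Default 3-gene genetic-mechanical run, 400 cells, full duration."""
    spec = default_network()
    traj = run_grn_simulation(spec, n_cells=GRN_N_CELLS, seed=GRN_SEED)
    return spec, traj
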