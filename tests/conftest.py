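"""Shared fixtures: synthetic systems reused across test modules.

Expensive toy-dynamics runs are session-scoped; everything is generated
programmatically (no data files).
"""

import numpy as np
import pytest

from mechanotraj import synthetic as syn


@pytest.fixture(scope="session")
def channel_model():
    """Synthetic C4 channel stand-in with known gate/AR/H-bond ground truth."""
    return syn.make_channel_model()


@pytest.fixture(scope="session")
def channel_domain_map():
    return syn.channel_model_domain_map()


@pytest.fixture(scope="session")
def spring_model():
    return syn.SpringModel(n_chains=4, k_chain_pn_per_nm=3.0)


@pytest.fixture(scope="session")
def spring_free_run(spring_model):
    """Force-free thermal run of the default 4-chain bundle."""
    return syn.simulate_overdamped(
        spring_model, temperature_K=300.0, n_steps=120_000, seed=2024
    )


@pytest.fixture(scope="session")
def spring_push_run(spring_model):
    """5 pN/chain compression run sharing the free run's noise sequence.

    Common random numbers: for this linear network the forced-minus-free
    difference is then essentially deterministic, so stiffness recovery is
    limited by equilibration, not thermal noise.
    """
    return syn.simulate_overdamped(
        spring_model,
        force_per_chain_pn=-5.0,
        temperature_K=300.0,
        n_steps=120_000,
        seed=2024,
    )


@pytest.fixture()
def straight_rod():
    """A 20-atom rod tilted 45 deg from z, for axis/angle fixtures."""
    from mechanotraj.structure import Structure

    n = 20
    coords = np.column_stack(
        [np.linspace(0.0, 10.0, n), np.zeros(n), np.linspace(0.0, 10.0, n)]
    )
    return Structure(
        chain_id=np.full(n, "A"),
        res_id=np.arange(1, n + 1),
        ins_code=np.full(n, ""),
        res_name=np.full(n, "ALA"),
        atom_name=np.full(n, "CA"),
        element=np.full(n, "C"),
        occupancy=np.ones(n),
        coords=coords,
    )
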