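import numpy as np
import pytest

from nanospec import fixio, rbmd
from nanospec.ffield import FragmentTopology, PairForceField


@pytest.fixture(scope="session")
def acn_topology():
    """Six-site rigid acetonitrile stand-in shipped with the package."""
    path = fixio.builtin_data_path("acetonitrile_synthetic_ff.yaml")
    return fixio.load_topology_config(path)["acetonitrile"]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_droplet(topology, n_molecules, pack_radius, seed, temperature=300.0):
    """Packed, minimized, momentum-sampled droplet plus its force field."""
    coms, quats = fixio.pack_droplet(n_molecules, pack_radius, 2.3, topology, seed=seed)
    state = rbmd.build_state([topology], np.zeros(n_molecules, dtype=int), coms, quats)
    ff = PairForceField([topology], np.zeros(n_molecules, dtype=int))
    state = rbmd.minimize_droplet(state, ff)
    state = rbmd.sample_momenta(state, temperature, np.random.default_rng(seed))
    return state, ff


@pytest.fixture(scope="session")
def small_droplet(acn_topology):
    """Ten acetonitrile molecules, minimized and thermalized."""
    return make_droplet(acn_topology, 10, 7.5, seed=11)


def lj_particle():
    """Reduced-units Lennard-Jones particle: sigma = 1 Å, eps = 1 kJ/mol, m = 1 amu."""
    return FragmentTopology(
        "lj", ["X"], [1.0], [0.0], [1.0], [1.0], [[0.0, 0.0, 0.0]], rigid=False
    )
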