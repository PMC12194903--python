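import numpy as np
import pytest

import bilayerkit as bk


@pytest.fixture(scope="session")
def planar_256():
    """Hydrated planar reference bilayer: 256 lipids at APL 0.61 nm²."""
    spec = bk.SyntheticSpec(n_lipids_per_leaflet=128, target_apl=0.61,
                            waters_per_lipid=30, seed=101)
    frame, topo = bk.build_bilayer(spec)
    return spec, frame, topo


@pytest.fixture(scope="session")
def small_planar():
    """Small dry planar bilayer for geometry tests."""
    spec = bk.SyntheticSpec(n_lipids_per_leaflet=16, waters_per_lipid=0,
                            chain_length=16, seed=7)
    frame, topo = bk.build_bilayer(spec)
    return spec, frame, topo


@pytest.fixture(scope="session")
def undulated_system():
    """Undulated dry bilayer, A = 1 nm, λ = box length."""
    spec = bk.SyntheticSpec(n_lipids_per_leaflet=256, target_apl=0.61,
                            waters_per_lipid=0, chain_length=4,
                            undulation_amplitude=1.0, seed=13)
    frame, topo = bk.build_bilayer(spec)
    return spec, frame, topo


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
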