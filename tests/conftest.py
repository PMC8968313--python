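import numpy as np
import pytest

from atrialab.geometry import build_idealized_la, make_pvi_lesions
from atrialab.ionic import CellState, preset_scales


@pytest.fixture(scope="session")
def la_mesh():
    """Small LA-like sheet with four PV sleeves (desk test resolution)."""
    return build_idealized_la(24.0, 24.0, target_edge_um=800.0,
                              pv_radius_mm=2.0, seed=11)


@pytest.fixture(scope="session")
def strip_mesh():
    """PV-free strip for planar-wave propagation tests."""
    return build_idealized_la(20.0, 6.0, target_edge_um=600.0,
                              pv_radius_mm=0.0, seed=7)


@pytest.fixture(scope="session")
def pvi_gap_lesions(la_mesh):
    return make_pvi_lesions(la_mesh, with_gaps=True)


@pytest.fixture(scope="session")
def cpvi_lesions(la_mesh):
    return make_pvi_lesions(la_mesh, with_gaps=False)


def random_valid_states(n, seed=0):
    """Random CRN states inside the physiological invariant box."""
    rng = np.random.default_rng(seed)
    st = CellState.resting(n)
    st.data[0] = rng.uniform(-90.0, 40.0, n)               # vm
    st.data[1:16] = rng.uniform(0.0, 1.0, (15, n))         # gates
    st.data[16] = rng.uniform(5.0, 20.0, n)                # na_i
    st.data[17] = rng.uniform(100.0, 160.0, n)             # k_i
    st.data[18] = rng.uniform(5e-5, 1e-3, n)               # ca_i
    st.data[19] = rng.uniform(0.1, 3.0, n)                 # ca_up
    st.data[20] = rng.uniform(0.1, 3.0, n)                 # ca_rel
    return st


@pytest.fixture(scope="session")
def af_scales():
    return preset_scales("af_remodeling")
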