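import numpy as np
import pytest

import switchlab as sl
from switchlab.synth import AAWeightModel, client_sequences, gen_array

STUDY_PREFS = {"C": 0.5, "Y": 0.5, "W": 0.5, "R": 0.5, "D": -0.5, "E": -0.5}


@pytest.fixture(scope="session")
def clients():
    """Five random client sequences at realistic tiled-protein lengths."""
    return client_sequences(seed=1)


@pytest.fixture(scope="session")
def preference_array(clients):
    """Array simulated with C/Y/W/R favoured and D/E disfavoured."""
    model = AAWeightModel.with_preferences(STUDY_PREFS, noise_sd=0.2, seed=1)
    return gen_array(clients, model, replicates=3)


@pytest.fixture(scope="session")
def helix20():
    return sl.gen_helix(sl.HelixSpec(n_res=20))


@pytest.fixture(scope="session")
def helix_dimer():
    """Two parallel ideal helices 9 Å apart, chains A and B."""
    a = sl.gen_helix(sl.HelixSpec(n_res=40), chain="A")
    b = sl.gen_helix(sl.HelixSpec(n_res=40), chain="B", offset=(9.0, 0.0, 0.0))
    return sl.StructureModel(
        chain=np.concatenate([a.chain, b.chain]),
        resnum=np.concatenate([a.resnum, b.resnum]),
        resname=np.concatenate([a.resname, b.resname]),
        atom_name=np.concatenate([a.atom_name, b.atom_name]),
        element=np.concatenate([a.element, b.element]),
        coords=np.vstack([a.coords, b.coords]),
    )


@pytest.fixture
def base_peaklist():
    peaks = [
        sl.Peak(f"I{100 + 5 * i}", 9.0 + 0.55 * i, 0.30 + 0.06 * i, 1.0 + 0.05 * i)
        for i in range(10)
    ]
    return sl.PeakList(peaks)
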