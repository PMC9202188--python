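import numpy as np
import pytest

from daforge import retro_da, synthetic


@pytest.fixture
def cyclohexene():
    return retro_da.Cycloadduct.from_smiles("C1=CCCCC1")

@pytest.fixture
def vinylcyclohexene():
    return retro_da.Cycloadduct.from_smiles("C=CC1CCC=CC1")

@pytest.fixture
def octalin():
    """Bicyclic adduct whose retro transformation is intramolecular."""
    return retro_da.Cycloadduct.from_smiles("C1=CCCC2CCCCC12")

@pytest.fixture
def two_ring_adduct():
    """Two cyclohexene substructures joined by a single bond: two competing sites."""
    return retro_da.Cycloadduct.from_smiles("C1=CC(CCC1)C1CCC=CC1")


@pytest.fixture
def fine_spec():
    """Synthetic double-well path dense enough for 1e-3 conservation checks."""
    return synthetic.PathSpec(
        functional_form="double_well_barrier",
        n_points_per_direction=50,
        step=0.04,
        n_atoms=4,
        seed=3,
    )

@pytest.fixture
def fine_path(fine_spec):
    return synthetic.make_path(fine_spec)


@pytest.fixture
def smiles_file(tmp_path):
    f = tmp_path / "SMILES.txt"
    f.write_text("C1=CCCCC1\nC=CC1CCC=CC1\nC1=CCCC2CCCCC12\n")
    return f


def interior(arr, margin=1):
    """Drop points whose stencil touches a one-sided endpoint derivative."""
    return np.asarray(arr)[margin:-margin]
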