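import numpy as np
import pytest

import arbormap as am
from arbormap.treeio import TaxonCharacterTable


@pytest.fixture(scope="session")
def toy_tree():
    return am.parse_tree("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def five_tip_tree():
    return am.parse_tree("((A:1,B:2):1.5,(C:0.5,(D:1,E:1):0.7):1);")


@pytest.fixture(scope="session")
def five_tip_table():
    states = ("arboreal", "semi-arboreal", "nonarboreal")
    return TaxonCharacterTable(
        states={lab: states[i % 3] for i, lab in enumerate("ABCDE")}
    )


@pytest.fixture(scope="session")
def mapping_fixture():
    """20-tip ultrametric tree with four-rate characters and known rates."""
    tree = am.simulate_birth_death_tree(20, 50.0, seed=3)
    spec = am.build_model_spec("four_rate")
    params = np.array([0.02, 0.01, 0.01, 0.01])
    truth = am.simulate_character_history(tree, spec, params, root_state=0, seed=4)
    return dict(tree=tree, spec=spec, params=params, table=truth.table,
                truth=truth)


@pytest.fixture(scope="session")
def study_fixture():
    return am.make_study_fixture(seed=0, n_posterior=25)
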