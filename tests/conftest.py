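import numpy as np
import pandas as pd
import pytest

from zincscreen.synthetic import (
    SyntheticSpec,
    generate_descriptor_table,
    generate_ligand_set,
)


@pytest.fixture(scope="session")
def spec200() -> SyntheticSpec:
    """Study-scale generator spec: 200 ligands, 5 informative among 50 columns."""
    return SyntheticSpec(
        seed=3,
        n_ligands=200,
        high_fraction=131 / 208,
        n_informative_descriptors=5,
        n_noise_descriptors=43,
        effect_size=1.5,
    )


@pytest.fixture(scope="session")
def ligand_set200(spec200):
    return generate_ligand_set(spec200)


@pytest.fixture(scope="session")
def table200(spec200, ligand_set200) -> pd.DataFrame:
    return generate_descriptor_table(spec200, ligand_set200)


@pytest.fixture(scope="session")
def labels200(ligand_set200) -> np.ndarray:
    return np.asarray([lig.true_class for lig in ligand_set200.ligands])


@pytest.fixture(scope="session")
def lg_ki200(ligand_set200, table200) -> pd.Series:
    return pd.Series(
        [lig.lg_ki for lig in ligand_set200.ligands], index=table200.index
    )
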