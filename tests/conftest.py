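import numpy as np
import pytest

from hpbridge import synthdata as sd
from hpbridge.seqmap import ModelParams, full_map


@pytest.fixture(scope="session")
def oracle_l4():
    return sd.oracle_enumerate(4)


@pytest.fixture(scope="session")
def oracle_l6():
    return sd.oracle_enumerate(6)


@pytest.fixture(scope="session")
def oracle_l8():
    return sd.oracle_enumerate(8)


@pytest.fixture(scope="session")
def map_l8():
    return full_map(ModelParams(L=8))


@pytest.fixture(scope="session")
def map_l10():
    return full_map(ModelParams(L=10))


@pytest.fixture
def synth_pdb(tmp_path):
    """Factory writing a synthetic contact-density PDB and returning its path."""

    def build(**kwargs):
        spec = sd.SyntheticStructureSpec(**kwargs)
        path = tmp_path / f"synth_{abs(hash(spec)) % 10**8}.pdb"
        sd.make_synthetic_structure(spec, path)
        return path

    return build


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20120913)
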