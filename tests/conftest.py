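import numpy as np
import pytest

from sapn.assembly import assemble_particle, build_monomer
from sapn.designs import full_length_construct, mini_peptide
from sapn.icosa import build_wedge, make_frame


@pytest.fixture(scope="session")
def frame():
    return make_frame()


@pytest.fixture(scope="session")
def wedge(frame):
    return build_wedge(frame)


@pytest.fixture(scope="session")
def peptide1():
    return mini_peptide(1)


@pytest.fixture(scope="session")
def monomer(peptide1):
    """Peptide-1 building block at the exact icosahedral hinge angle."""
    return build_monomer(peptide1)


@pytest.fixture(scope="session")
def particle(monomer, frame):
    """The assembled 60-chain mini nanoparticle (built once per session)."""
    return assemble_particle(monomer, frame)


@pytest.fixture
def rng():
    return np.random.default_rng(20151024)
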