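import pytest

from fluoribo import composition as C
from fluoribo import simulate as S


@pytest.fixture(scope="session")
def ribosome():
    """Synthetic four-species ribosome composition (fixed seed)."""
    return S.default_ribosome_composition(seed=0)


@pytest.fixture()
def small_comp():
    """Tiny hand-checkable composition: A=4, C=2, G=2, U=2."""
    seq = C.RnaSequence(id="toy", residues="AAAACCGGUU")
    return C.ribosome_composition([("toy", C.nucleotide_composition(seq))])
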