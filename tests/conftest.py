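import numpy as np
import pytest

from fireflyfold.lattice import CUBIC, FCC, Conformation


@pytest.fixture(params=["cubic", "fcc"], ids=["cubic", "fcc"])
def lattice(request):
    return CUBIC if request.param == "cubic" else FCC


@pytest.fixture
def square_hhhh():
    """Cubic 4-mer folded into a unit square: one h-h contact, energy -1."""
    return Conformation("hhhh", [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)], CUBIC)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
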