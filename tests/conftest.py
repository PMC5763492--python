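import numpy as np
import pytest

from carbmotif import Fragment, ProteinRecord
from carbmotif.alphabet import AMINO_ACIDS


def frag(window: str, label: str = "positive", source=("P1", 1)) -> Fragment:
    """Build a Fragment from a raw window string (centre inferred)."""
    n = len(window) // 2
    return Fragment(window=window, center_residue=window[n], label=label,
                    source=source)


@pytest.fixture
def rng():
    return np.random.default_rng(20170)


@pytest.fixture
def toy_protein():
    return ProteinRecord(id="TOY1", sequence="MKVLKACDEFGHKNPQRSTWYK")


def random_window(rng, n=10, center="K") -> str:
    aa = np.array(list(AMINO_ACIDS))
    sym = rng.integers(0, 20, size=2 * n + 1)
    w = "".join(aa[sym])
    return w[:n] + center + w[n + 1:]
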