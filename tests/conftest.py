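import numpy as np
import pytest

from grooveslide.io import make_atom_array


def ca_protein(res_names, spacing=3.8, chain="A", jitter=0.0, seed=0):
    """Straight CA-only chain with the given residue names."""
    n = len(res_names)
    coords = np.zeros((n, 3))
    coords[:, 0] = np.arange(n) * spacing
    if jitter:
        coords += np.random.default_rng(seed).normal(0, jitter, coords.shape)
    return make_atom_array(coords, ["CA"] * n, res_names,
                           list(range(1, n + 1)), [chain] * n, ["C"] * n)


@pytest.fixture
def tripeptide():
    return ca_protein(["LYS", "GLY", "GLU"])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
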