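import itertools

import numpy as np
import pytest

from gcdeform import DisplacementField, Volume
from gcdeform.energy import move_energy


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_volume(rng):
    return Volume(rng.random((8, 8, 8)) * 100.0)


def zero_field(shape):
    return DisplacementField.zeros(shape)


def brute_force_min(terms):
    """Independent oracle: exhaustive minimum of a block move energy."""
    n = len(terms.voxels)
    best_e = np.inf
    best_l = None
    for bits in itertools.product((0, 1), repeat=n):
        lab = np.array(bits)
        e = move_energy(terms, lab)
        if e < best_e:
            best_e = e
            best_l = lab
    return best_l, best_e


def brute_force_tables_min(unary, pairs, pairwise):
    """Exhaustive minimum over raw unary/pairwise tables."""
    n = len(unary)
    best = np.inf
    for bits in itertools.product((0, 1), repeat=n):
        lab = np.array(bits)
        e = unary[np.arange(n), lab].sum()
        for (i, j), tab in zip(pairs, pairwise):
            e += tab[2 * lab[i] + lab[j]]
        best = min(best, e)
    return best
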