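import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

import phylopart as pp


@pytest.fixture
def quartet():
    return pp.PhyloTree.from_newick("((A,B),(C,D));")


@pytest.fixture
def quartet_alt():
    return pp.PhyloTree.from_newick("((A,C),(B,D));")


@pytest.fixture
def rng():
    return np.random.default_rng(20170059)


def random_column(rng, n_taxa, n_states=3, p_missing=0.15, p_poly=0.15):
    """A random cell column with missing and polymorphic entries."""
    cells = []
    for _ in range(n_taxa):
        r = rng.random()
        if r < p_missing:
            cells.append(None)
        elif r < p_missing + p_poly and n_states >= 2:
            k = int(rng.integers(2, n_states + 1))
            cells.append(
                frozenset(rng.choice(n_states, size=k, replace=False).tolist())
            )
        else:
            cells.append(int(rng.integers(n_states)))
    if all(c is None for c in cells):
        cells[0] = 0
    return pp.CharacterColumn(tuple(cells))


@pytest.fixture
def small_matrix():
    """6 taxa, 4 characters (2 hard, 2 soft), mixed content."""
    return pp.matrix_from_strings(
        ["a", "b", "c", "d", "e", "f"],
        [
            [0, 0, 0, 0],
            [0, 1, 0, {0, 1}],
            [1, 1, None, 1],
            [1, 2, 1, 1],
            [1, 2, 1, None],
            [0, 0, 1, 0],
        ],
        ordering=["unordered", "ordered", "unordered", "unordered"],
        partition=["hard", "hard", "soft", "soft"],
    )
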