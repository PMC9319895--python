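import numpy as np
import pytest

import taxodelim as td


@pytest.fixture(scope="session")
def three_pop_matrix():
    """Three well-separated populations, four diploids each, no missing."""
    model = td.SpeciesModel(
        td.star_tree(["P1", "P2", "P3"], 0.4),
        n_individuals=4,
        n_sites=2000,
        seed=11,
    )
    matrix, truth = td.simulate_snp_matrix(model)
    return matrix, truth


@pytest.fixture(scope="session")
def bent_leaf_pair():
    """One strongly bent synthetic leaf with its straight ground truth."""
    model = td.LeafModel(
        length=400.0, dissection=1.0, bend_curvature=0.002, seed=7
    )
    return td.simulate_leaf(model)


@pytest.fixture(scope="session")
def small_landscape():
    return td.simulate_landscape(
        td.LandscapeModel(n_rows=30, n_cols=30, seed=5, n_occurrences=40)
    )


def codes_matrix(rows, taxa=None):
    """SnpMatrix from a list of genotype-code strings."""
    ids = [f"s{i}" for i in range(len(rows))]
    labels = {s: (taxa[i] if taxa else s) for i, s in enumerate(ids)}
    codes = np.array([list(r) for r in rows], dtype="U1")
    return td.SnpMatrix(ids, labels, codes)
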