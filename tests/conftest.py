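import numpy as np
import pytest

from anfscreen import default_catalog
from anfscreen.pangenome import PresenceMatrix


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture()
def toy_consortium_matrix():
    """Four genomes x four features; features 1-2 category A, 3-4 category B."""
    return PresenceMatrix(
        genome_ids=("g1", "g2", "g3", "g4"),
        feature_ids=("f1", "f2", "f3", "f4"),
        cells=np.array(
            [
                [1, 1, 0, 0],
                [0, 0, 1, 1],
                [1, 0, 1, 0],
                [1, 1, 1, 0],
            ]
        ),
        feature_category={"f1": "A", "f2": "A", "f3": "B", "f4": "B"},
        mode="enzyme",
    )


def random_matrix(rng, n_genomes, n_features, n_categories=3, density=0.4):
    """Random presence matrix with evenly assigned categories."""
    cells = (rng.random((n_genomes, n_features)) < density).astype(int)
    feature_ids = tuple(f"f{j}" for j in range(n_features))
    cats = {f: f"cat{j % n_categories}" for j, f in enumerate(feature_ids)}
    return PresenceMatrix(
        genome_ids=tuple(f"g{i:02d}" for i in range(n_genomes)),
        feature_ids=feature_ids,
        cells=cells,
        feature_category=cats,
        mode="enzyme",
    )
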