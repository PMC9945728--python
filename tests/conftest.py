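import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ixonet.network import InteractionMatrix
from ixonet.records import AssociationRecord, Realm, Stage
from ixonet.trees import tree_from_string


@pytest.fixture
def small_tree():
    """((A:1,B:1):1,C:2); — 3 tips, total length 5."""
    return tree_from_string("((A:1,B:1):1,C:2);")


@pytest.fixture
def sample_records():
    """Two species over three families in two realms, with stage structure."""
    R = AssociationRecord
    return [
        R("Ixodes_a", Stage.LARVA, "Muridae", "Rodentia", Realm.PALEARCTIC, 12),
        R("Ixodes_a", Stage.NYMPH, "Muridae", "Rodentia", Realm.PALEARCTIC, 5),
        R("Ixodes_a", Stage.NYMPH, "Turdidae", "Passeriformes", Realm.PALEARCTIC, 3),
        R("Ixodes_a", Stage.ADULT, "Cervidae", "Artiodactyla", Realm.PALEARCTIC, 7),
        R("Ixodes_b", Stage.ADULT, "Turdidae", "Passeriformes", Realm.NEARCTIC, 2),
        R("Ixodes_b", Stage.UNKNOWN, "Muridae", "Rodentia", Realm.NEARCTIC, 1),
    ]


def random_matrix(rng: np.random.Generator, shape=(6, 6), max_weight=5) -> InteractionMatrix:
    """Random weighted matrix without all-zero rows/columns."""
    while True:
        values = rng.integers(0, max_weight + 1, size=shape)
        if (values.sum(axis=1) > 0).all() and (values.sum(axis=0) > 0).all():
            return InteractionMatrix(
                row_labels=[f"t{i}" for i in range(shape[0])],
                col_labels=[f"h{j}" for j in range(shape[1])],
                values=values,
            )
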