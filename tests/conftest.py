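"""Shared fixtures: random model construction and the published-tally matrix."""
from __future__ import annotations

import numpy as np
import pytest

from accident_bn.catalog_io import ACCIDENT_TYPES
from accident_bn.reference_data import counts_matrix
from accident_bn.tan_model import CLASS_NODE, Cpt, SmoothingPolicy, TanModel, TanStructure


def random_model(rng: np.random.Generator, n_features: int) -> TanModel:
    """A random TAN over ``B1..Bn``: random recursive tree, random CPTs.

    Built directly through the model API (not the synthetic generator) so
    oracle comparisons exercise an independent construction path.
    """
    features = tuple(f"B{k}" for k in range(1, n_features + 1))
    parents: dict[str, str | None] = {features[0]: None}
    for k in range(1, n_features):
        parents[features[k]] = features[int(rng.integers(0, k))]
    structure = TanStructure(
        class_states=ACCIDENT_TYPES,
        features=features,
        parents=parents,
        root=features[0],
    )
    prior = rng.dirichlet(np.ones(4))
    cpts = {CLASS_NODE: Cpt(CLASS_NODE, (), prior)}
    for f in features:
        parent = parents[f]
        if parent is None:
            p_yes = rng.uniform(0.05, 0.95, size=4)
            cpts[f] = Cpt(f, (CLASS_NODE,), np.stack([1 - p_yes, p_yes]))
        else:
            p_yes = rng.uniform(0.05, 0.95, size=(4, 2))
            table = np.empty((2, 4, 2))
            table[1] = p_yes
            table[0] = 1 - p_yes
            cpts[f] = Cpt(f, (CLASS_NODE, parent), table)
    return TanModel(structure, cpts, SmoothingPolicy(0.0), {"source": "random test model"})


@pytest.fixture(scope="session")
def reference_matrix():
    """Case matrix reconstructing the published per-type occurrence tallies."""
    return counts_matrix()
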