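"""Shared fixtures: planted-signal dataset and a trained registry.

The planted fixture is the package's standard study condition: 200
genomes x 500 KOs, 5 classes with 20 informative KOs each (expected copy
number 5 in positives), 30 positives per class, 5% cell noise.  Training
the registry on it takes a couple of minutes, so it is session-scoped and
shared by the apply/refine/acceptance tests.
"""

import pytest

from traitpred import learn, synth

PLANTED_SEED = 101


@pytest.fixture(scope="session")
def planted_truth():
    return synth.make_default_truth(seed=PLANTED_SEED)


@pytest.fixture(scope="session")
def planted(planted_truth):
    """(annotations, labels, TraitDataset) for the planted fixture."""
    return synth.synth_dataset(planted_truth)


@pytest.fixture(scope="session")
def planted_dataset(planted):
    return planted[2]


@pytest.fixture(scope="session")
def planted_registry(planted_dataset):
    """Registry trained on the planted fixture at default grids."""
    return learn.train_registry(
        planted_dataset, learn.TrainConfig(seed=PLANTED_SEED)
    )


@pytest.fixture(scope="session")
def taxonomy_fixture():
    """(index, truth) for a 5-species, 2-strain taxonomy dump."""
    from traitpred import taxonomy

    names, nodes, merged, truth = synth.synth_taxonomy(5, 2, seed=7)
    return taxonomy.load_taxonomy(names, nodes, merged), truth


# small fast grids for unit tests that only need *a* trained model
FAST_GRIDS = {
    "LR": [{"C": 1.0, "penalty": "l2"}],
    "SVM": [{"kernel": "linear", "C": 1.0}],
    "RF": [{"n_trees": 50, "max_features_rule": "sqrt"}],
}


@pytest.fixture(scope="session")
def fast_config():
    return learn.TrainConfig(grids=FAST_GRIDS, seed=13)
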