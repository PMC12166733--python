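import pytest

from featshift import (FixtureSpec, ResidueClassifier, TrainingConfig,
                       generate_fixture_set, split_by_cluster, toy_backbone)


@pytest.fixture(scope="session")
def fixture_set():
    """Default synthetic dataset: 60 proteins in 12 families, motif feature."""
    return generate_fixture_set(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def split(fixture_set):
    return split_by_cluster(fixture_set.clusters(), seed=1)


def _subset(fixture_set, split, name):
    proteins = [p for p in fixture_set.proteins
                if split.assignment[p.id] == name]
    tracks = [t for t in fixture_set.true_tracks
              if split.assignment[t.protein_id] == name]
    return proteins, tracks


@pytest.fixture(scope="session")
def test_subset(fixture_set, split):
    return _subset(fixture_set, split, "test")


@pytest.fixture(scope="session")
def motif_results(fixture_set, split):
    """A trained frozen-embedding motif classifier on the windowed encoder.

    Class weighting is enabled: motif residues are rare (~5%), and the
    gain/loss-calling workflow needs probabilities calibrated enough for the
    positive class to cross the 0.5 decision threshold.
    """
    backbone = toy_backbone("onehot_window", window=1)
    model = ResidueClassifier.from_dataset(
        fixture_set.proteins, fixture_set.true_tracks, split.assignment,
        "motif", backbone,
        training_config=TrainingConfig(seed=1, class_weighting=True),
    )
    return model.fit()


@pytest.fixture(scope="session")
def motif_checkpoint(motif_results):
    return motif_results.checkpoint
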