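import numpy as np
import pytest
from hypothesis import settings

from herbnet import (
    Corpus,
    Herb,
    ModelConfig,
    Prescription,
    SynthConfig,
    build_graph,
    compatibility,
    filter_molecules,
    generate_corpus,
    train,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_corpus(prescriptions: list[set[str]], extra_herbs=()) -> Corpus:
    """Corpus with only herbs and prescriptions (no molecular annotation)."""
    herbs = sorted(set().union(*prescriptions, extra_herbs))
    return Corpus(
        herbs={h: Herb(h) for h in herbs},
        molecules={},
        targets={},
        prescriptions=[
            Prescription(f"r{i}", frozenset(p)) for i, p in enumerate(prescriptions)
        ],
    )


@pytest.fixture(scope="session")
def worked_example_corpus():
    """The two-prescription corpus {A,B,C}, {A,B} with denominator D = 4."""
    return make_corpus([{"A", "B", "C"}, {"A", "B"}])


# Small planted-block corpus shared by graph/model/scoring tests.
SMALL_CFG = SynthConfig(
    n_herbs=20,
    n_prescriptions=80,
    rx_size_range=(3, 6),
    n_blocks=2,
    within_block_boost=8.0,
    n_molecules=40,
    n_molecules_per_herb=(3, 6),
    n_targets=50,
    n_targets_per_mol=(5, 15),
    n_terms=12,
    seed=2,
)


@pytest.fixture(scope="session")
def small_corpus():
    return filter_molecules(generate_corpus(SMALL_CFG))


@pytest.fixture(scope="session")
def small_labels(small_corpus):
    return compatibility(small_corpus)


@pytest.fixture(scope="session")
def small_graph(small_corpus, small_labels):
    return build_graph(small_corpus, small_labels)


@pytest.fixture(scope="session")
def small_model(small_graph, small_labels):
    cfg = ModelConfig(hidden_channels=32, learning_rate=1e-3, epochs=40, seed=0)
    return train(small_graph, small_labels, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
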