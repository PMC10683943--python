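"""Shared fixtures: small seeded synthetic corpora."""

import pytest

from drugprotkit.synth import SynthConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """Mixed corpus with ~10% cross-sentence relations and distractors."""
    return generate_corpus(SynthConfig(n_docs=40, seed=123))


@pytest.fixture(scope="session")
def intra_corpus():
    """Corpus whose gold relations are all intra-sentence."""
    return generate_corpus(SynthConfig(n_docs=40, seed=321, cross_sentence_fraction=0.0))
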