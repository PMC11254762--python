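"""Shared fixtures: small synthetic sessions reused across test modules.

Session-scoped fixtures amortise generation cost; tests must not mutate them.
"""

import numpy as np
import pytest
from hypothesis import settings

import neurosem as ns

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cfg():
    """A scaled-down world for fast structural tests."""
    return ns.GeneratorConfig(
        n_domains=4, words_per_domain=12, dim=24, n_sentences=30,
        n_units=30, homophone_pairs=3, nonword_blocks=2,
        story_vocab_new=6, story_vocab_shared=4, n_story_sentences=4,
        min_homophone_occurrences=5, seed=11,
    )


@pytest.fixture(scope="session")
def small_session(small_cfg):
    return ns.generate_session(small_cfg)


@pytest.fixture(scope="session")
def small_matrix(small_session):
    return ns.align_responses(small_session.spikes, small_session.events)


@pytest.fixture(scope="session")
def default_session():
    """One full paper-scale session (133 units, 131 sentences, 9 domains)."""
    return ns.generate_session(ns.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def default_matrix(default_session):
    return ns.align_responses(default_session.spikes, default_session.events)


@pytest.fixture(scope="session")
def default_selectivity(default_session, default_matrix):
    sent = ns.select_events(default_matrix, conditions="sentence")
    return ns.domain_selectivity(sent, default_session.partition)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
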