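"""Shared fixtures: small synthetic corpora generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from sleepscan.synth import CorpusSpec, LognormalCount, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """60 reports at reduced numeric density: fast but structurally complete."""
    spec = CorpusSpec(
        n_reports=60,
        seed=11,
        numerics_per_page=LognormalCount(median=12, sigma=0.25, lo=6, hi=25),
    )
    return generate_corpus(spec)


@pytest.fixture(scope="session")
def default_corpus_small():
    """100 reports under the default (study-condition) corpus settings."""
    return generate_corpus(CorpusSpec(n_reports=100, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
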