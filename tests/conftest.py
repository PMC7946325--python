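"""Shared fixtures: the two-gene/two-ROI prototype model and small datasets."""

import numpy as np
import pytest

from iggsca.data import Dataset, standardize
from iggsca.model import build_model


@pytest.fixture
def prototype_spec():
    """Two genes and two brain regions (two indicators each) plus a
    single-indicator behavioral outcome; seven directed paths."""
    comps = [
        ("gene1", ["z1", "z2"]),
        ("gene2", ["z3", "z4"]),
        ("roi1", ["z5", "z6"]),
        ("roi2", ["z7", "z8"]),
        ("behavior", ["z9"]),
    ]
    paths = [
        ("gene1", "roi1"), ("gene1", "roi2"),
        ("gene2", "roi1"), ("gene2", "roi2"),
        ("roi1", "roi2"),
        ("roi1", "behavior"), ("roi2", "behavior"),
    ]
    return build_model(comps, [], paths)


@pytest.fixture
def interaction_spec():
    """A gene, a single-indicator environment, their interaction, one ROI
    and an outcome."""
    comps = [
        ("gene", ["s1", "s2", "s3"]),
        ("env", ["e"]),
        ("roi", ["r1", "r2"]),
        ("out", ["o"]),
    ]
    inters = [("gene", "env")]
    paths = [
        ("gene", "roi"), ("env", "roi"), ("gene x env", "roi"),
        ("roi", "out"), ("env", "out"),
    ]
    return build_model(comps, inters, paths)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def prototype_data(prototype_spec, rng):
    X = rng.normal(size=(120, 9))
    return standardize(Dataset(X, prototype_spec.observed))


@pytest.fixture
def interaction_data(interaction_spec, rng):
    X = rng.normal(size=(150, 7))
    return standardize(Dataset(X, interaction_spec.observed))
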