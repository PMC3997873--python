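import logging
import warnings

import numpy as np
import pytest

from dermamiml.imaging_io import DEFAULT_VOCABULARY, Bag, TermVector
from dermamiml.synthetic_data import SynthConfig, generate_bags


@pytest.fixture(autouse=True)
def _quiet_warnings():
    """Degenerate-geometry warnings are expected on tiny fixtures."""
    logging.disable(logging.WARNING)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
    logging.disable(logging.NOTSET)


@pytest.fixture
def vocab():
    return DEFAULT_VOCABULARY


@pytest.fixture
def small_bag_config():
    """Five independent terms, 2-D instances, well-separated clusters."""
    return SynthConfig(
        n_terms=5,
        term_frequencies=(0.5, 0.4, 0.4, 0.3, 0.3),
        instance_dim=2,
        instance_range=(3, 6),
        effect_separation=4.0,
        regions_per_image=5,
    )


@pytest.fixture
def small_bags(small_bag_config):
    return generate_bags(small_bag_config, 20, rng_seed=11)


def make_bag(rows, source_id="b"):
    return Bag(np.asarray(rows, dtype=float), source_id=source_id)


def make_terms(bits, vocabulary=None):
    bits = np.asarray(bits, dtype=np.int8)
    if vocabulary is None:
        vocabulary = tuple(f"term{i + 1}" for i in range(len(bits)))
    return TermVector(bits, vocabulary)
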