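import numpy as np
import pytest
from hypothesis import settings

from m5cpred.properties import DINUCLEOTIDES, PropertyTable, load_property_table, standardize

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

_IDX = {d: i for i, d in enumerate(DINUCLEOTIDES)}


def toy_table(*prop_value_maps, standardized=True):
    """Build a small property table from {dinucleotide: value} mappings."""
    vals = np.zeros((len(prop_value_maps), 16))
    for row, mapping in enumerate(prop_value_maps):
        for d, v in mapping.items():
            vals[row, _IDX[d]] = v
    names = tuple(f"p{i + 1}" for i in range(len(prop_value_maps)))
    return PropertyTable(names, vals, standardized=standardized)


@pytest.fixture(scope="session")
def default_table():
    return standardize(load_property_table())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_window(rng, length=41):
    """A random C-centered window."""
    chars = rng.choice(list("ACGU"), size=length)
    chars[length // 2] = "C"
    return "".join(chars)
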