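import numpy as np
import pytest

import fggaze as fg


@pytest.fixture(scope="session")
def base_pair():
    """One deterministic shape pair at a raster fine enough for geometry."""
    return fg.generate_shape_pair(0, extent_deg=9.0, px_per_deg=20.0)


@pytest.fixture(scope="session")
def variant_set(base_pair):
    return fg.make_variant_set(base_pair)


@pytest.fixture(scope="session")
def one_stimulus(variant_set):
    return variant_set[0]


@pytest.fixture(scope="session")
def full_set():
    """The complete factorial stimulus set (38 bases) at a modest raster."""
    return fg.build_stimulus_set(n_bases=38, extent_deg=9.0, px_per_deg=16.0,
                                 seed=0)


@pytest.fixture(scope="session")
def full_manifest(full_set):
    return full_set[1]
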