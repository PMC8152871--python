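import numpy as np
import pytest

from syntaxconn import classify_pairs, default_catalog
from syntaxconn.catalog import RegionCatalog, RegionSpec


@pytest.fixture(scope="session")
def catalog25():
    return default_catalog()


@pytest.fixture(scope="session")
def pairs25(catalog25):
    return classify_pairs(catalog25)


@pytest.fixture(scope="session")
def core14(catalog25):
    return catalog25.core()


def make_catalog(network_of: dict[str, str], spacing_mm: float = 30.0) -> RegionCatalog:
    """Small synthetic catalog: regions on a line, far enough apart
    that 6-mm spheres never overlap."""
    regions = []
    for k, (name, network) in enumerate(network_of.items()):
        regions.append(
            RegionSpec(
                name=name,
                side="left",
                network=network,
                center_mm=(-60.0 + k * spacing_mm, 0.0, 0.0),
            )
        )
    return RegionCatalog(tuple(regions))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
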