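import numpy as np
import pytest

from oxysites.io_model import Alignment, SiteRecord
from oxysites.site_encoding import load_zscales


@pytest.fixture(scope="session")
def zscales():
    return load_zscales()


@pytest.fixture
def toy_alignment():
    """Six sequences, two obvious groups differing at columns 2 and 4."""
    rows = {
        "s1": "AKLDEF",
        "s2": "AKLDEF",
        "s3": "AKLDEF",
        "s4": "AGLWEF",
        "s5": "AGLWEF",
        "s6": "AGLWEF",
    }
    return Alignment(
        ids=list(rows),
        rows=list(rows.values()),
        species_of={i: f"sp_{i}" for i in rows},
    )


@pytest.fixture
def toy_sites():
    return [SiteRecord("TOY", c) for c in range(1, 7)]


@pytest.fixture
def rng():
    return np.random.default_rng(42)
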