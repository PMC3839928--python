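import numpy as np
import pytest

from translen.lengthstats import LengthTable
from translen.model import ACSParams, GelGrid


@pytest.fixture
def grid50():
    return GelGrid.uniform(26.0, 50, 2.0)


@pytest.fixture
def params():
    return ACSParams(x0=84.0, k=0.1, s=2.0)


@pytest.fixture
def six_length_table():
    """The enumeration toy: lengths 1..6, subset {1, 2}."""
    ids = [f"g{i}" for i in range(1, 7)]
    return LengthTable(
        entity_ids=ids,
        lengths=np.arange(1.0, 7.0),
        annotation_sets={"short": {"g1", "g2"}},
    )
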