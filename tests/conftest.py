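import numpy as np
import pytest

from butyrogen import CultureRecord, default_registry, default_thermo_table


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def thermo_table():
    return default_thermo_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def worked_example_record():
    """Monoculture fixture: glucose 10 mM consumed, butyrate 5, net acetate -2,
    formate 1, lactate 0 (all mM)."""
    return CultureRecord(
        culture_id="wx1", strain="demo", condition="H2",
        endpoint={"glucose": 0.0, "butyrate": 5.0, "acetate": 28.0,
                  "formate": 1.0, "lactate": 0.0},
        blank={"glucose": 10.0, "butyrate": 0.0, "acetate": 30.0,
               "formate": 0.0, "lactate": 0.0},
    )
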