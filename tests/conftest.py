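import numpy as np
import pytest

from defacall import ErrorModel, MeasurementPanel


@pytest.fixture
def model():
    """Default error model: sigma 0.114/0.12 PRT, 0.15 log-ratio, range 2-16."""
    return ErrorModel()


@pytest.fixture
def full_panel():
    """A complete five-measurement panel around 7 copies."""
    return MeasurementPanel.from_values(
        "S7",
        {"MLT1A0": 7.07, "DEFA4": 7.03, "indel5": 1.32, "DefHae3": 2.38, "7bpdup": 2.43},
    )


def assert_valid_row(row):
    row = np.asarray(row)
    assert np.all(row >= 0) and np.all(row <= 1)
    assert row.max() == 1.0
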