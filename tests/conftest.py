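import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pytest
from hypothesis import settings

from harmviz import synthetic

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def ds():
    """The hand-enumerable 8-participant, 2-arm dataset."""
    return synthetic.fixture_small()


@pytest.fixture(autouse=True)
def _close_figures():
    yield
    plt.close("all")
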