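import numpy as np
import pytest

from rmda.datamodel import DesignSet, ResponsePanel


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def small_panel(rng):
    """4 individuals x 2 gaussian responses x 3 occasions, labelled 1/2."""
    values = rng.normal(size=(4, 2, 3))
    panel = ResponsePanel(values, ["gaussian", "gaussian"],
                          group_label=np.array([1, 1, 2, 2]))
    design = DesignSet(x=rng.normal(size=4), t=np.array([1.0, 2.0, 3.0]))
    return panel, design
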