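import numpy as np
import pytest

from socialconcord import RatingPanel


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def tiny_panel(rng):
    """5 items x 3 features x 4 raters with a couple of missing cells."""
    cube = rng.uniform(0, 10, size=(5, 3, 4))
    cube[0, 0, 1] = np.nan
    cube[3, 2, 0] = np.nan
    return RatingPanel(
        items=[f"i{k}" for k in range(5)],
        features=["a", "b", "c"],
        raters=[f"r{k}" for k in range(4)],
        ratings=cube,
    )
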