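import numpy as np
import pandas as pd
import pytest

from cystirep import synthdata as sd


@pytest.fixture
def small_screen_cfg():
    """A 40-compound zero-noise screen with two planted depleters."""
    return sd.ScreenSimConfig(
        n_compounds=40,
        wells_per_plate=48,
        neg_ctrl_per_plate=4,
        pos_ctrl_per_plate=4,
        planted_hits=(("CPD0003", 0.8), ("CPD0017", 0.55)),
        noise_sd=0.0,
        seed=5,
    )


@pytest.fixture
def tiny_counts():
    """A hand-checkable 3-gene, 2-sample count matrix (sample B = 2 x A)."""
    return pd.DataFrame(
        {"A": [10, 100, 1], "B": [20, 200, 2]},
        index=pd.Index(["g1", "g2", "g3"], name="gene"),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
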