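import numpy as np
import pandas as pd
import pytest

from fibroscore import synthdata


@pytest.fixture(scope="session")
def fixture_study():
    """The bundled small end-to-end study (degenerate coupling, seed 1)."""
    return synthdata.simulate_all(synthdata.make_fixture_config(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_design(sources=("A", "B", "C"), n_rep=3):
    rows = [
        {"sample_id": f"{s}_{c}_{r}", "source": s, "condition": c, "replicate": r}
        for s in sources
        for c in ("control", "treated")
        for r in range(1, n_rep + 1)
    ]
    return pd.DataFrame(rows)


@pytest.fixture()
def small_design():
    return make_design()
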