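import numpy as np
import pytest

import seqrep as s


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_positional_env():
    """Last-position-only world, 10 stimuli, 4 templates."""
    return s.build_positional_env(
        n_stimuli=10, n_templates=4, informative_positions=(0, 0, 0, 1.0)
    )


@pytest.fixture
def default_params():
    return s.AnalyticParams(n=12, r=0.5, tau=10.0, T=10_000)
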