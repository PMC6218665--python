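import numpy as np
import pytest

import monofem as mf


@pytest.fixture(scope="session")
def rod_run_h02():
    """A near-converged plane-wave rod run shared by measurement tests."""
    cfg = mf.protocol_rod(h=0.2, dt=0.005, t_end=150.0)
    mesh, result = mf.execute(cfg)
    return mesh, result


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
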