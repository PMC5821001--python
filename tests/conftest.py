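import numpy as np
import pytest

from phibar import synth
from phibar.preprocess import segment_epochs


@pytest.fixture(scope="session")
def white_epochs_16():
    """16 independent unit-variance white channels, 60 s at 500 Hz."""
    rng = np.random.default_rng(2024)
    from phibar.io import TimeSeriesMatrix
    ts = TimeSeriesMatrix(rng.standard_normal((16, 30000)), 500.0,
                          [f"E{i+1}" for i in range(16)])
    return segment_epochs(ts, 6, 10)


@pytest.fixture(scope="session")
def coupled_epochs_16():
    """Homogeneously coupled 16-channel VAR, 60 s at 500 Hz."""
    model = synth.homogeneous_var(16, spectral_radius=0.9)
    ts = synth.simulate(model, 60, seed=77)
    return segment_epochs(ts, 6, 10)


@pytest.fixture(scope="session")
def two_pair_var():
    """4-channel VAR of two independent coupled pairs (1<->2, 3<->4)."""
    A = np.zeros((4, 4))
    A[:2, :2] = [[0.5, 0.3], [0.3, 0.5]]
    A[2:, 2:] = [[0.5, 0.3], [0.3, 0.5]]
    return synth.VARModel(A=A, alpha=np.zeros(4), noise_cov=np.eye(4))
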