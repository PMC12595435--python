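import numpy as np
import pytest

import esprox as ep


@pytest.fixture(scope="session")
def small_topology():
    """Connected random graph reused across simulation tests."""
    return ep.generate_topology("random", 25, 100, seed=7)


@pytest.fixture(scope="session")
def warm_integrator(small_topology):
    """Trigger JIT compilation once so timing-sensitive tests stay fast."""
    cfg = ep.SimulationConfig(duration=1.0, transient=0.5, seed=0,
                              store_state=False)
    ep.simulate(small_topology, cfg)
    return True


def fgn(hurst: float, n: int, seed: int) -> np.ndarray:
    """Fractional Gaussian noise by circulant embedding (Davies-Harte).

    Independent oracle for the DFA estimator: the autocovariance of fGn
    with Hurst exponent H is gamma(k) = 0.5 (|k+1|^2H - 2|k|^2H + |k-1|^2H).
    """
    k = np.arange(n)
    gamma = 0.5 * (
        np.abs(k + 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    eig = np.fft.fft(row).real
    eig[eig < 0] = 0.0
    m = row.size
    rng = np.random.default_rng(seed)
    w = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    sample = np.fft.fft(np.sqrt(eig / (2 * m)) * w)
    return np.sqrt(2) * sample[:n].real
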