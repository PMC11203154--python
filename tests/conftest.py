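import numpy as np
import pytest

from spikelft.kernelspace import BinaryKernel


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture
def random_kernel(rng):
    def make(n=6, t=9, p=0.4, tau_ms=1.0):
        return BinaryKernel(values=(rng.random((n, t)) < p).astype(int),
                            tau_ms=tau_ms)
    return make
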