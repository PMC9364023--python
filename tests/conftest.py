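import numpy as np
import pytest

import kymoblink as kb
from kymoblink import blink


@pytest.fixture
def exact_mixture_histogram():
    """Factory: percentage histogram built from exact mixture pmf values."""

    def _make(bl_mon, alpha, duration_s, max_n=40, n_kymographs=50):
        n = np.arange(max_n + 1)
        p = kb.mixture_pmf(n, bl_mon, alpha, duration_s) * 100.0
        p = p / p.sum() * 100.0  # renormalize the truncated tail
        return blink.BlinkHistogram(
            duration_s=duration_s,
            percent_at_n={int(i): float(v) for i, v in zip(n, p)},
            n_kymographs=n_kymographs,
        )

    return _make


@pytest.fixture
def default_kymo():
    """One default-SNR simulated kymograph with ground truth (seed 7)."""
    return kb.simulate_kymograph(kb.KymoSimParams(seed=7))
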