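import numpy as np
import pytest

import helicount as hc


@pytest.fixture(scope="session")
def channel():
    return hc.ChannelSpec()


def make_plan(n_pairs: int) -> hc.AcquisitionPlan:
    """Full physical field of view on the 4x-downscaled 320x240 test grid."""
    return hc.AcquisitionPlan(n_frame_pairs=n_pairs).downscaled(4)


@pytest.fixture(scope="session")
def noisy_scan(channel):
    """Default-noise scan reused by synthgen/quantify tests (seed 7, 12 pairs)."""
    return hc.generate_scan(7, hc.PopulationSpec(), hc.NoiseSpec(), make_plan(12), channel)


@pytest.fixture(scope="session")
def lossless_scan(channel):
    """Noise-free well-separated scan with exact-recovery guarantees."""
    pop, noise = hc.exact_recovery_conditions()
    return hc.generate_scan(3, pop, noise, make_plan(12), channel)
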