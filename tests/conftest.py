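import numpy as np
import pytest

from spindleq import SimulationConfig, gen_recording


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_recording():
    """A 3-min synthetic recording shared across tests (seed-fixed)."""
    cfg = SimulationConfig(duration=180.0, seed=42)
    rec, hyp, gt = gen_recording(cfg)
    return cfg, rec, hyp, gt


def brute_force_detect(times, r, r_b, r_a):
    """Reference hysteresis scanner: walk every sample, track state.

    Independent of the vectorised implementation; returns (start_idx,
    end_idx) pairs with end_idx = first index below r_b after the run,
    merged while the dip stays >= r_a.
    """
    events = []
    i, n = 0, len(r)
    while i < n:
        if r[i] >= r_b:
            start = i
            while i < n and r[i] >= r_b:
                i += 1
            end = i
            # try to extend: merge following runs while dip stays >= r_a
            while True:
                j = end
                while j < n and r_a <= r[j] < r_b:
                    j += 1
                if j < n and r[j] >= r_b:
                    while j < n and r[j] >= r_b:
                        j += 1
                    end = j
                else:
                    break
            events.append((start, end))
            i = end
        else:
            i += 1
    return events
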