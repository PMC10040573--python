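import numpy as np
import pytest

import spectraldiff as sd


def poisson_ensemble(
    n_units: int, duration: float, rate: float = 8.0, seed: int = 0
) -> sd.RateMatrix:
    """i.i.d. constant-rate Poisson units, binned and smoothed."""
    rng = np.random.default_rng(seed)
    signal = np.full(int(duration * 200), rate)
    rows = []
    for _ in range(n_units):
        spikes = sd.gen_poisson_spikes(signal, duration, seed=rng)
        rows.append(sd.smooth_rates(sd.bin_spikes(spikes, duration)))
    return sd.RateMatrix(np.stack(rows))


def rates_from_trains(trains, duration: float) -> sd.RateMatrix:
    rows = [
        sd.smooth_rates(sd.bin_spikes(t, duration)) for t in trains
    ]
    return sd.RateMatrix(np.stack(rows))


@pytest.fixture(scope="session")
def iid_ensemble() -> sd.RateMatrix:
    """60 i.i.d. 8 Hz units over 60 s; shared across scaling/flattening tests."""
    return poisson_ensemble(60, 60.0, rate=8.0, seed=0)
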