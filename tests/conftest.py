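import numpy as np
import pytest

from vethresh import synth


@pytest.fixture
def erg_truth():
    return synth.WaveformTruth(noise_sd=0.0, n_sweeps=1, seed=1)


@pytest.fixture
def pilot_truth():
    return synth.DoseResponseTruth(
        theta0=20.5, phi0=1475.0, c1=-0.0221, c2=0.0, sigma=0.0,
        design=synth.pilot_design(), seed=1)


@pytest.fixture
def pilot_records(pilot_truth):
    return synth.generate_dose_response(pilot_truth)


def random_erg_truth(rng: np.random.Generator, seed: int,
                     noise_sd: float = 0.0,
                     n_sweeps: int = 1) -> synth.WaveformTruth:
    """Randomized physiologic truth whose OP train fits the ascending limb."""
    op_freq = rng.uniform(110.0, 140.0)
    period = 1000.0 / op_freq
    a_time = rng.uniform(14.0, 20.0)
    b_time = a_time + 4.0 * period + rng.uniform(6.0, 10.0)
    return synth.WaveformTruth(
        a_amp=rng.uniform(60.0, 180.0), a_time=a_time,
        b_amp=rng.uniform(150.0, 350.0), b_time=b_time,
        op_amps=tuple(rng.uniform(5.0, 15.0, size=4)), op_freq=op_freq,
        phnr_amp=rng.uniform(15.0, 60.0),
        phnr_time=b_time + rng.uniform(40.0, 70.0),
        noise_sd=noise_sd, n_sweeps=n_sweeps, seed=seed)
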