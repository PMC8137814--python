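import numpy as np
import pytest

from interbrain.core import DyadDataset, HbO2Series
from interbrain.preprocess import bandpass
from interbrain.simulate import NoiseSpec, SimulationConfig, generate_dyad


def make_config(seed=0, duration_s=160.0, **overrides) -> SimulationConfig:
    """Small-but-realistic simulation config for fast tests."""
    overrides.setdefault("n_latent_events", max(4, int(duration_s / 20)))
    return SimulationConfig(seed=seed, duration_s=duration_s, **overrides)


def ar_noise_spec(ar_coeff=0.9, ar_amp=1.0, white_sd=0.3) -> NoiseSpec:
    """Purely autoregressive + white noise (no oscillations, no drift)."""
    return NoiseSpec(
        cardiac_amp=0.0,
        respiratory_amp=0.0,
        mayer_amp=0.0,
        drift_amp=0.0,
        ar_coeff=ar_coeff,
        ar_amp=ar_amp,
        white_sd=white_sd,
    )


def bandpassed(dyad: DyadDataset) -> DyadDataset:
    fs = dyad.sampling_rate
    return DyadDataset(
        teacher=HbO2Series(bandpass(dyad.teacher.values, fs), fs, dyad.montage, "band-passed"),
        student=HbO2Series(bandpass(dyad.student.values, fs), fs, dyad.montage, "band-passed"),
        dyad_id=dyad.dyad_id,
        meta=dyad.meta,
    )


@pytest.fixture(scope="session")
def null_dyad() -> DyadDataset:
    dyad, _ = generate_dyad(make_config(seed=11))
    return dyad


@pytest.fixture(scope="session")
def coupled_dyad():
    gain = np.zeros((18, 18))
    for ch in (9, 10, 13):  # TPJ student channels driven by same-index teacher
        gain[ch - 1, ch - 1] = 1.0
    dyad, truth = generate_dyad(make_config(seed=21, duration_s=600.0, coupling_gain=gain))
    return dyad, truth
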