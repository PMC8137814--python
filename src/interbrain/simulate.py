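"""Synthetic fNIRS dyads with known ground-truth cross-brain coupling.

The real recordings behind this kind of hyperscanning analysis are rarely
shareable, so every downstream stage is exercised on simulated dyads whose
coupling structure is known exactly. The generative model follows standard
fNIRS phenomenology:

* a latent "task" signal — quasi-regular event onsets convolved with a
  double-gamma hemodynamic response — whose spectral mass lies inside the
  analysis band (0.01-0.2 Hz);
* teacher channels mixing the shared latent signal with channel-specific
  hemodynamic activity;
* student channels driven by a configurable teacher-channel -> student-channel
  linear gain matrix applied to the teacher's noise-free signal parts
  (all-zero gain = null dyad), plus independent noise;
* physiological noise: cardiac (~1.2 Hz), respiratory (~0.3 Hz) and Mayer
  (~0.1 Hz) oscillations with slowly diffusing phase, an autoregressive
  low-frequency component, random-walk drift, and white measurement noise.

The oscillatory components carry phase noise on purpose: two independent
subjects with *pure* sinusoids at a shared in-band frequency would correlate
at cos(phase difference) no matter how long the recording, which would make
"statistically independent null dyad" unattainable. Phase diffusion makes
the components mixing, so null-dyad correlations vanish with record length.

Teacher and student randomness comes from separate child streams of the
master seed, so a null dyad's two recordings are independent by
construction, not merely uncorrelated in sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter as _lfilter
from scipy.stats import gamma as _gamma_dist

from interbrain.core import DyadDataset, HbO2Series, Montage, RawRecording
from interbrain.preprocess import DEFAULT_DPF, DEFAULT_EXTINCTION, forward_od

__all__ = [
    "HRFParams",
    "NoiseSpec",
    "SimulationConfig",
    "GroundTruth",
    "double_gamma_hrf",
    "generate_latent_signal",
    "generate_dyad",
    "render_raw_intensities",
]


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma hemodynamic response: peak minus scaled undershoot."""

    peak_time_s: float = 6.0
    undershoot_time_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    length_s: float = 30.0


@dataclass(frozen=True)
class NoiseSpec:
    """Amplitudes (uM) and frequencies (Hz) of the physiological noise model.

    ``phase_jitter`` is the standard deviation (radians per sqrt(sample)) of
    the Wiener phase noise on each oscillatory component.
    """

    cardiac_hz: float = 1.2
    cardiac_amp: float = 0.35
    respiratory_hz: float = 0.3
    respiratory_amp: float = 0.25
    mayer_hz: float = 0.1
    mayer_amp: float = 0.4
    drift_amp: float = 0.4
    ar_coeff: float = 0.95
    ar_amp: float = 0.5
    white_sd: float = 0.3
    phase_jitter: float = 0.1

    def sample(self, n: int, sampling_rate: float, rng: np.random.Generator) -> np.ndarray:
        """One channel's worth of noise, shape (n,)."""
        t = np.arange(n) / sampling_rate
        out = np.zeros(n)
        for f, amp in (
            (self.cardiac_hz, self.cardiac_amp),
            (self.respiratory_hz, self.respiratory_amp),
            (self.mayer_hz, self.mayer_amp),
        ):
            if amp > 0:
                phase = rng.uniform(0, 2 * np.pi) + self.phase_jitter * np.cumsum(
                    rng.standard_normal(n)
                )
                out += amp * np.cos(2 * np.pi * f * t + phase)
        if self.drift_amp > 0:
            walk = np.cumsum(rng.standard_normal(n))
            sd = walk.std()
            if sd > 0:
                out += self.drift_amp * walk / sd
        if self.ar_amp > 0:
            a = self.ar_coeff
            # stationary start, then recursive AR(1) via an IIR filter
            init = rng.standard_normal() / np.sqrt(max(1.0 - a * a, 1e-12))
            innov = rng.standard_normal(n)
            ar, _ = _lfilter([1.0], [1.0, -a], innov, zi=[a * init])
            out += self.ar_amp * ar * np.sqrt(1.0 - a * a)
        if self.white_sd > 0:
            out += self.white_sd * rng.standard_normal(n)
        return out

    def sample_matrix(
        self, n: int, n_channels: int, sampling_rate: float, rng: np.random.Generator
    ) -> np.ndarray:
        return np.column_stack(
            [self.sample(n, sampling_rate, rng) for _ in range(n_channels)]
        )


@dataclass
class SimulationConfig:
    """Study-condition knobs for one simulated dyad.

    Defaults emulate the acquisition regime of a ~15-minute teaching
    interaction sampled at 7.81 Hz (~7,000 samples) over 18 channels per
    subject (PFC 1-8, TPJ 9-18). ``coupling_gain`` is the teacher-channel ->
    student-channel linear influence matrix; all zeros defines a null dyad.
    """

    n_channels: int = 18
    sampling_rate: float = 7.81
    duration_s: float = 900.0
    coupling_gain: np.ndarray | None = None  # (n_channels, n_channels)
    coupling_lag_samples: int = 0
    n_latent_events: int = 45
    event_jitter: float = 0.35
    hrf: HRFParams = field(default_factory=HRFParams)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    signal_amp: float = 0.5
    shared_loading_range: tuple[float, float] = (0.5, 1.0)
    idiosyncratic_weight: float = 1.0
    target_snr: float | None = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if self.coupling_gain is None:
            self.coupling_gain = np.zeros((self.n_channels, self.n_channels))
        self.coupling_gain = np.asarray(self.coupling_gain, dtype=float)
        if self.coupling_gain.shape != (self.n_channels, self.n_channels):
            raise ValueError("coupling_gain must be (n_channels, n_channels)")
        if not np.all(np.isfinite(self.coupling_gain)):
            raise ValueError("coupling_gain entries must be finite")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.sampling_rate))

    def montage(self) -> Montage:
        if self.n_channels == 18:
            return Montage.default_18()
        ids = tuple(range(1, self.n_channels + 1))
        regions = tuple("PFC" if i <= self.n_channels // 2 else "TPJ" for i in ids)
        return Montage(channel_ids=ids, regions=regions)


@dataclass
class GroundTruth:
    """What the generator actually planted, for power/type-I evaluation."""

    coupled_channel_pairs: list[tuple[int, int]]
    latent_signal: np.ndarray
    teacher_signal: np.ndarray  # noise-free teacher signal parts, time x channel
    student_signal: np.ndarray  # gain-mixed signal arriving at the student
    snr_per_channel: dict[int, float]


def double_gamma_hrf(
    t: np.ndarray, params: HRFParams | None = None
) -> np.ndarray:
    """Canonical double-gamma HRF evaluated at times ``t`` (s), peak scaled to 1."""
    p = params or HRFParams()
    t = np.asarray(t, dtype=float)
    # gamma pdf mode = (shape - 1) * scale, so shape = peak/dispersion + 1
    # puts the response maximum at peak_time_s exactly
    peak = _gamma_dist.pdf(
        t, p.peak_time_s / p.peak_dispersion_s + 1.0, scale=p.peak_dispersion_s
    )
    under = _gamma_dist.pdf(
        t,
        p.undershoot_time_s / p.undershoot_dispersion_s + 1.0,
        scale=p.undershoot_dispersion_s,
    )
    h = peak - p.undershoot_ratio * under
    m = np.max(np.abs(h))
    return h / m if m > 0 else h


def _hrf_kernel(config: SimulationConfig) -> np.ndarray:
    tt = np.arange(0, config.hrf.length_s, 1.0 / config.sampling_rate)
    return double_gamma_hrf(tt, config.hrf)


def _event_train(
    n: int, n_events: int, kernel_len: int, jitter: float, rng: np.random.Generator
) -> np.ndarray:
    """Quasi-regular onsets: a regular grid with uniform jitter.

    Regular-with-jitter rather than fully random placement keeps the event
    train's low-frequency rate fluctuations small, so the convolved signal's
    power stays inside the analysis band.
    """
    train = np.zeros(n)
    if n_events == 0:
        return train
    usable = n - kernel_len
    if usable < n_events:
        min_dur = (n_events + kernel_len) / n * 100  # percent of requested length
        raise ValueError(
            f"duration too short for {n_events} events plus a {kernel_len}-sample "
            f"response; need at least {n_events + kernel_len} samples "
            f"({min_dur:.0f}% of the requested length)"
        )
    spacing = usable / n_events
    offsets = rng.uniform(-jitter, jitter, size=n_events) * spacing
    idx = np.clip((np.arange(n_events) * spacing + spacing / 2 + offsets), 0, usable - 1)
    train[idx.astype(int)] = 1.0
    return train


def generate_latent_signal(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Latent task-locked hemodynamic signal shared across channels.

    An event train (quasi-regular onsets, see :func:`_event_train`) convolved
    with the double-gamma HRF, standardized to unit variance. With zero
    events the series is identically zero.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    n = config.n_samples
    kernel = _hrf_kernel(config)
    train = _event_train(n, config.n_latent_events, len(kernel), config.event_jitter, rng)
    sig = np.convolve(train, kernel)[:n]
    sd = sig.std()
    return sig / sd if sd > 0 else sig


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_dyad(config: SimulationConfig) -> tuple[DyadDataset, GroundTruth]:
    """Simulate one teacher-student dyad.

    Teacher channel k carries ``loading_k * latent + idio_weight * idio_k``
    (standardized, scaled to ``signal_amp``) plus physiological noise.
    Student channels receive ``coupling_gain @ teacher_signal`` (optionally
    lagged) plus independent physiological noise; when ``target_snr`` is set,
    each coupled student channel's noise is rescaled so that
    var(signal)/var(noise) equals it.
    """
    n = config.n_samples
    nc = config.n_channels
    (rng_latent, rng_teacher_sig, rng_teacher_noise, rng_student_noise) = _streams(
        config.seed, 4
    )
    kernel = _hrf_kernel(config)
    latent = generate_latent_signal(config, rng_latent)

    loadings = rng_teacher_sig.uniform(*config.shared_loading_range, size=nc)
    teacher_signal = np.empty((n, nc))
    for k in range(nc):
        idio_train = _event_train(
            n, config.n_latent_events, len(kernel), config.event_jitter, rng_teacher_sig
        )
        idio = np.convolve(idio_train, kernel)[:n]
        sd = idio.std()
        idio = idio / sd if sd > 0 else idio
        mix = loadings[k] * latent + config.idiosyncratic_weight * idio
        norm = np.hypot(loadings[k], config.idiosyncratic_weight)
        teacher_signal[:, k] = config.signal_amp * mix / (norm if norm > 0 else 1.0)

    teacher_noise = config.noise.sample_matrix(n, nc, config.sampling_rate, rng_teacher_noise)
    teacher = teacher_signal + teacher_noise

    student_signal = teacher_signal @ config.coupling_gain.T
    if config.coupling_lag_samples:
        lag = int(config.coupling_lag_samples)
        shifted = np.zeros_like(student_signal)
        if lag < n:
            shifted[lag:] = student_signal[: n - lag]
        student_signal = shifted

    student_noise = config.noise.sample_matrix(n, nc, config.sampling_rate, rng_student_noise)
    snr: dict[int, float] = {}
    montage = config.montage()
    for k in range(nc):
        sig_var = float(student_signal[:, k].var())
        noise_var = float(student_noise[:, k].var())
        if config.target_snr is not None and sig_var > 0 and noise_var > 0:
            scale = np.sqrt(sig_var / (config.target_snr * noise_var))
            student_noise[:, k] *= scale
            noise_var = float(student_noise[:, k].var())
        snr[montage.channel_ids[k]] = sig_var / noise_var if noise_var > 0 else np.inf
    student = student_signal + student_noise

    fs = config.sampling_rate
    dyad = DyadDataset(
        teacher=HbO2Series(teacher, fs, montage, "simulated"),
        student=HbO2Series(student, fs, montage, "simulated"),
        dyad_id=f"sim-{config.seed}",
        meta={"seed": config.seed, "null": bool(not np.any(config.coupling_gain))},
    )
    pairs = [
        (montage.channel_ids[i], montage.channel_ids[j])
        for j, i in zip(*np.nonzero(config.coupling_gain))
    ]
    truth = GroundTruth(
        coupled_channel_pairs=sorted(set(pairs)),
        latent_signal=latent,
        teacher_signal=teacher_signal,
        student_signal=student_signal,
        snr_per_channel=snr,
    )
    return dyad, truth


def render_raw_intensities(
    dyad: DyadDataset,
    config: SimulationConfig | None = None,
    baseline_intensity: float = 1.0,
    dpf: tuple[float, float] = DEFAULT_DPF,
    extinction: np.ndarray | None = None,
    distance_mm: float | None = None,
    hbr_ratio: float = -1.0 / 3.0,
    hbr_noise_sd: float = 0.02,
) -> tuple[RawRecording, RawRecording]:
    """Invert the MBLL: render two-wavelength (760/850 nm) raw intensities.

    HbR series are synthesized as ``hbr_ratio * HbO2`` plus white noise (the
    usual anticorrelated approximation) purely so both chromophores exist
    for the two-wavelength forward model; the analysis itself uses HbO2 only.

    The forward model is ``I = I0 * 10**(-dOD)`` with ``dOD`` from
    :func:`interbrain.preprocess.forward_od`, so applying
    :func:`interbrain.preprocess.mbll` with the same constants recovers the
    input concentrations up to a per-channel additive constant (the
    whole-series-mean baseline convention absorbs constants).
    """
    eps = DEFAULT_EXTINCTION if extinction is None else np.asarray(extinction, dtype=float)
    seed = config.seed if config is not None else int(dyad.meta.get("seed", 0))
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5EED)).generate_state(4))
    out = []
    for sub in (dyad.teacher, dyad.student):
        hbo = sub.values
        hbr = hbr_ratio * hbo + hbr_noise_sd * rng.standard_normal(hbo.shape)
        d_mm = distance_mm if distance_mm is not None else sub.montage.distance_mm
        od = forward_od(hbo, hbr, dpf=dpf, extinction=eps, distance_mm=d_mm)
        with np.errstate(over="ignore", under="ignore"):
            intensities = baseline_intensity * 10.0 ** (-od)
        if np.any(intensities <= 0) or np.any(~np.isfinite(intensities)):
            raise ValueError(
                "concentration excursions too extreme: rendered intensities are "
                "non-positive or non-finite"
            )
        out.append(
            RawRecording(
                intensities=intensities,
                wavelengths=(760.0, 850.0),
                sampling_rate=sub.sampling_rate,
                montage=sub.montage,
            )
        )
    return out[0], out[1]


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Convenience: a zero-coupling (null) dyad configuration."""
    return SimulationConfig(seed=seed, coupling_gain=None, **overrides)


def coupled_config(
    pairs: dict[tuple[int, int], float], seed: int = 0, **overrides
) -> SimulationConfig:
    """Convenience: coupling on given (teacher_channel, student_channel) pairs.

    Channel numbers are 1-based, matching the montage.
    """
    n = overrides.get("n_channels", 18)
    gain = np.zeros((n, n))
    for (ti, sj), g in pairs.items():
        gain[sj - 1, ti - 1] = g
    return SimulationConfig(seed=seed, coupling_gain=gain, **overrides)
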