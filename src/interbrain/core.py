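"""In-memory containers for dyad recordings.

Conventions: time runs along axis 0; channels are numbered 1..18 with the
prefrontal cortex (PFC) on channels 1-8 and the temporo-parietal junction
(TPJ) on channels 9-18; HbO2 concentration changes are in micromolar when a
source-detector distance is known, otherwise in uM*mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PFC_CHANNELS = tuple(range(1, 9))
TPJ_CHANNELS = tuple(range(9, 19))


@dataclass(frozen=True)
class Montage:
    """Channel layout shared by both members of a dyad.

    Parameters
    ----------
    channel_ids
        Unique 1-based channel identifiers.
    regions
        Region label per channel, one of ``{"PFC", "TPJ"}``.
    distance_mm
        Geometric source-detector separation. ``None`` leaves concentration
        output in uM*mm (path length not divided out).
    """

    channel_ids: tuple[int, ...]
    regions: tuple[str, ...]
    distance_mm: float | None = 30.0
    sources: tuple[int, ...] | None = None
    detectors: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel ids must be unique")
        if len(self.regions) != len(self.channel_ids):
            raise ValueError("one region label per channel required")
        bad = set(self.regions) - {"PFC", "TPJ"}
        if bad:
            raise ValueError(f"unknown region labels: {sorted(bad)}")
        if self.distance_mm is not None and self.distance_mm <= 0:
            raise ValueError("distance_mm must be positive")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def region_of(self, channel: int) -> str:
        return self.regions[self.channel_ids.index(channel)]

    @classmethod
    def default_18(cls, distance_mm: float | None = 30.0) -> "Montage":
        """Standard 18-channel layout: PFC = 1-8, TPJ = 9-18."""
        ids = tuple(range(1, 19))
        regions = tuple("PFC" if c in PFC_CHANNELS else "TPJ" for c in ids)
        return cls(channel_ids=ids, regions=regions, distance_mm=distance_mm)


def _check_series(values: np.ndarray, montage: Montage, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError(f"{name} must be 2-D (time x channel)")
    if values.shape[1] != montage.n_channels:
        raise ValueError(
            f"{name} has {values.shape[1]} channels, montage has {montage.n_channels}"
        )
    return values


@dataclass
class HbO2Series:
    """Oxyhemoglobin concentration changes, time x channel.

    ``baseline_convention`` records what zero means; the pipeline's modified
    Beer-Lambert step uses the mean over the whole recording as baseline, so
    each channel is only determined up to an additive constant.
    """

    values: np.ndarray
    sampling_rate: float
    montage: Montage
    baseline_convention: str = "whole-series-mean"

    def __post_init__(self) -> None:
        self.values = _check_series(self.values, self.montage, "values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("HbO2 values must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class RawRecording:
    """Two-wavelength raw light intensities, time x channel x wavelength."""

    intensities: np.ndarray
    wavelengths: tuple[float, ...]
    sampling_rate: float
    montage: Montage

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be 3-D (time x channel x wavelength)")
        if len(self.wavelengths) < 2:
            raise ValueError("at least two wavelengths required")
        if self.intensities.shape[2] != len(self.wavelengths):
            raise ValueError("wavelength axis does not match wavelength list")
        if self.intensities.shape[1] != self.montage.n_channels:
            raise ValueError("channel axis does not match montage")
        if self.intensities.shape[0] < 2:
            raise ValueError("need at least two time samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]


@dataclass
class DyadDataset:
    """Paired teacher/student recordings sharing one clock and montage."""

    teacher: HbO2Series
    student: HbO2Series
    dyad_id: str = "dyad"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.teacher.n_samples != self.student.n_samples:
            raise ValueError("teacher and student series must share length")
        if self.teacher.sampling_rate != self.student.sampling_rate:
            raise ValueError("teacher and student must share sampling rate")

    @property
    def n_samples(self) -> int:
        return self.teacher.n_samples

    @property
    def sampling_rate(self) -> float:
        return self.teacher.sampling_rate

    @property
    def montage(self) -> Montage:
        return self.teacher.montage
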