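"""Raw fNIRS intensities to band-limited HbO2 concentration changes.

The chain mirrors standard continuous-wave fNIRS practice: screen channels
for acquisition problems, band-pass to the hemodynamic band (default
0.01-0.2 Hz, removing drift below and cardiac/respiratory cycles above),
and convert two-wavelength optical densities to chromophore concentration
changes with the modified Beer-Lambert law (MBLL), taking the mean over the
whole recording as the optical-density baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from interbrain.core import HbO2Series, RawRecording

#: Decadic extinction coefficients, 1/(mM*cm), rows = wavelengths (760, 850 nm),
#: columns = (HbO2, HbR). Values from the commonly used compiled hemoglobin
#: spectra (Prahl/Gratzer compilation); overridable everywhere they are used.
DEFAULT_EXTINCTION = np.array(
    [
        [0.5860, 1.5485],  # 760 nm
        [1.0580, 0.6913],  # 850 nm
    ]
)

#: Differential pathlength factors for (760, 850) nm.
DEFAULT_DPF = (7.25, 6.38)

DEFAULT_BAND = (0.01, 0.2)


# ---------------------------------------------------------------------------
# Quality screening
# ---------------------------------------------------------------------------

@dataclass
class QCThresholds:
    """Automatic surrogate for visual inspection of raw channels.

    saturation_fraction: flag a channel saturated when at least this fraction
    of samples sits within ``rail_tolerance`` (relative) of the channel's
    maximum recorded intensity. missing_fraction: flag missing when at least
    this fraction of samples is non-finite or exactly zero.
    flat_variance_ratio: flag flat when the variance falls below this ratio
    of the squared mean intensity.
    """

    saturation_fraction: float = 0.05
    rail_tolerance: float = 1e-3
    missing_fraction: float = 0.05
    flat_variance_ratio: float = 1e-12


@dataclass
class QCReport:
    """Per-channel screening outcome; exactly one flag per channel."""

    flags: dict[int, str]
    stats: dict[int, dict[str, float]] = field(default_factory=dict)

    @property
    def ok_channels(self) -> list[int]:
        return [c for c, f in self.flags.items() if f == "ok"]

    @property
    def bad_channels(self) -> list[int]:
        return [c for c, f in self.flags.items() if f != "ok"]


def quality_screen(raw: RawRecording, thresholds: QCThresholds | None = None) -> QCReport:
    """Flag channels as ok / saturated / missing / flat.

    A channel is screened across all wavelengths; the worst wavelength
    determines the flag. Precedence when several conditions hold:
    missing > saturated > flat.

    Raises
    ------
    ValueError
        If every channel is flagged (no usable channels).
    """
    thr = thresholds or QCThresholds()
    flags: dict[int, str] = {}
    stats: dict[int, dict[str, float]] = {}
    # the rail is a device property: the maximum recorded anywhere, per wavelength
    finite_vals = np.where(np.isfinite(raw.intensities), raw.intensities, -np.inf)
    rails = finite_vals.max(axis=(0, 1))
    rails = np.where(np.isfinite(rails), rails, np.nan)
    for k, ch in enumerate(raw.montage.channel_ids):
        x = raw.intensities[:, k, :]  # time x wavelength
        finite = np.isfinite(x)
        missing_frac = float(np.mean(~finite | (x == 0)))
        rail_frac = 0.0
        var_ratio = np.inf
        for w in range(x.shape[1]):
            col = x[finite[:, w], w]
            if col.size == 0:
                continue
            rail = rails[w]
            if np.isfinite(rail) and rail > 0:
                rail_frac = max(rail_frac, float(np.mean(np.abs(col - rail) <= thr.rail_tolerance * rail)))
            scale = float(np.mean(col)) ** 2
            if scale > 0:
                var_ratio = min(var_ratio, float(np.var(col)) / scale)
        stats[ch] = {
            "missing_fraction": missing_frac,
            "rail_fraction": rail_frac,
            "variance_ratio": float(var_ratio) if np.isfinite(var_ratio) else 0.0,
        }
        if missing_frac >= thr.missing_fraction:
            flags[ch] = "missing"
        elif rail_frac >= thr.saturation_fraction:
            flags[ch] = "saturated"
        elif var_ratio < thr.flat_variance_ratio:
            flags[ch] = "flat"
        else:
            flags[ch] = "ok"
    report = QCReport(flags=flags, stats=stats)
    if not report.ok_channels:
        raise ValueError("no usable channels: every channel failed quality screening")
    return report


# ---------------------------------------------------------------------------
# Band-pass filtering
# ---------------------------------------------------------------------------

def bandpass(
    series: np.ndarray,
    sampling_rate: float,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = 3,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the time axis.

    A forward-backward pass (``sosfiltfilt``) of an order-``order``
    Butterworth band-pass, so the effective magnitude response is the
    squared single-pass response and the phase response is exactly zero —
    phase matters here because filtered series from two people are
    subsequently regressed on one another.

    Parameters
    ----------
    series
        1-D (time,) or 2-D (time x channel) array.
    low, high
        Band edges in Hz; must satisfy ``0 < low < high < sampling_rate/2``.
    """
    x = np.asarray(series, dtype=float)
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got low={low}, high={high}")
    if high >= sampling_rate / 2:
        raise ValueError(f"high={high} Hz must be below Nyquist ({sampling_rate / 2} Hz)")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=sampling_rate, output="sos")
    # sosfiltfilt needs more samples than its edge padding
    padlen = 3 * (2 * sos.shape[0] + 1)
    n = x.shape[0]
    if n <= padlen:
        raise ValueError(
            f"series too short for zero-phase filtering: {n} samples <= warm-up {padlen}"
        )
    return sps.sosfiltfilt(sos, x, axis=0)


def bandpass_response(
    freq_hz: float | np.ndarray,
    sampling_rate: float,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = 3,
) -> np.ndarray:
    """Magnitude response of :func:`bandpass` (zero-phase, so single-pass squared)."""
    sos = sps.butter(order, [low, high], btype="bandpass", fs=sampling_rate, output="sos")
    w = np.atleast_1d(np.asarray(freq_hz, dtype=float)) / (sampling_rate / 2) * np.pi
    _, h = sps.sosfreqz(sos, worN=w)
    return np.abs(h) ** 2


# ---------------------------------------------------------------------------
# Modified Beer-Lambert law
# ---------------------------------------------------------------------------

def optical_density(intensities: np.ndarray) -> np.ndarray:
    """Decadic optical-density change with the whole-series mean as baseline.

    ``dOD(t) = -log10(I(t) / mean_t I)`` per channel and wavelength. Only
    intensity ratios enter, so any positive per-channel gain cancels.
    """
    x = np.asarray(intensities, dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("intensities must be finite and strictly positive")
    baseline = x.mean(axis=0, keepdims=True)
    return -np.log10(x / baseline)


def mbll(
    raw: RawRecording,
    dpf: tuple[float, float] = DEFAULT_DPF,
    extinction: np.ndarray | None = None,
    distance_mm: float | None = None,
    return_hbr: bool = False,
) -> HbO2Series | tuple[HbO2Series, np.ndarray]:
    """Convert two-wavelength intensities to HbO2 (and optionally HbR) changes.

    Solves, per channel and time point, the 2x2 linear system

        dOD_lambda / (DPF_lambda * d) = eps[lambda, HbO2] * dHbO2
                                        + eps[lambda, HbR] * dHbR

    with ``dOD`` computed against the whole-series mean intensity. With a
    source-detector distance ``d`` (cm, from ``distance_mm``) the output is
    in uM; without one, pathlength is not divided out and units are uM*mm.

    Because the baseline is the recording's own mean, the recovered
    concentration changes are determined only up to an additive constant per
    channel (see docs/methods.md).
    """
    eps = DEFAULT_EXTINCTION if extinction is None else np.asarray(extinction, dtype=float)
    if eps.shape != (2, 2):
        raise ValueError("extinction must be a 2x2 matrix (wavelength x chromophore)")
    if abs(np.linalg.det(eps)) < 1e-12:
        raise ValueError("extinction matrix is singular; chromophores not separable")
    if distance_mm is None:
        distance_mm = raw.montage.distance_mm
    od = optical_density(raw.intensities)  # time x channel x wavelength
    dpf_arr = np.asarray(dpf, dtype=float)
    if dpf_arr.shape != (2,):
        raise ValueError("need one DPF per wavelength (2)")
    d_cm = (distance_mm / 10.0) if distance_mm is not None else 1.0
    # effective pathlength per wavelength
    pathlength = dpf_arr * d_cm
    rhs = od / pathlength  # broadcasts over trailing wavelength axis
    inv = np.linalg.inv(eps)
    conc = rhs @ inv.T  # time x channel x (HbO2, HbR), in mM
    conc_um = conc * 1e3
    hbo = HbO2Series(
        values=conc_um[:, :, 0],
        sampling_rate=raw.sampling_rate,
        montage=raw.montage,
        baseline_convention="whole-series-mean",
    )
    if return_hbr:
        return hbo, conc_um[:, :, 1]
    return hbo


def preprocess_raw(
    raw: RawRecording,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    dpf: tuple[float, float] = DEFAULT_DPF,
    extinction: np.ndarray | None = None,
    thresholds: QCThresholds | None = None,
    filter_stage: str = "od",
) -> tuple[HbO2Series, QCReport]:
    """Full preprocessing: QC, band-pass, MBLL.

    ``filter_stage`` chooses where the band-pass acts: ``"od"`` filters
    optical densities before the MBLL inversion (default), ``"concentration"``
    filters after it. The two are numerically equivalent because MBLL is
    linear in dOD; both are offered because acquisition pipelines differ in
    where they filter. ``"raw"`` filters intensities directly (not strictly
    equivalent owing to the log).
    """
    if filter_stage not in {"raw", "od", "concentration"}:
        raise ValueError(f"unknown filter_stage {filter_stage!r}")
    report = quality_screen(raw, thresholds)
    if filter_stage == "raw":
        filt = bandpass(raw.intensities.reshape(raw.n_samples, -1), raw.sampling_rate, low, high)
        shifted = filt.reshape(raw.intensities.shape) + raw.intensities.mean(axis=0, keepdims=True)
        if np.any(shifted <= 0):
            raise ValueError("band-passed intensities are non-positive; filter at 'od' instead")
        raw = RawRecording(shifted, raw.wavelengths, raw.sampling_rate, raw.montage)
        hbo = mbll(raw, dpf=dpf, extinction=extinction)
    elif filter_stage == "od":
        od = optical_density(raw.intensities)
        od_f = bandpass(od.reshape(raw.n_samples, -1), raw.sampling_rate, low, high)
        od_f = od_f.reshape(od.shape)
        hbo = _mbll_from_od(od_f, raw, dpf, extinction)
    else:
        hbo = mbll(raw, dpf=dpf, extinction=extinction)
        values = bandpass(hbo.values, raw.sampling_rate, low, high)
        hbo = HbO2Series(values, raw.sampling_rate, raw.montage, hbo.baseline_convention)
    return hbo, report


def _mbll_from_od(
    od: np.ndarray,
    raw: RawRecording,
    dpf: tuple[float, float],
    extinction: np.ndarray | None,
) -> HbO2Series:
    eps = DEFAULT_EXTINCTION if extinction is None else np.asarray(extinction, dtype=float)
    if abs(np.linalg.det(eps)) < 1e-12:
        raise ValueError("extinction matrix is singular; chromophores not separable")
    distance_mm = raw.montage.distance_mm
    d_cm = (distance_mm / 10.0) if distance_mm is not None else 1.0
    pathlength = np.asarray(dpf, dtype=float) * d_cm
    conc = (od / pathlength) @ np.linalg.inv(eps).T * 1e3
    return HbO2Series(conc[:, :, 0], raw.sampling_rate, raw.montage, "whole-series-mean")


def forward_od(
    hbo_um: np.ndarray,
    hbr_um: np.ndarray,
    dpf: tuple[float, float] = DEFAULT_DPF,
    extinction: np.ndarray | None = None,
    distance_mm: float | None = 30.0,
) -> np.ndarray:
    """Forward Beer-Lambert model: concentration changes (uM) to dOD.

    Inverse of the solve inside :func:`mbll`; used by the simulator to render
    raw intensities and by tests as the round-trip oracle.
    """
    eps = DEFAULT_EXTINCTION if extinction is None else np.asarray(extinction, dtype=float)
    conc_mm = np.stack([hbo_um, hbr_um], axis=-1) * 1e-3  # mM
    d_cm = (distance_mm / 10.0) if distance_mm is not None else 1.0
    pathlength = np.asarray(dpf, dtype=float) * d_cm
    return (conc_mm @ eps.T) * pathlength
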