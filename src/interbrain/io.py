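"""File formats: tabular HbO2 text, minimal SNIRF, JSON sidecars.

Tabular series are plain TSV, one header row of channel ids, optional
``# key: value`` comment lines for sampling metadata. SNIRF support covers
the subset of the (HDF5-based) standard needed for two-wavelength
continuous-wave recordings: ``/nirs/data1/dataTimeSeries``, ``time``, the
per-measurement ``measurementList`` groups, and the probe wavelengths.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from interbrain.core import HbO2Series, Montage, RawRecording
from interbrain.models import ModelGrid, PredictionModelSpec
from interbrain.simulate import GroundTruth

__all__ = [
    "write_hbo2_tsv",
    "read_hbo2_tsv",
    "write_ground_truth_json",
    "read_ground_truth_json",
    "write_snirf",
    "read_snirf",
    "write_model_grid_json",
    "read_model_grid_json",
    "write_results",
]


# ---------------------------------------------------------------------------
# Tabular HbO2 text
# ---------------------------------------------------------------------------

def write_hbo2_tsv(series: HbO2Series, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# sampling_rate_hz: {series.sampling_rate}\n")
        fh.write(f"# baseline_convention: {series.baseline_convention}\n")
        fh.write(f"# regions: {','.join(series.montage.regions)}\n")
        header = "\t".join(f"ch{c}" for c in series.montage.channel_ids)
        fh.write(header + "\n")
        np.savetxt(fh, series.values, delimiter="\t", fmt="%.10g")


def read_hbo2_tsv(path: str | Path) -> HbO2Series:
    path = Path(path)
    meta: dict[str, str] = {}
    skip = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
    df = pd.read_csv(path, sep="\t", skiprows=skip)
    channel_ids = tuple(int(c.removeprefix("ch")) for c in df.columns)
    regions = meta.get("regions")
    if regions:
        region_tuple = tuple(regions.split(","))
    else:
        region_tuple = tuple("PFC" if c <= 8 else "TPJ" for c in channel_ids)
    montage = Montage(channel_ids=channel_ids, regions=region_tuple)
    return HbO2Series(
        values=df.to_numpy(dtype=float),
        sampling_rate=float(meta.get("sampling_rate_hz", 7.81)),
        montage=montage,
        baseline_convention=meta.get("baseline_convention", "unknown"),
    )


# ---------------------------------------------------------------------------
# Ground-truth sidecar
# ---------------------------------------------------------------------------

def write_ground_truth_json(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "schema": "interbrain-ground-truth/1",
        "coupled_channel_pairs": [list(p) for p in truth.coupled_channel_pairs],
        "snr_per_channel": {str(k): v for k, v in truth.snr_per_channel.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_ground_truth_json(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    payload["coupled_channel_pairs"] = [tuple(p) for p in payload["coupled_channel_pairs"]]
    payload["snr_per_channel"] = {int(k): v for k, v in payload["snr_per_channel"].items()}
    return payload


# ---------------------------------------------------------------------------
# Minimal SNIRF
# ---------------------------------------------------------------------------

def write_snirf(raw: RawRecording, path: str | Path) -> None:
    """Write a continuous-wave recording as a minimal SNIRF file.

    Measurement columns are ordered channel-major: all channels at the first
    wavelength, then all channels at the second.
    """
    n, k, w = raw.intensities.shape
    data = raw.intensities.transpose(0, 2, 1).reshape(n, w * k)
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(raw.wavelengths, dtype=float))
        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=data)
        d1.create_dataset("time", data=np.arange(n) / raw.sampling_rate)
        idx = 1
        for wi in range(w):
            for ch in raw.montage.channel_ids:
                ml = d1.create_group(f"measurementList{idx}")
                ml.create_dataset("sourceIndex", data=int(ch))
                ml.create_dataset("detectorIndex", data=int(ch))
                ml.create_dataset("wavelengthIndex", data=wi + 1)
                ml.create_dataset("dataType", data=1)  # CW amplitude
                ml.create_dataset("dataTypeIndex", data=1)
                idx += 1


def read_snirf(path: str | Path, montage: Montage | None = None) -> RawRecording:
    """Read a SNIRF file written by :func:`write_snirf` (CW amplitude subset)."""
    with h5py.File(path, "r") as f:
        d1 = f["nirs/data1"]
        data = np.asarray(d1["dataTimeSeries"])
        time = np.asarray(d1["time"])
        wavelengths = tuple(float(x) for x in np.asarray(f["nirs/probe/wavelengths"]))
        mls = sorted(
            (name for name in d1 if name.startswith("measurementList")),
            key=lambda s: int(s.removeprefix("measurementList")),
        )
        src = [int(np.asarray(d1[m]["sourceIndex"])) for m in mls]
        wli = [int(np.asarray(d1[m]["wavelengthIndex"])) for m in mls]
    if len(time) > 1:
        fs = 1.0 / float(np.median(np.diff(time)))
    else:
        fs = 1.0
    channels = sorted(set(src))
    k, w = len(channels), len(wavelengths)
    intensities = np.empty((data.shape[0], k, w))
    for col, (s, wi) in enumerate(zip(src, wli)):
        intensities[:, channels.index(s), wi - 1] = data[:, col]
    if montage is None:
        if k == 18:
            montage = Montage.default_18()
        else:
            montage = Montage(
                channel_ids=tuple(channels),
                regions=tuple("PFC" if c <= k // 2 else "TPJ" for c in channels),
            )
    return RawRecording(
        intensities=intensities,
        wavelengths=wavelengths,
        sampling_rate=fs,
        montage=montage,
    )


# ---------------------------------------------------------------------------
# Model grids and results
# ---------------------------------------------------------------------------

def write_model_grid_json(grid: ModelGrid, path: str | Path) -> None:
    payload = {
        "schema": "interbrain-model-grid/1",
        "boundary": grid.boundary,
        "families": list(grid.families),
        "skipped": grid.skipped,
        "models": [
            {
                "family": m.family,
                "response_channel": m.response_channel,
                "weights": m.weights.tolist(),
                "intercept": m.intercept,
                "hyperparameters": m.hyperparameters,
            }
            for m in grid.models.values()
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_model_grid_json(path: str | Path) -> ModelGrid:
    payload = json.loads(Path(path).read_text())
    models = {}
    for d in payload["models"]:
        spec = PredictionModelSpec(
            family=d["family"],
            response_channel=d["response_channel"],
            weights=np.asarray(d["weights"]),
            intercept=d["intercept"],
            hyperparameters=d.get("hyperparameters", {}),
        )
        models[(spec.response_channel, spec.family)] = spec
    return ModelGrid(
        models=models,
        skipped=payload.get("skipped", []),
        boundary=payload["boundary"],
        families=tuple(payload["families"]),
    )


def write_results(table: pd.DataFrame, path_tsv: str | Path,
                  path_json: str | Path | None = None) -> None:
    table.to_csv(path_tsv, sep="\t", index=False, float_format="%.6g")
    if path_json is not None:
        Path(path_json).write_text(table.to_json(orient="records", indent=2))
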