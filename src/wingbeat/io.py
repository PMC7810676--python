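"""Container formats: HDF5 recordings, CSV tables, YAML run config.

A recording file holds ``/samples`` (4 x N float64) with ``sample_rate``,
``channel_names`` and ``wavelengths`` attributes, and an optional
``/truth`` table of half-open (start, end) sample intervals with species
labels.  Event, feature and fold tables are plain comma-separated CSV
with a header row, '.' decimal and UTF-8 encoding; indices are 0-based.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .detect import DetectionParams
from .sensor import SensorConfig
from .simulate import Recording

__all__ = [
    "RunConfig",
    "read_recording",
    "write_recording",
    "write_events_csv",
    "write_truth_csv",
    "write_features_csv",
]


def write_recording(recording: Recording, path) -> None:
    """Write a recording to HDF5; lossless round-trip with
    :func:`read_recording`."""
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("samples", data=recording.samples)
        dset.attrs["sample_rate"] = recording.sensor.sample_rate
        dset.attrs["bandwidth"] = recording.sensor.bandwidth
        dset.attrs["channel_names"] = list(recording.sensor.channel_names)
        dset.attrs["wavelengths"] = list(recording.sensor.wavelengths)
        if recording.truth:
            starts = np.array([t[0] for t in recording.truth], dtype=np.int64)
            ends = np.array([t[1] for t in recording.truth], dtype=np.int64)
            names = [t[2] for t in recording.truth]
            g = f.create_group("truth")
            g.create_dataset("start", data=starts)
            g.create_dataset("end", data=ends)
            g.create_dataset(
                "species", data=np.array(names, dtype=h5py.string_dtype())
            )


def read_recording(path) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    with h5py.File(path, "r") as f:
        if "samples" not in f:
            raise ValueError(f"{path}: missing /samples dataset")
        dset = f["samples"]
        samples = dset[()]
        if samples.ndim != 2 or samples.shape[0] != 4:
            raise ValueError(
                f"{path}: expected 4 channels, found shape {samples.shape}"
            )
        sensor = SensorConfig(
            sample_rate=float(dset.attrs["sample_rate"]),
            bandwidth=float(dset.attrs.get("bandwidth", 5000.0)),
            channel_names=tuple(
                s.decode() if isinstance(s, bytes) else str(s)
                for s in dset.attrs["channel_names"]
            ),
            wavelengths=tuple(float(w) for w in dset.attrs["wavelengths"]),
        )
        truth = []
        if "truth" in f:
            g = f["truth"]
            for s, e, name in zip(g["start"][()], g["end"][()], g["species"][()]):
                truth.append(
                    (int(s), int(e), name.decode() if isinstance(name, bytes)
                     else str(name))
                )
    return Recording(samples=samples, sensor=sensor, truth=truth)


def write_truth_csv(recording: Recording, path) -> None:
    pd.DataFrame(
        recording.truth, columns=["start_sample", "end_sample", "species"]
    ).to_csv(path, index=False)


def write_events_csv(events: Sequence, path, recording_id: str = "") -> None:
    rows = [
        {
            "recording_id": recording_id,
            "start_sample": ev.start,
            "end_sample": ev.end,
            "duration_ms": 1000.0 * ev.duration,
            "peak_snr": ev.peak_snr if ev.peak_snr is not None else np.nan,
        }
        for ev in events
    ]
    pd.DataFrame(
        rows,
        columns=["recording_id", "start_sample", "end_sample", "duration_ms",
                 "peak_snr"],
    ).to_csv(path, index=False)


def write_features_csv(feature_sets, labels, path) -> None:
    """One row per event: event_id, label, then the canonical features."""
    from .features import FEATURE_NAMES

    rows = []
    for i, (fs, lab) in enumerate(zip(feature_sets, labels)):
        row = {"event_id": i, "label": lab}
        row.update({name: getattr(fs, name) for name in FEATURE_NAMES})
        rows.append(row)
    columns = ["event_id", "label", *FEATURE_NAMES]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration with the reference defaults:
    SNR threshold 10, erosion 0.25 ms, dilation 40 ms, 20 kHz sampling,
    333/42/50 split counts and 100 folds."""

    sample_rate: float = 20_000.0
    bandwidth: float = 5_000.0
    snr_threshold: float = 10.0
    erosion_width_ms: float = 0.25
    dilation_width_ms: float = 40.0
    band_lo: float = 30.0
    band_hi: float = 1000.0
    methods: tuple = ("wbf", "features", "nn")
    n_target_train: int = 333
    n_other_train_each: int = 42
    n_test_each: int = 50
    n_folds: int = 100
    n_per_species: int = 500
    noise_sd: float = 1.0
    peak_snr: float = 30.0
    seed: int = 0
    nn_layers: tuple = (2000, 1500, 1000)
    nn_epochs: int = 30
    nn_batch_size: int = 32
    nn_learning_rate: float = 1e-3
    n_trees: int = 500

    def sensor(self) -> SensorConfig:
        return SensorConfig(sample_rate=self.sample_rate, bandwidth=self.bandwidth)

    def detection(self) -> DetectionParams:
        return DetectionParams(
            snr_threshold=self.snr_threshold,
            erosion_width=self.erosion_width_ms / 1000.0,
            dilation_width=self.dilation_width_ms / 1000.0,
        )

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["methods"] = list(self.methods)
        data["nn_layers"] = list(self.nn_layers)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("methods", "nn_layers"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)
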