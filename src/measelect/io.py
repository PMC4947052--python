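"""Readers and writers for the pipeline's file formats.

Spike trains: two-column CSV (electrode_id, spike_time_s) or HDF5.
Stimulation log: CSV (stim_time_s, site_label).
Patterns: HDF5 (stimulus x electrode x bin counts + activation times).
Signatures: CSV matrices (electrodes x bins, empty cell = not applicable).
Reports and ground truth: JSON.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import SpikeTrainSet, StimulationLog, WindowSpec
from .features import ResponsePattern
from .selectivity import OverlapSignature, SelectivitySignature
from .synthetic import GroundTruth, RawRecording

__all__ = [
    "write_spikes_csv", "read_spikes_csv", "write_spikes_h5", "read_spikes_h5",
    "write_stims_csv", "read_stims_csv", "write_patterns_h5", "read_patterns_h5",
    "write_signature_csv", "read_signature_csv", "write_json", "read_json",
    "write_raw_h5", "read_raw_h5", "write_ground_truth", "ground_truth_to_dict",
]

_H5_OPTS = {"track_times": False}  # keep HDF5 output byte-reproducible


def write_spikes_csv(spikes: SpikeTrainSet, path: str | Path) -> None:
    rows = [
        (e, t)
        for e in spikes.electrode_ids
        for t in spikes.train(e)
    ]
    df = pd.DataFrame(rows, columns=["electrode_id", "spike_time_s"])
    df.to_csv(path, index=False, float_format="%.6f")


def read_spikes_csv(
    path: str | Path, n_electrodes: int | None = None, duration: float | None = None
) -> SpikeTrainSet:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - passthrough context
        raise ValueError(f"cannot parse spike CSV {path}: {exc}") from exc
    for col in ("electrode_id", "spike_time_s"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if not df.empty and df["spike_time_s"].isna().any():
        row = int(df.index[df["spike_time_s"].isna()][0]) + 2
        raise ValueError(f"{path}: non-numeric spike time at line {row}")
    if not df["spike_time_s"].is_monotonic_increasing:
        by_electrode = df.groupby("electrode_id")["spike_time_s"]
        if not all(g.is_monotonic_increasing for _, g in by_electrode):
            warnings.warn(f"{path}: spike times out of order; sorting", stacklevel=2)
    n_e = n_electrodes or (int(df["electrode_id"].max()) if len(df) else 0)
    trains = {
        int(e): g["spike_time_s"].to_numpy()
        for e, g in df.groupby("electrode_id")
    }
    dur = duration if duration is not None else (
        float(df["spike_time_s"].max()) + 1.0 if len(df) else 0.0
    )
    return SpikeTrainSet(trains, n_electrodes=n_e, duration=dur)


def write_spikes_h5(spikes: SpikeTrainSet, path: str | Path) -> None:
    eids = np.concatenate(
        [np.full(len(spikes.train(e)), e, dtype=np.int32) for e in spikes.electrode_ids]
        or [np.empty(0, dtype=np.int32)]
    )
    times = np.concatenate(
        [spikes.train(e) for e in spikes.electrode_ids] or [np.empty(0)]
    )
    with h5py.File(path, "w") as f:
        f.create_dataset("electrode_id", data=eids, **_H5_OPTS)
        f.create_dataset("spike_time_s", data=times, **_H5_OPTS)
        f.attrs["n_electrodes"] = spikes.n_electrodes
        f.attrs["duration"] = spikes.duration


def read_spikes_h5(path: str | Path) -> SpikeTrainSet:
    with h5py.File(path, "r") as f:
        eids = f["electrode_id"][:]
        times = f["spike_time_s"][:]
        n_e = int(f.attrs["n_electrodes"])
        dur = float(f.attrs["duration"])
    trains: dict[int, np.ndarray] = {}
    for e in np.unique(eids):
        trains[int(e)] = times[eids == e]
    return SpikeTrainSet(trains, n_electrodes=n_e, duration=dur)


def write_stims_csv(stims: StimulationLog, path: str | Path) -> None:
    pd.DataFrame({"stim_time_s": stims.times, "site_label": stims.sites}).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_stims_csv(path: str | Path, allowed_sites: tuple[str, ...] | None = None) -> StimulationLog:
    df = pd.read_csv(path)
    for col in ("stim_time_s", "site_label"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if allowed_sites is not None:
        bad = ~df["site_label"].isin(allowed_sites)
        if bad.any():
            row = int(df.index[bad][0])
            raise ValueError(
                f"{path}: unknown site label {df['site_label'][row]!r} at line {row + 2}"
            )
    return StimulationLog(df["stim_time_s"].to_numpy(), df["site_label"].to_numpy())


def write_patterns_h5(
    patterns: list[ResponsePattern],
    path: str | Path,
    window: WindowSpec | None = None,
    metadata: dict | None = None,
) -> None:
    window = window or WindowSpec()
    counts = np.stack([p.counts for p in patterns]).astype(np.int32)
    activation = np.stack([p.activation_time for p in patterns])
    sites = np.array([p.site for p in patterns], dtype="S8")
    idx = np.array([p.stimulus_index for p in patterns], dtype=np.int32)
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=counts, **_H5_OPTS)
        f.create_dataset("activation_time_ms", data=activation, **_H5_OPTS)
        f.create_dataset("site", data=sites, **_H5_OPTS)
        f.create_dataset("stimulus_index", data=idx, **_H5_OPTS)
        f.attrs["response_window_ms"] = window.response_window
        f.attrs["synaptic_onset_ms"] = window.synaptic_onset
        f.attrs["bin_width_ms"] = window.bin_width
        for k, v in (metadata or {}).items():
            f.attrs[k] = v


def read_patterns_h5(path: str | Path) -> tuple[list[ResponsePattern], WindowSpec]:
    with h5py.File(path, "r") as f:
        counts = f["counts"][:]
        activation = f["activation_time_ms"][:]
        sites = [s.decode() for s in f["site"][:]]
        idx = f["stimulus_index"][:]
        window = WindowSpec(
            response_window=float(f.attrs["response_window_ms"]),
            synaptic_onset=float(f.attrs["synaptic_onset_ms"]),
            bin_width=float(f.attrs["bin_width_ms"]),
            n_bins=counts.shape[2],
        )
    patterns = [
        ResponsePattern(int(i), s, c, a)
        for i, s, c, a in zip(idx, sites, counts, activation)
    ]
    return patterns, window


def write_signature_csv(signature: SelectivitySignature | OverlapSignature, path: str | Path) -> None:
    if isinstance(signature, OverlapSignature):
        values = np.where(signature.valid, signature.overlaps, np.nan)
    else:
        values = np.where(signature.valid, signature.flags.astype(float), np.nan)
    df = pd.DataFrame(
        values,
        index=[f"e{i + 1}" for i in range(values.shape[0])],
        columns=[f"bin{b + 1}" for b in range(values.shape[1])],
    )
    df.to_csv(path, float_format="%.4f", na_rep="NA")


def read_signature_csv(path: str | Path) -> np.ndarray:
    """Signature matrix as floats with NaN for not-applicable cells."""
    return pd.read_csv(path, index_col=0, na_values=["NA"]).to_numpy(dtype=float)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def ground_truth_to_dict(truth: GroundTruth) -> dict:
    return {
        "selective_electrodes": sorted(truth.selective_electrodes),
        "selective_cells": sorted([list(c) for c in truth.selective_cells]),
        "inter_stimulus_interval": truth.inter_stimulus_interval,
        "spontaneous_burst_times": truth.spontaneous_burst_times.tolist(),
        "seed": truth.seed,
    }


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    write_json(ground_truth_to_dict(truth), path)


def write_raw_h5(raw: RawRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data_uv", data=raw.data, **_H5_OPTS)
        f.attrs["sampling_rate_hz"] = raw.sampling_rate


def read_raw_h5(path: str | Path) -> RawRecording:
    with h5py.File(path, "r") as f:
        return RawRecording(data=f["data_uv"][:], sampling_rate=float(f.attrs["sampling_rate_hz"]))
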