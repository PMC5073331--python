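"""File formats: spike-train CSV, raw-recording HDF5, ground-truth JSON.

Spike trains travel as two-column CSV (electrode_id, timestamp_s) with
metadata in '#'-prefixed header lines; raw voltage as HDF5 with a
``/voltage`` (channels x samples, float32 microvolts) dataset and
``sampling_rate_hz`` / ``channel_ids`` attributes. Timestamps are stored
in seconds with 6 decimal places (1 microsecond, below the 10 kHz sample
period).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .types import GroundTruth, RawRecording, SpikeTrainSet

__all__ = [
    "write_spike_trains",
    "read_spike_trains",
    "write_raw",
    "read_raw",
    "write_ground_truth",
    "read_ground_truth",
    "write_metrics",
    "read_metrics",
]

_META_FIELDS = ("duration", "culture_id", "condition", "div",
                "n_active_at_final_div")


def write_spike_trains(spikes: SpikeTrainSet, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# duration={spikes.duration!r}\n")
        for key in ("culture_id", "condition", "div", "n_active_at_final_div"):
            val = getattr(spikes, key)
            if val is not None:
                fh.write(f"# {key}={val}\n")
        fh.write("electrode_id,timestamp_s\n")
        for eid in spikes.electrode_ids:
            for t in spikes.trains[eid]:
                fh.write(f"{eid},{t:.6f}\n")


def read_spike_trains(path) -> SpikeTrainSet:
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        df = pd.read_csv(fh)
    if "duration" not in meta:
        raise ValueError(f"{path}: missing '# duration=' header (rates "
                         "would be incomputable)")
    duration = float(meta["duration"])
    if not df.empty and (df["timestamp_s"] < 0).any():
        row = int(df.index[df["timestamp_s"] < 0][0]) + 1
        raise ValueError(f"{path}: negative timestamp at data row {row}")
    trains: dict[int, np.ndarray] = {}
    for eid, grp in df.groupby("electrode_id"):
        t = grp["timestamp_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            bad = int(grp.index[np.flatnonzero(np.diff(t) < 0)[0] + 1]) + 1
            raise ValueError(
                f"{path}: unsorted timestamps for electrode {eid} at data "
                f"row {bad}")
        trains[int(eid)] = t
    return SpikeTrainSet(
        trains=trains, duration=duration,
        culture_id=meta.get("culture_id"),
        condition=meta.get("condition"),
        div=int(meta["div"]) if "div" in meta else None,
        n_active_at_final_div=(int(meta["n_active_at_final_div"])
                               if "n_active_at_final_div" in meta else None))


def write_raw(rec: RawRecording, path) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("voltage", data=rec.voltage.astype(np.float32))
        ds.attrs["units"] = "uV"
        f.attrs["sampling_rate_hz"] = rec.sampling_rate
        f.attrs["channel_ids"] = np.asarray(rec.channel_ids, dtype=np.int64)


def read_raw(path) -> RawRecording:
    with h5py.File(path, "r") as f:
        voltage = f["voltage"][()].astype(np.float64)
        fs = float(f.attrs["sampling_rate_hz"])
        channel_ids = [int(c) for c in f.attrs["channel_ids"]]
    return RawRecording(voltage=voltage, sampling_rate=fs,
                        channel_ids=channel_ids)


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "burst_onsets": truth.burst_onsets.tolist(),
        "burst_offsets": truth.burst_offsets.tolist(),
        "truncated": truth.truncated.astype(bool).tolist(),
        "n_background_spikes": truth.n_background_spikes,
        "n_burst_spikes": truth.n_burst_spikes,
        "warning": truth.warning,
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return GroundTruth(
        burst_onsets=np.asarray(payload["burst_onsets"]),
        burst_offsets=np.asarray(payload["burst_offsets"]),
        truncated=np.asarray(payload["truncated"], dtype=bool),
        n_background_spikes=payload["n_background_spikes"],
        n_burst_spikes=payload["n_burst_spikes"],
        warning=payload.get("warning"))


def write_metrics(table: pd.DataFrame, path, parameter_hash: str | None = None,
                  ) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if parameter_hash is not None:
            fh.write(f"# parameter_hash={parameter_hash}\n")
        table.to_csv(fh, index=False)


def read_metrics(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
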