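"""File I/O: flat interleaved int16 binary with a JSON sidecar (the
convention of common open acquisition systems), delimited spike tables, and
session truth ledgers."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .spikes import SpikeTrain
from .stim import AnalogRecord


def write_flat_binary(record: AnalogRecord, prefix: str | Path, volts_per_bit: float | None = None) -> None:
    """Write channels as interleaved little-endian int16 plus a sidecar.

    ``volts_per_bit`` defaults to spanning the record's absolute maximum over
    the int16 range (with 5% headroom).
    """
    prefix = Path(prefix)
    names = list(record.channels)
    data = np.column_stack([record.channels[n] for n in names]) if names else np.zeros((0, 0))
    if volts_per_bit is None:
        vmax = float(np.max(np.abs(data))) if data.size else 1.0
        volts_per_bit = (vmax * 1.05) / 32767 if vmax > 0 else 1.0 / 32767
    quantized = np.clip(np.round(data / volts_per_bit), -32768, 32767).astype("<i2")
    quantized.tofile(prefix.with_suffix(".bin"))
    sidecar = {
        "sample_rate_hz": record.sample_rate,
        "channel_names": names,
        "volts_per_bit": volts_per_bit,
        "n_samples": int(data.shape[0]),
        "dtype": "int16-le",
        "start_time_s": record.start_time,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_flat_binary(prefix: str | Path) -> AnalogRecord:
    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    names = sidecar["channel_names"]
    raw = np.fromfile(prefix.with_suffix(".bin"), dtype="<i2")
    n_ch = len(names)
    if n_ch and raw.size % n_ch:
        raise InvalidInputError("binary size not divisible by channel count")
    data = raw.reshape(-1, n_ch).astype(float) * sidecar["volts_per_bit"]
    return AnalogRecord(
        channels={name: data[:, i] for i, name in enumerate(names)},
        sample_rate=float(sidecar["sample_rate_hz"]),
        start_time=float(sidecar.get("start_time_s", 0.0)),
    )


def write_spike_tables(trains: list[SpikeTrain], path: str | Path) -> None:
    frames = [t.to_frame() for t in trains]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=["unit_id", "time_s"])
    df.to_csv(path, index=False)


def session_duration(session_dir: str | Path, fallback: float) -> float:
    """Recording duration from the session's truth ledger when present;
    otherwise the caller's fallback (typically the schedule span)."""
    truth = Path(session_dir) / "truth.json"
    if truth.exists():
        return float(json.loads(truth.read_text())["duration_s"])
    return fallback


def read_spike_tables(path: str | Path, duration: float) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    if len(df):
        # tolerate spikes just past the nominal span (decoded schedules
        # underestimate the recording length)
        duration = max(duration, float(df["time_s"].max()) + 1e-9)
    trains = []
    for uid, grp in df.groupby("unit_id", sort=True):
        trains.append(
            SpikeTrain(
                unit_id=str(uid),
                spike_times=np.sort(grp["time_s"].to_numpy(dtype=float)),
                duration=duration,
            )
        )
    return trains
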