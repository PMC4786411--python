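"""Readers and writers for the pipeline's on-disk formats.

Recordings and evoked datasets live in single-file HDF5 containers with
fixed dataset names; event and electrode metadata are plain CSV; audio is
PCM WAV. All writers round-trip losslessly with their readers.

Recording container layout::

    /signal        float32, channels x samples (microvolts)
    /fs            scalar sampling rate (Hz)
    /channel_ids   UTF-8 strings
    attrs: bank_size
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import h5py
from scipy.io import wavfile

from .core import ElectrodeTable, EventTable, EvokedDataset, HighGammaSeries, Recording
from .errors import FormatError, ValidationError


def write_recording(path, rec: Recording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=np.asarray(rec.signal, dtype=np.float32))
        f.create_dataset("fs", data=float(rec.fs))
        f.create_dataset(
            "channel_ids", data=np.array(rec.channel_ids, dtype=h5py.string_dtype())
        )
        f.attrs["bank_size"] = int(rec.bank_size)


def read_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        for name in ("signal", "fs", "channel_ids"):
            if name not in f:
                raise FormatError(f"recording container lacks /{name}")
        signal = f["signal"][()]
        fs = float(f["fs"][()])
        ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["channel_ids"][()]]
        bank_size = int(f.attrs.get("bank_size", 16))
    if signal.ndim != 2:
        raise ValidationError("signal dataset must be channels x samples")
    return Recording(signal=signal, fs=fs, channel_ids=ids, bank_size=bank_size)


def write_events(path, events: EventTable) -> None:
    events.df.to_csv(path, index=False)


def read_events(path, inventory: set[str] | None = None) -> EventTable:
    return EventTable(pd.read_csv(path), inventory=inventory)


def write_electrodes(path, electrodes: ElectrodeTable) -> None:
    electrodes.df.to_csv(path, index=False)


def read_electrodes(path) -> ElectrodeTable:
    return ElectrodeTable(pd.read_csv(path))


def write_audio(path, waveform: np.ndarray, fs: int) -> None:
    wavfile.write(path, int(fs), np.asarray(waveform, dtype=np.float32))


def read_audio(path) -> tuple[np.ndarray, int]:
    fs, data = wavfile.read(path)
    return np.asarray(data), int(fs)


def write_evoked(path, ds: EvokedDataset) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("responses", data=ds.responses)
        f.create_dataset("time_axis", data=ds.time_axis)
        f.create_dataset("tokens", data=np.array(ds.tokens, dtype=h5py.string_dtype()))
        f.create_dataset(
            "electrode_ids",
            data=np.array(ds.electrode_ids, dtype=h5py.string_dtype()),
        )
        f.attrs["task"] = ds.task


def read_evoked(path) -> EvokedDataset:
    with h5py.File(path, "r") as f:
        for name in ("responses", "time_axis", "tokens", "electrode_ids"):
            if name not in f:
                raise FormatError(f"evoked container lacks /{name}")
        return EvokedDataset(
            responses=f["responses"][()],
            time_axis=f["time_axis"][()],
            tokens=[t.decode() for t in f["tokens"][()]],
            electrode_ids=[e.decode() for e in f["electrode_ids"][()]],
            task=str(f.attrs.get("task", "listen")),
        )


def write_high_gamma(path, hg: HighGammaSeries) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=hg.values)
        f.create_dataset("fs_out", data=float(hg.fs_out))
        f.create_dataset(
            "channel_ids", data=np.array(hg.channel_ids, dtype=h5py.string_dtype())
        )
        if hg.baseline_mean is not None:
            f.create_dataset("baseline_mean", data=hg.baseline_mean)
            f.create_dataset("baseline_sd", data=hg.baseline_sd)


def read_high_gamma(path) -> HighGammaSeries:
    with h5py.File(path, "r") as f:
        for name in ("values", "fs_out", "channel_ids"):
            if name not in f:
                raise FormatError(f"high-gamma container lacks /{name}")
        return HighGammaSeries(
            values=f["values"][()],
            fs_out=float(f["fs_out"][()]),
            channel_ids=[c.decode() for c in f["channel_ids"][()]],
            baseline_mean=f["baseline_mean"][()] if "baseline_mean" in f else None,
            baseline_sd=f["baseline_sd"][()] if "baseline_sd" in f else None,
        )
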