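"""Core domain containers for the ECoG speech-analysis pipeline.

The pipeline moves through three representations of neural activity:

* :class:`Recording` -- raw multichannel voltage straight off the amplifier,
  sampled at several kHz, organized in contiguous amplifier banks.
* :class:`HighGammaSeries` -- the analytic amplitude of the 70-150 Hz band,
  downsampled (default 100 Hz) and z-scored against baseline rest data.
* :class:`EvokedDataset` -- trial-aligned high-gamma responses, one
  electrode x token x trial x time array with t = 0 at acoustic onset.

Event and electrode metadata travel as validated :class:`pandas.DataFrame`
wrappers (:class:`EventTable`, :class:`ElectrodeTable`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger("amecog")

#: Closed set of anatomical region labels used throughout.
REGIONS = ("vSMC_sup", "vSMC_inf", "STG", "other")

#: Task labels of the syllable experiments.
TASKS = ("listen", "speak")


def get_logger(name: str = "amecog") -> logging.Logger:
    return logging.getLogger(name)


@dataclass
class Recording:
    """Continuous multichannel voltage (microvolts).

    ``signal`` is channels x samples; ``bank_size`` is the number of
    channels wired to one amplifier bank (the last bank may be short).
    """

    signal: np.ndarray
    fs: float
    channel_ids: list[str]
    bank_size: int = 16

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 2:
            raise ValidationError("signal must be 2-D (channels x samples)")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_ids) != self.signal.shape[0]:
            raise ValidationError(
                f"{len(self.channel_ids)} channel ids for "
                f"{self.signal.shape[0]} signal rows"
            )
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValidationError("channel ids must be unique")
        if self.bank_size < 1:
            raise ValidationError("bank_size must be >= 1")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def banks(self) -> list[np.ndarray]:
        """Indices of each contiguous amplifier bank (last may be short)."""
        edges = range(0, self.n_channels, self.bank_size)
        return [np.arange(s, min(s + self.bank_size, self.n_channels)) for s in edges]


class EventTable:
    """Validated table of labeled events on the recording clock.

    Columns: ``onset_s``, ``offset_s``, ``label``, ``task``; extra columns
    are preserved but ignored by the pipeline.
    """

    REQUIRED = ("onset_s", "offset_s", "label", "task")

    def __init__(self, df: pd.DataFrame, inventory: set[str] | None = None):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"event table missing columns: {missing}")
        df = df.reset_index(drop=True)
        bad = df["onset_s"] >= df["offset_s"]
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"event row {i}: onset {df['onset_s'][i]} >= offset {df['offset_s'][i]}"
            )
        unknown_task = ~df["task"].isin(TASKS)
        if unknown_task.any():
            raise ValidationError(
                f"unknown task labels: {sorted(df['task'][unknown_task].unique())}"
            )
        if inventory is not None:
            unknown = ~df["label"].isin(inventory)
            if unknown.any():
                raise ValidationError(
                    f"labels outside inventory: {sorted(df['label'][unknown].unique())}"
                )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def for_task(self, task: str) -> "EventTable":
        return EventTable(self.df[self.df["task"] == task])

    @property
    def labels(self) -> list[str]:
        return list(self.df["label"])


class ElectrodeTable:
    """Electrode metadata: 2-D cortical-plane coordinates and region labels.

    ``dist_cs_mm`` / ``dist_sf_mm`` are signed distances from the central
    sulcus and the Sylvian fissure.
    """

    REQUIRED = ("id", "x_mm", "y_mm", "dist_cs_mm", "dist_sf_mm", "region")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"electrode table missing columns: {missing}")
        df = df.reset_index(drop=True)
        if df["id"].duplicated().any():
            raise ValidationError("electrode ids must be unique")
        unknown = ~df["region"].isin(REGIONS)
        if unknown.any():
            raise ValidationError(
                f"unknown region labels: {sorted(df['region'][unknown].unique())}"
            )
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> list[str]:
        return [str(i) for i in self.df["id"]]

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of x/y coordinates in mm."""
        return self.df[["x_mm", "y_mm"]].to_numpy(float)

    def regions(self) -> pd.Series:
        return self.df.set_index("id")["region"]

    def subset(self, ids) -> "ElectrodeTable":
        ids = set(ids)
        return ElectrodeTable(self.df[self.df["id"].isin(ids)])


@dataclass
class EvokedDataset:
    """Trial-aligned z-scored high-gamma responses.

    ``responses`` has shape (electrode, token, trial, time); ``time_axis``
    is seconds relative to acoustic onset and must bracket t = 0.
    """

    responses: np.ndarray
    time_axis: np.ndarray
    tokens: list[str]
    electrode_ids: list[str]
    task: str = "listen"

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.responses.ndim != 4:
            raise ValidationError("responses must be 4-D (electrode,token,trial,time)")
        n_el, n_tok, n_tr, n_t = self.responses.shape
        if n_tr < 1:
            raise ValidationError("need at least one trial per electrode")
        if len(self.tokens) != n_tok or len(self.electrode_ids) != n_el:
            raise ValidationError("label lengths do not match responses shape")
        if len(self.time_axis) != n_t:
            raise ValidationError("time axis length does not match responses")
        if np.any(np.diff(self.time_axis) <= 0):
            raise ValidationError("time axis must be strictly increasing")
        if not (self.time_axis[0] <= 0.0 <= self.time_axis[-1]):
            raise ValidationError("time axis must contain t = 0")

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time_axis)))

    def window_slice(self, window: tuple[float, float]) -> slice:
        lo, hi = window
        idx = np.flatnonzero((self.time_axis >= lo) & (self.time_axis <= hi))
        if idx.size == 0:
            raise ValidationError(f"window {window} is outside the time axis")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def token_mean(self) -> np.ndarray:
        """(electrode, token, time) trial-mean responses."""
        return self.responses.mean(axis=2)

    def subset_electrodes(self, ids) -> "EvokedDataset":
        keep = [i for i, e in enumerate(self.electrode_ids) if e in set(ids)]
        return EvokedDataset(
            self.responses[keep],
            self.time_axis,
            list(self.tokens),
            [self.electrode_ids[i] for i in keep],
            self.task,
        )


@dataclass
class HighGammaSeries:
    """Channels x samples analytic-amplitude series at ``fs_out``.

    ``baseline_mean`` / ``baseline_sd`` hold the per-channel rest statistics
    once :func:`amecog.preprocess.zscore_to_baseline` has run, making the
    z-scoring invertible.
    """

    values: np.ndarray
    fs_out: float
    channel_ids: list[str]
    baseline_mean: np.ndarray | None = None
    baseline_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be 2-D (channels x samples)")
        if len(self.channel_ids) != self.values.shape[0]:
            raise ValidationError("channel id count does not match values")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def is_zscored(self) -> bool:
        return self.baseline_mean is not None
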