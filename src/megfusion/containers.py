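"""Shared data containers and HDF5 serialization helpers.

The central container is :class:`EpochedRecording`: a trials x channels x
time block of epoched multichannel data with per-trial condition labels and
a millisecond time axis, the unit on which all preprocessing and decoding
operates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = ["EpochedRecording", "save_array", "load_array"]


@dataclass
class EpochedRecording:
    """Epoched multichannel recording.

    Parameters
    ----------
    data
        Array of shape (n_trials, n_channels, n_times), field-strength
        units (fT) for real MEG or arbitrary units for synthetic data.
    labels
        Integer condition id per trial, shape (n_trials,).
    time_axis
        Time in ms relative to stimulus onset, shape (n_times,).
    sampling_rate
        Sampling rate in Hz.
    baseline_window
        (start_ms, end_ms) of the baseline period, inclusive; must lie
        within the time axis.
    history
        Ordered record of processing steps applied to the data.
    """

    data: np.ndarray
    labels: np.ndarray
    time_axis: np.ndarray
    sampling_rate: float
    baseline_window: tuple[float, float]
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        self.time_axis = np.asarray(self.time_axis, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_times)")
        if self.data.shape[2] != self.time_axis.size:
            raise ValueError(
                f"time_axis length {self.time_axis.size} does not match "
                f"data's third extent {self.data.shape[2]}"
            )
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError("labels must have one entry per trial")
        lo, hi = self.baseline_window
        if lo > hi:
            raise ValueError("baseline_window start exceeds end")
        if lo < self.time_axis[0] or hi > self.time_axis[-1]:
            raise ValueError("baseline_window falls outside the time axis")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def baseline_mask(self) -> np.ndarray:
        lo, hi = self.baseline_window
        return (self.time_axis >= lo) & (self.time_axis <= hi)

    def copy_with(self, data: np.ndarray, step: str) -> "EpochedRecording":
        """Return a copy carrying new data and an appended history entry."""
        return EpochedRecording(
            data=data,
            labels=self.labels.copy(),
            time_axis=self.time_axis.copy(),
            sampling_rate=self.sampling_rate,
            baseline_window=self.baseline_window,
            history=[*self.history, step],
        )

    def pick_channels(self, indices) -> "EpochedRecording":
        """Restrict to a channel subset (e.g. the sources of one ROI)."""
        idx = np.asarray(indices)
        return self.copy_with(
            self.data[:, idx, :], f"pick_channels(n={idx.size})"
        )

    # -- serialization -----------------------------------------------------

    def save(self, path, **attrs) -> None:
        """Write to HDF5 (datasets: data, labels, time_axis)."""
        with h5py.File(path, "w", track_order=True) as f:
            for name, arr in (
                ("data", self.data),
                ("labels", self.labels),
                ("time_axis", self.time_axis),
            ):
                f.create_dataset(name, data=arr, track_times=False)
            f.attrs["sampling_rate"] = self.sampling_rate
            f.attrs["baseline_window"] = list(self.baseline_window)
            f.attrs["history"] = json.dumps(self.history)
            for key, val in attrs.items():
                f.attrs[key] = val

    @classmethod
    def load(cls, path) -> "EpochedRecording":
        with h5py.File(path, "r") as f:
            return cls(
                data=f["data"][()],
                labels=f["labels"][()],
                time_axis=f["time_axis"][()],
                sampling_rate=float(f.attrs["sampling_rate"]),
                baseline_window=tuple(f.attrs["baseline_window"]),
                history=json.loads(f.attrs["history"]),
            )


def save_array(path, name: str, arr: np.ndarray, **attrs) -> None:
    """Write a single named array (plus attributes) to an HDF5 file."""
    with h5py.File(path, "w", track_order=True) as f:
        f.create_dataset(name, data=arr, track_times=False)
        for key, val in attrs.items():
            f.attrs[key] = val


def load_array(path, name: str) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f[name][()]
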