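"""Epoch conditioning before decoding: baseline, artifact rejection, smoothing.

The default pipeline order is baseline correction, then peak-to-peak trial
rejection, then low-pass smoothing of the surviving trials; each step
appends itself to the recording's history so the order applied is always
recoverable from the output.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .containers import EpochedRecording

__all__ = [
    "EpochedRecording",
    "baseline_correct",
    "reject_by_peak_to_peak",
    "rejection_report",
    "lowpass",
    "preprocess",
    "DEFAULT_REJECT_THRESHOLD_FT",
    "DEFAULT_LOWPASS_HZ",
]

DEFAULT_REJECT_THRESHOLD_FT = 6000.0
DEFAULT_LOWPASS_HZ = 20.0


def baseline_correct(epochs: EpochedRecording) -> EpochedRecording:
    """Subtract each trial/channel's mean over the baseline window."""
    mask = epochs.baseline_mask()
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    means = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return epochs.copy_with(epochs.data - means, "baseline_correct")


def _peak_to_peak(data: np.ndarray) -> np.ndarray:
    """Per-trial, per-channel max - min over time: (n_trials, n_channels)."""
    return data.max(axis=2) - data.min(axis=2)


def reject_by_peak_to_peak(
    epochs: EpochedRecording, threshold: float = DEFAULT_REJECT_THRESHOLD_FT
) -> tuple[EpochedRecording, np.ndarray]:
    """Drop trials whose span on any channel strictly exceeds `threshold`.

    A trial spanning exactly the threshold is kept (strict inequality,
    so the boundary rule is deterministic). Surviving trials keep their
    original order. Returns the reduced recording and the indices of the
    rejected trials.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    spans = _peak_to_peak(epochs.data)
    bad = (spans > threshold).any(axis=1)
    rejected = np.flatnonzero(bad)
    if rejected.size == epochs.n_trials:
        raise ValueError(
            f"all {epochs.n_trials} trials exceed the {threshold} "
            "peak-to-peak rejection threshold"
        )
    kept = EpochedRecording(
        data=epochs.data[~bad],
        labels=epochs.labels[~bad],
        time_axis=epochs.time_axis.copy(),
        sampling_rate=epochs.sampling_rate,
        baseline_window=epochs.baseline_window,
        history=[*epochs.history, f"reject_by_peak_to_peak(threshold={threshold})"],
    )
    return kept, rejected


def rejection_report(
    epochs: EpochedRecording, threshold: float = DEFAULT_REJECT_THRESHOLD_FT
) -> list[dict]:
    """JSON-ready record of which trials a threshold would reject and why."""
    spans = _peak_to_peak(epochs.data)
    bad = (spans > threshold).any(axis=1)
    report = []
    for idx in np.flatnonzero(bad):
        ch = int(np.argmax(spans[idx]))
        report.append(
            {
                "trial": int(idx),
                "worst_channel": ch,
                "span": float(spans[idx, ch]),
                "threshold": float(threshold),
            }
        )
    return report


def lowpass(
    epochs: EpochedRecording, cutoff: float = DEFAULT_LOWPASS_HZ
) -> EpochedRecording:
    """Zero-phase low-pass smoothing (4th-order Butterworth, filtfilt).

    Forward-backward application cancels the filter's phase, so the peak
    of a symmetric pulse is not shifted — essential because latencies are
    the downstream quantities of interest. Epoch edges are handled by
    reflect-padding before filtering.
    """
    nyquist = epochs.sampling_rate / 2.0
    if cutoff >= nyquist:
        raise ValueError(
            f"cutoff {cutoff} Hz must be below the Nyquist rate {nyquist} Hz"
        )
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sos = signal.butter(4, cutoff, btype="low", fs=epochs.sampling_rate, output="sos")
    smoothed = signal.sosfiltfilt(sos, epochs.data, axis=2, padtype="even")
    return epochs.copy_with(
        np.ascontiguousarray(smoothed), f"lowpass(cutoff={cutoff})"
    )


def preprocess(
    epochs: EpochedRecording,
    reject_threshold: float = DEFAULT_REJECT_THRESHOLD_FT,
    lowpass_hz: float = DEFAULT_LOWPASS_HZ,
) -> tuple[EpochedRecording, np.ndarray]:
    """Default chain: baseline -> peak-to-peak rejection -> low-pass."""
    corrected = baseline_correct(epochs)
    kept, rejected = reject_by_peak_to_peak(corrected, reject_threshold)
    return lowpass(kept, lowpass_hz), rejected
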