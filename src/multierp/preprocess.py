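"""Filtering, epoching, baseline correction, re-referencing, rejection.

Filters are zero-phase (forward-backward Butterworth): a first-order 0.1 Hz
high-pass and a 4th-order 40 Hz low-pass by default.  Peri-stimulus epochs
span -1 to 2 s; response-locked epochs default to -0.5 to 0.8 s.  Artifact
handling is a simple absolute-amplitude epoch rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ParameterError, SelectionError
from .simulate import RawRecording

STIM_WINDOW_MS = (-1000.0, 2000.0)
RESPONSE_WINDOW_MS = (-500.0, 800.0)
DEFAULT_BASELINE_MS = (-200.0, 0.0)


@dataclass
class EpochSet:
    """epochs x channels x time, with per-epoch condition labels."""

    data: np.ndarray
    times_ms: np.ndarray
    channels: tuple[str, ...]
    labels: pd.DataFrame
    srate_hz: float
    lock: str
    baseline_ms: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ParameterError("epoch data must be 3-D")
        if len(self.labels) != self.data.shape[0]:
            raise ParameterError("label count must equal epoch count")
        if self.baseline_ms is not None:
            lo, hi = self.baseline_ms
            if lo < self.times_ms[0] or hi > self.times_ms[-1]:
                raise ParameterError("baseline outside the epoch window")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def channel_index(self, name: str) -> int:
        return self.channels.index(name)

    def select(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return replace(self, data=self.data[idx],
                       labels=self.labels.iloc[idx].reset_index(drop=True))


def concat_epochs(epoch_sets: list[EpochSet]) -> EpochSet:
    """Pool epoch sets with identical grids/channels (e.g. across runs)."""
    if not epoch_sets:
        raise ParameterError("nothing to concatenate")
    first = epoch_sets[0]
    for es in epoch_sets[1:]:
        if es.channels != first.channels or \
                len(es.times_ms) != len(first.times_ms):
            raise ParameterError("epoch sets are not alignable")
    return replace(first,
                   data=np.concatenate([es.data for es in epoch_sets]),
                   labels=pd.concat([es.labels for es in epoch_sets],
                                    ignore_index=True))


def filter_band(recording: RawRecording, hp_hz: float = 0.1,
                lp_hz: float = 40.0, hp_order: int = 1,
                lp_order: int = 4) -> RawRecording:
    """Zero-phase band-limiting: first-order high-pass + low-pass."""
    nyq = recording.srate_hz / 2.0
    if lp_hz >= nyq:
        raise ParameterError(f"low-pass {lp_hz} Hz at/above Nyquist {nyq}")
    if hp_hz <= 0 or hp_hz >= lp_hz:
        raise ParameterError("need 0 < hp_hz < lp_hz")
    sig = recording.signal
    b, a = sps.butter(hp_order, hp_hz / nyq, btype="highpass")
    sig = sps.filtfilt(b, a, sig, axis=1)
    b, a = sps.butter(lp_order, lp_hz / nyq, btype="lowpass")
    sig = sps.filtfilt(b, a, sig, axis=1)
    return RawRecording(signal=sig, srate_hz=recording.srate_hz,
                        montage=recording.montage,
                        events=recording.events,
                        meta={**recording.meta,
                              "filter": [hp_hz, lp_hz]})


def epoch(recording: RawRecording, events: pd.DataFrame,
          lock: str = "stimulus",
          window_ms: tuple[float, float] | None = None) -> EpochSet:
    """Cut one epoch per event row; out-of-bounds events are dropped.

    ``events`` is any subset of the recording's event table (the caller
    selects rows, e.g. all ``stimulus`` events or all ``response`` events).
    """
    if window_ms is None:
        window_ms = RESPONSE_WINDOW_MS if lock == "response" else STIM_WINDOW_MS
    if len(events) == 0:
        raise SelectionError("empty event selection")
    sr = recording.srate_hz
    lo = int(round(window_ms[0] * sr / 1000.0))
    hi = int(round(window_ms[1] * sr / 1000.0))
    n = recording.n_samples
    keep, slabs = [], []
    for i, s in enumerate(events["sample"].to_numpy()):
        start, stop = s + lo, s + hi
        if start < 0 or stop > n:
            continue
        keep.append(i)
        slabs.append(recording.signal[:, start:stop])
    if not keep:
        raise SelectionError("all events fell outside the recording")
    data = np.stack(slabs)
    times = (np.arange(lo, hi) / sr) * 1000.0
    labels = events.iloc[keep].reset_index(drop=True)
    dropped = len(events) - len(keep)
    es = EpochSet(data=data, times_ms=times,
                  channels=tuple(recording.montage.channels),
                  labels=labels, srate_hz=sr, lock=lock)
    es.labels.attrs["n_dropped"] = dropped
    return es


def baseline_correct(epochs: EpochSet,
                     baseline_ms: tuple[float, float] = DEFAULT_BASELINE_MS
                     ) -> EpochSet:
    """Subtract the per-epoch, per-channel mean over the baseline window."""
    lo, hi = baseline_ms
    mask = (epochs.times_ms >= lo) & (epochs.times_ms <= hi)
    if not mask.any():
        raise ParameterError("baseline window contains no samples")
    mean = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - mean, baseline_ms=baseline_ms)


def average_reference(obj):
    """Re-reference to the per-sample channel mean (idempotent)."""
    if isinstance(obj, EpochSet):
        if obj.data.shape[1] < 2:
            raise ParameterError("average reference needs >= 2 channels")
        return replace(obj, data=obj.data - obj.data.mean(axis=1,
                                                          keepdims=True))
    if obj.signal.shape[0] < 2:
        raise ParameterError("average reference needs >= 2 channels")
    return RawRecording(
        signal=obj.signal - obj.signal.mean(axis=0, keepdims=True),
        srate_hz=obj.srate_hz, montage=obj.montage, events=obj.events,
        meta={**obj.meta, "reference": "average"})


def reject_epochs(epochs: EpochSet,
                  abs_threshold_uv: float = 100.0
                  ) -> tuple[EpochSet, dict]:
    """Drop epochs with any sample beyond the absolute threshold."""
    if abs_threshold_uv <= 0:
        raise ParameterError("threshold must be positive")
    peak = np.abs(epochs.data).max(axis=(1, 2))
    bad = np.flatnonzero(peak > abs_threshold_uv)
    if len(bad) == epochs.n_epochs:
        raise ParameterError(
            f"threshold {abs_threshold_uv} uV rejects every epoch")
    report = {"threshold_uv": abs_threshold_uv,
              "n_rejected": int(len(bad)),
              "rejected_indices": bad.tolist()}
    good = np.setdiff1d(np.arange(epochs.n_epochs), bad)
    return epochs.select(good), report
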