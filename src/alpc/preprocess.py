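"""Multichannel preprocessing and trial-phase extraction.

Three-stage cleanup of an epoched multichannel recording -- common average
reference, zero-phase filtering (high-pass plus line notch), automatic
rejection of outlier trials -- followed by two alternative phase
extraction schemes: averaging the signals across trials before extracting
phases ("avg_eeg"), or extracting phases per epoch and averaging them on
the circle with equal weights ("avg_phase").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.signal import butter, filtfilt, iirnotch, sosfiltfilt

from .metrics import EpochPhaseTable
from .phase import PhaseMeasurement, extract_phases, fold_angles

__all__ = [
    "EpochedRecording",
    "TrialExclusion",
    "rereference_car",
    "zero_phase_filter",
    "reject_bad_trials",
    "extract_trial_phases",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class TrialExclusion:
    trial: int
    reason: str
    mean_p2p: float
    var_p2p: float


@dataclass
class EpochedRecording:
    """Trials x channels x samples, plus bookkeeping flags."""

    data: np.ndarray
    fs_hz: float
    channel_names: tuple[str, ...] = ()
    trial_onsets_s: tuple[float, ...] = ()
    car_applied: bool = False
    filtered: bool = False
    exclusions: tuple[TrialExclusion, ...] = ()

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(data.shape[1]))
        if len(self.channel_names) != data.shape[1]:
            raise ValueError("channel_names must match the channel axis")
        self.data = data

    @property
    def n_trials(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.data.shape[1])

    @property
    def excluded_trials(self) -> tuple[int, ...]:
        return tuple(e.trial for e in self.exclusions)

    @property
    def retained_trials(self) -> tuple[int, ...]:
        excluded = set(self.excluded_trials)
        return tuple(i for i in range(self.n_trials) if i not in excluded)

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            return self.channel_names.index(channel)
        return int(channel)


def rereference_car(recording: EpochedRecording) -> EpochedRecording:
    """Common average reference: subtract the channel mean at every sample."""
    if recording.n_channels < 2:
        raise ValueError("CAR needs at least two channels")
    data = recording.data - recording.data.mean(axis=1, keepdims=True)
    return replace(recording, data=data, car_applied=True)


def zero_phase_filter(
    recording: EpochedRecording,
    highpass_hz: float = 1.0,
    order: int = 10,
    notch_hz: float | None = 50.0,
    notch_q: float = 35.0,
) -> EpochedRecording:
    """Forward-backward high-pass Butterworth plus line-noise notch.

    Both filters are applied in both directions, so steady-state phases in
    the passband are preserved (zero phase shift).
    """
    nyq = recording.fs_hz / 2.0
    if highpass_hz >= nyq:
        raise ValueError("high-pass cutoff at or above Nyquist")
    sos = butter(order, highpass_hz, btype="highpass", fs=recording.fs_hz,
                 output="sos")
    data = sosfiltfilt(sos, recording.data, axis=-1)
    if notch_hz is not None:
        if notch_hz >= nyq:
            raise ValueError("notch frequency at or above Nyquist")
        b, a = iirnotch(notch_hz, notch_q, fs=recording.fs_hz)
        data = filtfilt(b, a, data, axis=-1)
    return replace(recording, data=data, filtered=True)


def reject_bad_trials(
    recording: EpochedRecording, cap_fraction: float = 0.05
) -> EpochedRecording:
    """Exclude trials whose peak-to-peak statistics are positive outliers.

    Per trial, the peak-to-peak range of every channel is computed; the
    mean and the variance of those ranges across channels are the two
    indicators.  A trial is flagged when either indicator exceeds
    Q3 + 1.5*IQR over trials.  At most ``cap_fraction`` of the trials are
    excluded, worst offenders first.
    """
    if recording.n_trials < 4:
        raise ValueError("need at least four trials for quartile statistics")
    p2p = recording.data.max(axis=-1) - recording.data.min(axis=-1)  # trials x ch
    mean_ind = p2p.mean(axis=1)
    var_ind = p2p.var(axis=1)

    def fence_and_scale(ind: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        q1, q3 = np.percentile(ind, [25, 75])
        iqr = q3 - q1
        fence = q3 + 1.5 * iqr
        scale = iqr if iqr > 0 else 1.0
        return ind > fence, (ind - fence) / scale

    mean_out, mean_sev = fence_and_scale(mean_ind)
    var_out, var_sev = fence_and_scale(var_ind)
    flagged = np.flatnonzero(mean_out | var_out)
    severity = np.maximum(mean_sev, var_sev)

    # round up so a gross outlier in a small set can still be dropped
    n_max = int(math.ceil(cap_fraction * recording.n_trials - 1e-9))
    order = sorted(flagged, key=lambda i: -severity[i])[:n_max]
    exclusions = tuple(
        TrialExclusion(
            trial=int(i),
            reason="mean_p2p" if mean_out[i] and mean_sev[i] >= var_sev[i] else "var_p2p",
            mean_p2p=float(mean_ind[i]),
            var_p2p=float(var_ind[i]),
        )
        for i in sorted(order)
    )
    return replace(recording, exclusions=exclusions)


def extract_trial_phases(
    recording: EpochedRecording,
    frequencies: Sequence[float],
    method: Literal["avg_eeg", "avg_phase"] = "avg_eeg",
    channel: int | str = 0,
    onset_skip_s: float = 0.3,
    epoch_s: float = 1.0,
) -> tuple[PhaseMeasurement, EpochPhaseTable]:
    """Steady-state phases of one channel over the retained trials.

    Epochs of length ``epoch_s`` tile each retained trial contiguously
    from ``onset_skip_s``; partial trailing epochs are dropped and the
    first ``onset_skip_s`` never enters any epoch.  ``avg_eeg`` averages
    the trials in the time domain and extracts phases (and amplitudes)
    from the average; ``avg_phase`` extracts per-epoch phases and returns
    their equal-weight circular mean.  Both also return the per-epoch
    phase table (epochs pooled across trials) for consistency statistics.
    """
    if method not in ("avg_eeg", "avg_phase"):
        raise ValueError(f"unknown method {method!r}")
    fs = recording.fs_hz
    ch = recording.channel_index(channel)
    retained = recording.retained_trials
    if not retained:
        raise ValueError("no retained trials")
    trial_len_s = recording.data.shape[2] / fs
    n_epochs = int(math.floor((trial_len_s - onset_skip_s) / epoch_s + 1e-9))
    if n_epochs < 1:
        raise ValueError("trials too short for the onset skip plus one epoch")

    trials = recording.data[list(retained), ch, :]

    cols = []
    amps = []
    for trial in trials:
        for k in range(n_epochs):
            m = extract_phases(
                trial, fs, frequencies,
                window_start=onset_skip_s + k * epoch_s,
                window_length=epoch_s,
            )
            cols.append(m.measured_phases)
            amps.append(m.amplitudes)
    table = EpochPhaseTable(
        frequencies=tuple(float(f) for f in frequencies),
        phases=np.asarray(cols, dtype=float).T,
        epoch_length_s=epoch_s,
    )

    if method == "avg_eeg":
        avg = trials.mean(axis=0)
        measurement = extract_phases(
            avg, fs, frequencies,
            window_start=onset_skip_s, window_length=n_epochs * epoch_s,
        )
    else:
        resultant = table.resultant()
        alpha = fold_angles(np.angle(resultant))
        measurement = PhaseMeasurement(
            frequencies=tuple(float(f) for f in frequencies),
            measured_phases=tuple(float(a) for a in alpha),
            initial_phases=tuple(0.0 for _ in frequencies),
            amplitudes=tuple(float(a) for a in np.mean(amps, axis=0)),
            window_start=onset_skip_s,
            window_length=epoch_s,
        )
    return measurement, table
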