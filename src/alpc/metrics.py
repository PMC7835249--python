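"""Significance and quality statistics for steady-state components.

* latency consistency index (LCI): resultant length of per-epoch phases,
  with the theoretical 95% significance threshold ``sqrt(3/K)``;
* phase-lock value (PLV): within-epoch consistency of the phase
  difference between a narrow signal band and a reference oscillator,
  used to filter poorly locked epochs;
* neighboring SNR: power of a target bin over the mean power of its
  neighbors, with significance thresholds from the F(2, 2N) null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt
from scipy.stats import f as f_dist

__all__ = [
    "EpochPhaseTable",
    "epoch_phase_table",
    "lci",
    "lci_threshold",
    "plv",
    "filter_epochs_by_plv",
    "neighboring_snr",
    "snr_threshold",
    "NeighboringSnr",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class EpochPhaseTable:
    """Per-epoch phases for a set of frequencies.

    ``phases`` has shape (n_frequencies, K) for K non-overlapping epochs
    of equal duration.  The epoch length must be an integer multiple of
    every component period so that the assumed initial phases are the same
    in every epoch.
    """

    frequencies: tuple[float, ...]
    phases: np.ndarray
    epoch_length_s: float

    def __post_init__(self) -> None:
        phases = np.asarray(self.phases, dtype=float)
        if phases.ndim != 2 or phases.shape[0] != len(self.frequencies):
            raise ValueError("phases must have shape (n_frequencies, K)")
        if phases.shape[1] < 2:
            raise ValueError("need at least two epochs")
        cycles = np.asarray(self.frequencies) * self.epoch_length_s
        if np.any(np.abs(cycles - np.round(cycles)) > 1e-6):
            raise ValueError(
                "epoch length must be an integer multiple of every component period"
            )
        object.__setattr__(self, "phases", phases)

    @property
    def n_epochs(self) -> int:
        return int(self.phases.shape[1])

    def resultant(self) -> np.ndarray:
        """Complex mean phasor per frequency (length = LCI)."""
        return np.exp(1j * self.phases).mean(axis=1)


def epoch_phase_table(
    signal: np.ndarray,
    sampling_rate: float,
    frequencies: Sequence[float],
    window_start: float = 0.0,
    epoch_length_s: float = 1.0,
    n_epochs: int | None = None,
) -> EpochPhaseTable:
    """Tile ``signal`` with non-overlapping epochs and extract their phases.

    Epochs start at ``window_start`` and tile contiguously; a partial
    trailing epoch is dropped.  Phases are cosine-referenced to each
    epoch's own start (epoch lengths commensurate with every component
    keep the assumed initial phases constant across epochs).
    """
    from .phase import extract_phases

    signal = np.asarray(signal, dtype=float)
    total = signal.size / sampling_rate
    max_epochs = int(math.floor((total - window_start) / epoch_length_s + 1e-9))
    if n_epochs is None:
        n_epochs = max_epochs
    if n_epochs > max_epochs or n_epochs < 2:
        raise ValueError("signal too short for the requested epochs")
    cols = []
    for k in range(n_epochs):
        m = extract_phases(
            signal,
            sampling_rate,
            frequencies,
            window_start=window_start + k * epoch_length_s,
            window_length=epoch_length_s,
        )
        cols.append(m.measured_phases)
    return EpochPhaseTable(
        frequencies=tuple(float(f) for f in frequencies),
        phases=np.asarray(cols, dtype=float).T,
        epoch_length_s=epoch_length_s,
    )


def lci(table: EpochPhaseTable, frequency_index: int | None = None):
    """Latency consistency index: resultant length of the per-epoch phases.

    Returns a float for a single ``frequency_index`` or the full vector
    when the index is omitted.  Always in [0, 1]; 1 for perfectly stable
    phases, ~K**-0.5 for random ones.
    """
    r = np.abs(table.resultant())
    if frequency_index is None:
        return r
    return float(r[frequency_index])


def lci_threshold(n_epochs: int) -> float:
    """Theoretical 95% significance threshold ``sqrt(3/K)`` for the LCI."""
    if n_epochs < 1:
        raise ValueError("need at least one epoch")
    return math.sqrt(3.0 / n_epochs)


def plv(
    epoch: np.ndarray,
    sampling_rate: float,
    frequency: float,
    band_halfwidth: float = 2.0,
    edge_trim: float = 0.1,
) -> float:
    """Phase-lock value of an epoch to a reference frequency, in [0, 1].

    The epoch is band-pass filtered around ``frequency`` (zero-phase,
    4th-order Butterworth, ``+-band_halfwidth`` Hz), the instantaneous
    analytic phase is extracted, the reference oscillator phase
    ``2*pi*f*t`` is subtracted, and the resultant length of the phase
    difference is returned.  ``edge_trim`` is the fraction trimmed from
    each end to suppress filter transients.
    """
    epoch = np.asarray(epoch, dtype=float)
    lo = frequency - band_halfwidth
    hi = frequency + band_halfwidth
    if hi >= sampling_rate / 2.0:
        raise ValueError("band exceeds Nyquist")
    if lo <= 0.0:
        lo = min(frequency / 2.0, 0.5)
    sos = butter(4, [lo, hi], btype="bandpass", fs=sampling_rate, output="sos")
    narrow = sosfiltfilt(sos, epoch)
    inst_phase = np.angle(hilbert(narrow))
    t = np.arange(epoch.size) / sampling_rate
    diff = inst_phase - TWO_PI * frequency * t
    n_trim = int(edge_trim * epoch.size)
    if n_trim:
        diff = diff[n_trim:-n_trim]
    return float(np.abs(np.exp(1j * diff).mean()))


def filter_epochs_by_plv(
    epochs: Sequence[np.ndarray] | np.ndarray,
    sampling_rate: float,
    frequencies: Sequence[float],
    theta: float,
    reduce: str = "mean",
    band_halfwidth: float = 2.0,
) -> np.ndarray:
    """Indices of epochs whose PLV meets the threshold ``theta``.

    ``reduce`` selects how multiple frequencies of interest are combined:
    ``"mean"`` keeps an epoch when the mean PLV across frequencies is
    >= theta, ``"any"`` when any single frequency reaches it.  ``theta = 0``
    retains every epoch.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    if reduce not in ("mean", "any"):
        raise ValueError("reduce must be 'mean' or 'any'")
    kept = []
    for k, epoch in enumerate(epochs):
        if theta == 0.0:
            kept.append(k)
            continue
        values = [
            plv(epoch, sampling_rate, f, band_halfwidth=band_halfwidth)
            for f in frequencies
        ]
        stat = float(np.mean(values)) if reduce == "mean" else float(np.max(values))
        if stat >= theta:
            kept.append(k)
    return np.asarray(kept, dtype=int)


class NeighboringSnr(NamedTuple):
    snr_db: float
    n_neighbors: int


def neighboring_snr(
    frequencies: np.ndarray,
    powers: np.ndarray,
    target_frequency: float,
    halfwidth: float = 0.5,
    exclude: Sequence[float] | None = None,
) -> NeighboringSnr:
    """Power of the target bin over the mean power of its neighbors, in dB.

    Neighbors are the bins within ``+-halfwidth`` Hz of the target,
    excluding the target bin itself and any frequency listed in
    ``exclude`` (e.g. other known response components in the window).
    """
    frequencies = np.asarray(frequencies, dtype=float)
    powers = np.asarray(powers, dtype=float)
    it = int(np.argmin(np.abs(frequencies - target_frequency)))
    sel = np.abs(frequencies - frequencies[it]) <= halfwidth + 1e-12
    sel[it] = False
    if exclude is not None:
        for f in exclude:
            sel &= np.abs(frequencies - f) > 1e-9
    n = int(sel.sum())
    if n < 1:
        raise ValueError("no neighbor bins within the requested range")
    denom = float(powers[sel].mean())
    if denom <= 0.0:
        raise ValueError("zero neighbor power")
    return NeighboringSnr(10.0 * math.log10(float(powers[it]) / denom), n)


def snr_threshold(alpha: float, n_neighbors: int) -> float:
    """Significance threshold (dB) for the neighboring SNR.

    Under the no-signal null the SNR ratio follows an F distribution with
    (2, 2N) degrees of freedom; the threshold is the 1-alpha quantile in
    dB.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_neighbors < 1:
        raise ValueError("need at least one neighbor bin")
    q = f_dist.ppf(1.0 - alpha, 2, 2 * n_neighbors)
    return 10.0 * math.log10(q)
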