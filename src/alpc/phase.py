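"""Steady-state phase extraction and latency estimation.

The latency of a set of frequency components sharing a common delay is
estimated by minimising the mean phase error (MPE)

    MPE(tau) = (1/N) * sum_i | exp(j*(alpha_i + tau*w_i)) - exp(j*phi_i) |

over a candidate delay ``tau``, where ``alpha_i`` are the measured phases,
``phi_i`` the assumed initial phases and ``w_i = 2*pi*f_i``.  The minimiser
is periodic in the smallest common multiple of the component periods, so a
prior latency range must be imposed.  When the analysis window starts at an
offset ``delta_t`` into the steady state of a zero-initial-phase stimulus,
the search returns a pseudo-latency which is compensated by adding
``delta_t`` back (time compensation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .distortion import common_period

__all__ = [
    "PhaseMeasurement",
    "LatencyEstimate",
    "extract_phases",
    "mean_phase_error",
    "estimate_latency",
    "time_compensate",
]

TWO_PI = 2.0 * math.pi

def fold_angles(values: np.ndarray) -> np.ndarray:
    """Fold angles to [0, 2*pi), snapping 2*pi - eps roundoff back to 0."""
    out = np.mod(np.asarray(values, dtype=float), TWO_PI)
    out[TWO_PI - out < 1e-9] = 0.0
    return out


#: Tolerance (in MPE units) within which distinct refined local minima are
#: considered tied with the global minimum.  Must absorb the residual of
#: the 1e-3 ms golden-section refinement (a chord of ~2*pi*f*1e-6 s).
_AMBIGUITY_TOL = 1e-3


@dataclass(frozen=True)
class PhaseMeasurement:
    """Measured steady-state phases at a set of target frequencies.

    Phases are cosine-referenced with the time origin at the window start
    and folded to [0, 2*pi).  ``initial_phases`` are the assumed initial
    phases of the components (zero for a zero-phase multi-cosine
    stimulus).
    """

    frequencies: tuple[float, ...]
    measured_phases: tuple[float, ...]
    initial_phases: tuple[float, ...]
    amplitudes: tuple[float, ...] | None = None
    window_start: float = 0.0
    window_length: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.frequencies)
        if len(self.measured_phases) != n or len(self.initial_phases) != n:
            raise ValueError("phase vectors must match the frequency vector")
        if self.amplitudes is not None and len(self.amplitudes) != n:
            raise ValueError("amplitudes must match the frequency vector")
        for name in ("measured_phases", "initial_phases"):
            vals = getattr(self, name)
            if any(not (0.0 <= v < TWO_PI + 1e-12) for v in vals):
                raise ValueError(f"{name} must lie in [0, 2*pi)")

    def __len__(self) -> int:
        return len(self.frequencies)

    def subset(self, indices: Sequence[int]) -> "PhaseMeasurement":
        """A new measurement restricted to the given component indices."""
        pick = lambda tup: tuple(tup[i] for i in indices)
        return replace(
            self,
            frequencies=pick(self.frequencies),
            measured_phases=pick(self.measured_phases),
            initial_phases=pick(self.initial_phases),
            amplitudes=None if self.amplitudes is None else pick(self.amplitudes),
        )

    def with_initial_phases(self, phases: Sequence[float]) -> "PhaseMeasurement":
        return replace(self, initial_phases=tuple(float(p) % TWO_PI for p in phases))


@dataclass(frozen=True)
class LatencyEstimate:
    """Result of a latency search on a :class:`PhaseMeasurement`.

    ``latency_ms`` is the time-compensated latency, ``pseudo_latency_ms``
    the raw minimiser of the MPE over the shifted prior range.  ``slope``
    is the least-squares slope (rad/Hz) of the compensated absolute phase
    lags versus frequency; by the apparent-latency rule it satisfies
    ``latency_ms ~= 1000 * slope / (2*pi)``.  ``absolute_phase_lags`` are
    in the pseudo-latency frame (``2*pi*n_i + phi_i - alpha_i``), so their
    own slope corresponds to the pseudo latency.
    """

    latency_ms: float
    pseudo_latency_ms: float
    mpe: float
    frequencies: tuple[float, ...]
    cycle_counts: tuple[int, ...]
    absolute_phase_lags: tuple[float, ...]
    slope: float
    period_ms: float
    prior_range_ms: tuple[float, float]
    per_frequency_phase_error: tuple[float, ...]
    ambiguous: bool = False
    minima_ms: tuple[float, ...] = ()
    delta_t_ms: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mpe <= 2.0 + 1e-9):
            raise ValueError("MPE must lie in [0, 2]")


def extract_phases(
    signal: np.ndarray,
    sampling_rate: float,
    frequencies: Sequence[float],
    window_start: float = 0.0,
    window_length: float | None = None,
) -> PhaseMeasurement:
    """Phases of ``signal`` at target frequencies over an analysis window.

    The phase of component ``i`` is the argument of the complex projection
    of the window onto ``exp(-j*2*pi*f_i*t)`` with the time origin at the
    window start (cosine reference), folded to [0, 2*pi).  Amplitudes are
    the projection magnitudes (the amplitude of a pure cosine is
    recovered exactly).  The window length must be an integer number of
    samples and an integer multiple of every component period, so that
    projections of distinct commensurate components are orthogonal.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    freqs = np.asarray(frequencies, dtype=float)
    if freqs.size == 0:
        raise ValueError("need at least one target frequency")
    if np.any(freqs >= sampling_rate / 2.0):
        raise ValueError("target frequency at or above Nyquist")
    if window_length is None:
        window_length = signal.size / sampling_rate
    n_samples_f = window_length * sampling_rate
    n_samples = int(round(n_samples_f))
    if abs(n_samples_f - n_samples) > 1e-6:
        raise ValueError("window_length times sampling rate must be an integer")
    start = int(round(window_start * sampling_rate))
    if start < 0 or start + n_samples > signal.size:
        raise ValueError("analysis window does not fit inside the signal")
    cycles = freqs * window_length
    if np.any(np.abs(cycles - np.round(cycles)) > 1e-6):
        raise ValueError(
            "window_length must be an integer multiple of every component period"
        )
    seg = signal[start : start + n_samples]
    t = np.arange(n_samples) / sampling_rate
    basis = np.exp(-2j * math.pi * np.outer(freqs, t))
    coef = 2.0 / n_samples * basis @ seg
    alpha = fold_angles(np.angle(coef))
    return PhaseMeasurement(
        frequencies=tuple(freqs),
        measured_phases=tuple(alpha),
        initial_phases=tuple(0.0 for _ in freqs),
        amplitudes=tuple(np.abs(coef)),
        window_start=window_start,
        window_length=window_length,
    )


def mean_phase_error(
    measurement: PhaseMeasurement, tau: float | np.ndarray
) -> float | np.ndarray:
    """Mean phase-error length at candidate delay ``tau`` (seconds).

    Returns the mean chord length between the delayed measured phasors and
    the assumed initial-phase phasors; a value in [0, 2].  ``tau`` may be
    an array, in which case the MPE is evaluated for each entry.
    """
    if len(measurement) == 0:
        raise ValueError("empty measurement")
    omega = TWO_PI * np.asarray(measurement.frequencies)
    alpha = np.asarray(measurement.measured_phases)
    phi = np.asarray(measurement.initial_phases)
    tau_arr = np.atleast_1d(np.asarray(tau, dtype=float))
    err = np.abs(
        np.exp(1j * (alpha[None, :] + tau_arr[:, None] * omega[None, :]))
        - np.exp(1j * phi[None, :])
    ).mean(axis=1)
    return float(err[0]) if np.isscalar(tau) or np.ndim(tau) == 0 else err


def time_compensate(pseudo_latency_ms: float, delta_t_ms: float) -> float:
    """Actual latency from pseudo-latency: ``tau_e = tau_p + delta_t``."""
    return pseudo_latency_ms + delta_t_ms


def _local_minima(values: np.ndarray) -> np.ndarray:
    """Indices of local minima of ``values``, boundaries included."""
    idx = []
    n = values.size
    for i in range(n):
        left = values[i - 1] if i > 0 else np.inf
        right = values[i + 1] if i < n - 1 else np.inf
        if values[i] <= left and values[i] <= right:
            idx.append(i)
    return np.asarray(idx, dtype=int)


def estimate_latency(
    measurement: PhaseMeasurement,
    prior_range_ms: tuple[float, float] = (0.0, 100.0),
    grid_step_ms: float = 0.1,
    delta_t_ms: float = 0.0,
    refine: bool = True,
    system_delay_ms: float = 0.0,
) -> LatencyEstimate:
    """Estimate the common latency of the measured components.

    The pseudo-latency is grid-searched over the prior range shifted by
    ``-delta_t_ms``; the best grid point is refined by bounded
    golden-section search to 1e-3 ms (unless ``refine`` is False), and
    time compensation ``tau_e = tau_p + delta_t`` is applied.  Solutions
    are periodic in the common period of the components; local minima tied
    with the global one are reported in ``minima_ms`` (smallest first, and
    the smallest is the one returned).  ``system_delay_ms`` is an optional
    fixed instrumentation delay added to the reported latency.
    """
    if len(measurement) == 0:
        raise ValueError("empty measurement")
    lo, hi = prior_range_ms
    if not hi > lo:
        raise ValueError("prior range must be non-empty")

    omega = TWO_PI * np.asarray(measurement.frequencies)
    alpha = np.asarray(measurement.measured_phases)
    phi = np.asarray(measurement.initial_phases)

    grid_ms = np.arange(lo - delta_t_ms, hi - delta_t_ms + grid_step_ms / 2, grid_step_ms)
    mpe_grid = np.asarray(mean_phase_error(measurement, grid_ms / 1000.0))

    def _refine(i: int) -> tuple[float, float]:
        tau0 = grid_ms[i]
        if not refine:
            return tau0, float(mpe_grid[i])
        lo_b = max(grid_ms[0], tau0 - grid_step_ms)
        hi_b = min(grid_ms[-1], tau0 + grid_step_ms)
        if hi_b <= lo_b:
            return tau0, float(mpe_grid[i])
        res = minimize_scalar(
            lambda t_ms: mean_phase_error(measurement, t_ms / 1000.0),
            bounds=(lo_b, hi_b),
            method="bounded",
            options={"xatol": 1e-3},
        )
        if res.fun <= mpe_grid[i]:
            return float(res.x), float(res.fun)
        return tau0, float(mpe_grid[i])

    # refine every grid-level local minimum, then compare the refined values
    candidates = sorted(_refine(i) for i in _local_minima(mpe_grid))
    deduped: list[tuple[float, float]] = []
    for tau_c, mpe_c in candidates:
        if deduped and abs(tau_c - deduped[-1][0]) < grid_step_ms / 2:
            if mpe_c < deduped[-1][1]:
                deduped[-1] = (tau_c, mpe_c)
        else:
            deduped.append((tau_c, mpe_c))
    mpe_best = min(m for _, m in deduped)
    tied = [(t, m) for t, m in deduped if m <= mpe_best + _AMBIGUITY_TOL]
    # ties broken toward the smallest latency
    tau_p_ms, mpe_opt = tied[0]
    minima_ms = tuple(round(t + delta_t_ms, 6) for t, _ in tied)

    period_ms = 1000.0 * common_period(measurement.frequencies)
    ambiguous = len(tied) > 1 or (hi - lo) > period_ms + 1e-9

    tau_p = tau_p_ms / 1000.0
    cycles = np.round((alpha + tau_p * omega - phi) / TWO_PI).astype(int)
    lags = TWO_PI * cycles + phi - alpha
    eps = tau_p * omega - lags
    # compensated lags follow tau_e * omega; their LS slope (with free
    # intercept) gives the apparent latency
    freqs = np.asarray(measurement.frequencies)
    comp_lags = lags + omega * delta_t_ms / 1000.0
    if len(freqs) > 1:
        design = np.vstack([freqs, np.ones_like(freqs)]).T
        slope = float(np.linalg.lstsq(design, comp_lags, rcond=None)[0][0])
    else:
        slope = float(comp_lags[0] / freqs[0])

    return LatencyEstimate(
        latency_ms=time_compensate(tau_p_ms, delta_t_ms) + system_delay_ms,
        pseudo_latency_ms=tau_p_ms,
        mpe=mpe_opt,
        frequencies=measurement.frequencies,
        cycle_counts=tuple(int(c) for c in cycles),
        absolute_phase_lags=tuple(float(v) for v in lags),
        slope=slope,
        period_ms=period_ms,
        prior_range_ms=(float(lo), float(hi)),
        per_frequency_phase_error=tuple(float(e) for e in eps),
        ambiguous=ambiguous,
        minima_ms=minima_ms,
        delta_t_ms=delta_t_ms,
    )
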