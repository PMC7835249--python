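"""Parametric baseline: one latency per assumed nonlinear system order.

Given an assumed order ``R``, every order-``R`` combination product of the
stimulus carriers is enumerated, the significant ones (epoch-phase
consistency above the LCI threshold) are retained, and a single latency is
fitted to the whole retained set by minimising the mean phase error --
with no subset selection.  When several subsystems with different
latencies contribute products of the same order, this lumping yields a
biased estimate; with a single common latency it coincides with the
selection-based estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distortion import DistortionSet, StimulusComplex, enumerate_distortions
from .metrics import EpochPhaseTable, lci_threshold
from .phase import LatencyEstimate, PhaseMeasurement, estimate_latency, fold_angles

__all__ = ["MspcResult", "mspc_estimate", "mspc_from_signal", "order_products"]


@dataclass(frozen=True)
class MspcResult:
    """Outcome of one per-order latency fit.

    ``estimate`` is None when no component of the assumed order is
    significant.  ``coupling`` holds the LCI of every candidate product,
    significant or not.
    """

    assumed_order: int
    estimate: LatencyEstimate | None
    used_frequencies: tuple[float, ...]
    candidate_frequencies: tuple[float, ...]
    coupling: tuple[float, ...]
    lci_threshold: float

    @property
    def has_estimate(self) -> bool:
        return self.estimate is not None


def order_products(
    stimulus: StimulusComplex,
    order: int,
    band_limit: float | None = None,
) -> DistortionSet:
    """Combination products of exactly the assumed order ``sum|a_i| = R``."""
    dset = enumerate_distortions(stimulus, order, band_limit=band_limit)
    exact = {
        f: [p for p in prods if p.order == order]
        for f, prods in dset.products.items()
        if any(p.order == order for p in prods)
    }
    return DistortionSet(exact, order, stimulus)


def mspc_estimate(
    stimulus: StimulusComplex,
    table: EpochPhaseTable,
    assumed_order: int,
    significance: float | None = None,
    prior_range_ms: tuple[float, float] = (0.0, 100.0),
    grid_step_ms: float = 0.1,
    delta_t_ms: float = 0.0,
) -> MspcResult:
    """Latency of the assumed-order system from all its significant products.

    ``table`` must contain per-epoch phases for (at least) the exact
    order-``assumed_order`` products of ``stimulus``; measured phases are
    the circular means across epochs and the coupling strength of each
    product is its LCI.  ``significance`` defaults to the theoretical
    threshold ``sqrt(3/K)``.  Initial phases are compensated with the
    linear rule ``phi = sum_i a_i phi_i`` using, for frequencies generated
    by several coefficient vectors, the vector of lowest order.
    """
    if assumed_order < 1:
        raise ValueError("assumed_order must be >= 1")
    products = order_products(stimulus, assumed_order)
    tbl = np.asarray(table.frequencies)
    freqs = [
        f for f in products.frequencies if np.min(np.abs(tbl - f)) <= 1e-9
    ]
    if not freqs:
        raise ValueError("epoch table contains no product of the assumed order")
    if significance is None:
        significance = lci_threshold(table.n_epochs)

    tbl_freqs = np.asarray(table.frequencies)
    idx = [int(np.argmin(np.abs(tbl_freqs - f))) for f in freqs]
    resultant = table.resultant()[idx]
    coupling = np.abs(resultant)
    keep = coupling > significance

    used = [f for f, k in zip(freqs, keep) if k]
    if not used:
        return MspcResult(
            assumed_order=assumed_order,
            estimate=None,
            used_frequencies=(),
            candidate_frequencies=tuple(freqs),
            coupling=tuple(float(c) for c in coupling),
            lci_threshold=significance,
        )

    alpha = fold_angles(np.angle(resultant[keep]))
    phi = []
    for f in used:
        best = min(products[f], key=lambda p: p.order)
        phi.append(best.predicted_phase)
    measurement = PhaseMeasurement(
        frequencies=tuple(used),
        measured_phases=tuple(float(a) for a in alpha),
        initial_phases=tuple(float(p) for p in phi),
        window_length=table.epoch_length_s,
    )
    est = estimate_latency(
        measurement,
        prior_range_ms=prior_range_ms,
        grid_step_ms=grid_step_ms,
        delta_t_ms=delta_t_ms,
    )
    return MspcResult(
        assumed_order=assumed_order,
        estimate=est,
        used_frequencies=tuple(used),
        candidate_frequencies=tuple(freqs),
        coupling=tuple(float(c) for c in coupling),
        lci_threshold=significance,
    )


def mspc_from_signal(
    signal: np.ndarray,
    sampling_rate: float,
    stimulus: StimulusComplex,
    assumed_order: int,
    window_start: float = 0.0,
    epoch_length_s: float = 1.0,
    band_limit: float | None = None,
    significance: float | None = None,
    prior_range_ms: tuple[float, float] = (0.0, 100.0),
    grid_step_ms: float = 0.1,
    candidate_filter: "np.ndarray | list[float] | tuple[float, ...] | None" = None,
) -> MspcResult:
    """Convenience wrapper: enumerate, build the epoch table, estimate.

    The time compensation equals ``window_start`` (the epochs' phases are
    referenced to epoch starts, all congruent to ``window_start`` modulo
    the 1-epoch period).  ``candidate_filter``, when given, restricts the
    order products to frequencies known to carry signal power (e.g. the
    spectrum-detected components); this screens out empty bins whose
    epoch-phase consistency would pass the LCI threshold by chance at the
    ~5% null rate and would pollute the fit with junk phases.
    """
    from .metrics import epoch_phase_table

    if band_limit is None:
        band_limit = sampling_rate / 2.0 - 1.0
    products = order_products(stimulus, assumed_order, band_limit=band_limit)
    freqs = [
        f for f in products.frequencies
        if (f * epoch_length_s) % 1.0 < 1e-9 or abs((f * epoch_length_s) % 1.0 - 1.0) < 1e-9
    ]
    if candidate_filter is not None:
        allowed = np.asarray(candidate_filter, dtype=float)
        freqs = [f for f in freqs if np.min(np.abs(allowed - f)) <= 1e-9]
    if not freqs:
        raise ValueError("no order product commensurate with the epoch length")
    table = epoch_phase_table(
        signal, sampling_rate, freqs, window_start=window_start,
        epoch_length_s=epoch_length_s,
    )
    return mspc_estimate(
        stimulus,
        table,
        assumed_order,
        significance=significance,
        prior_range_ms=prior_range_ms,
        grid_step_ms=grid_step_ms,
        delta_t_ms=window_start * 1000.0,
    )
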