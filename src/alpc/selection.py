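"""Sequential forward selection of latency-consistent frequency subsets.

Starting from a seed frequency (or pair), the selection greedily adds the
candidate component whose inclusion yields the smallest mean phase error,
and terminates when the configured criteria fail: the cost increase of
the step must stay below ``max_mpe_step`` (see ``SfsConfig.step_rule``)
and the running MPE below ``max_mpe``; pair starts additionally require
the latency to move by less than ``max_latency_jump_ms`` per step.
Criteria are tested before committing a candidate, so the offending
frequency is never added.  Repeating the procedure on the leftover
candidates extracts multiple latencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .phase import LatencyEstimate, PhaseMeasurement, estimate_latency

__all__ = ["SfsConfig", "SfsStep", "SfsResult", "sfs_select", "extract_all_latencies"]


@dataclass(frozen=True)
class SfsConfig:
    """Configuration of one selection run.

    ``start`` is a single frequency (Hz), a pair of frequencies, or
    ``"auto"`` (seed with the pair of largest significance weight --
    LCI when supplied, amplitude otherwise; ties resolved toward the
    lower frequency).
    """

    start: float | tuple[float, float] | Literal["auto"] = "auto"
    max_mpe: float = 0.5
    max_mpe_step: float = 0.1
    max_latency_jump_ms: float = 5.0
    prior_range_ms: tuple[float, float] = (0.0, 100.0)
    grid_step_ms: float = 0.1
    delta_t_ms: float = 0.0
    #: How the per-step cost increase is measured against ``max_mpe_step``:
    #: "added_pe" uses the phase-error length of the newly added component
    #: at the new optimum (size-independent; an aliased component whose
    #: wrapped phase error stays large is rejected no matter how big the
    #: subset already is); "mpe_diff" uses the raw difference
    #: MPE(after) - MPE(before), which dilutes the new component's error
    #: by the subset size.
    step_rule: Literal["added_pe", "mpe_diff"] = "added_pe"

    def __post_init__(self) -> None:
        if self.max_mpe <= 0 or self.max_mpe > 2:
            raise ValueError("max_mpe must lie in (0, 2]")
        if self.max_mpe_step <= 0 or self.max_latency_jump_ms <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class SfsStep:
    """One committed step of the greedy growth."""

    step: int
    added_frequency: float
    mpe: float
    latency_ms: float


@dataclass(frozen=True)
class SfsResult:
    selected_frequencies: tuple[float, ...]
    estimate: LatencyEstimate
    trace: tuple[SfsStep, ...]
    low_confidence: bool = False  # fewer than 3 components selected


def _match_index(frequencies: Sequence[float], target: float) -> int:
    arr = np.asarray(frequencies, dtype=float)
    idx = int(np.argmin(np.abs(arr - target)))
    if abs(arr[idx] - target) > 1e-6:
        raise ValueError(f"start frequency {target} Hz absent from candidates")
    return idx


def _auto_start(
    candidates: PhaseMeasurement, weights: Sequence[float] | None
) -> tuple[int, int]:
    """Indices of the two strongest candidates (ties -> lower frequency)."""
    if weights is None:
        weights = candidates.amplitudes
    if weights is None:
        weights = [0.0] * len(candidates)
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-float(weights[i]), candidates.frequencies[i]),
    )
    return order[0], order[1]


def sfs_select(
    candidates: PhaseMeasurement,
    config: SfsConfig,
    weights: Sequence[float] | None = None,
) -> SfsResult:
    """Grow a latency-consistent subset of ``candidates`` greedily.

    ``weights`` (e.g. per-frequency LCI values) are only used to resolve an
    ``"auto"`` start.  Returns the selected subset with its latency
    estimate and the per-step trace.
    """
    n = len(candidates)
    pair_start = config.start == "auto" or isinstance(config.start, (tuple, list))
    if pair_start and config.start == "auto" and n < 2:
        raise ValueError("auto start needs at least two candidates")

    if config.start == "auto":
        selected = list(_auto_start(candidates, weights))
    elif isinstance(config.start, (tuple, list)):
        selected = [_match_index(candidates.frequencies, f) for f in config.start]
        if len(selected) != 2 or selected[0] == selected[1]:
            raise ValueError("pair start must name two distinct candidates")
    else:
        selected = [_match_index(candidates.frequencies, float(config.start))]

    est = estimate_latency(
        candidates.subset(selected),
        prior_range_ms=config.prior_range_ms,
        grid_step_ms=config.grid_step_ms,
        delta_t_ms=config.delta_t_ms,
    )
    trace = [
        SfsStep(0, candidates.frequencies[i], est.mpe, est.latency_ms)
        for i in selected
    ]

    remaining = [i for i in range(n) if i not in selected]
    step = 1
    while remaining:
        best_idx, best_est = None, None
        for j in remaining:
            cand_est = estimate_latency(
                candidates.subset(selected + [j]),
                prior_range_ms=config.prior_range_ms,
                grid_step_ms=config.grid_step_ms,
                delta_t_ms=config.delta_t_ms,
            )
            if best_est is None or cand_est.mpe < best_est.mpe:
                best_idx, best_est = j, cand_est
        assert best_idx is not None and best_est is not None
        # termination is tested before committing the candidate
        if config.step_rule == "added_pe":
            eps_new = best_est.per_frequency_phase_error[-1]
            step_cost = 2.0 * abs(math.sin(eps_new / 2.0))
        else:
            step_cost = best_est.mpe - est.mpe
        if step_cost >= config.max_mpe_step:
            break
        if best_est.mpe >= config.max_mpe:
            break
        if pair_start and abs(best_est.latency_ms - est.latency_ms) >= config.max_latency_jump_ms:
            break
        selected.append(best_idx)
        remaining.remove(best_idx)
        est = best_est
        trace.append(
            SfsStep(step, candidates.frequencies[best_idx], est.mpe, est.latency_ms)
        )
        step += 1

    return SfsResult(
        selected_frequencies=tuple(candidates.frequencies[i] for i in selected),
        estimate=est,
        trace=tuple(trace),
        low_confidence=len(selected) < 3,
    )


def extract_all_latencies(
    candidates: PhaseMeasurement,
    config: SfsConfig,
    max_subsystems: int = 5,
    weights: Sequence[float] | None = None,
    first_start: float | tuple[float, float] | None = None,
) -> list[SfsResult]:
    """Repeatedly run :func:`sfs_select`, removing each selected subset.

    ``first_start`` optionally overrides ``config.start`` for the first
    pass only (later passes fall back to ``config.start``, or ``"auto"``
    if that seed has already been consumed).  Extraction stops when fewer
    than two candidates remain, a selected subset fails the MPE criterion,
    or ``max_subsystems`` is reached.  Returned subsets are disjoint.
    """
    from dataclasses import replace

    results: list[SfsResult] = []
    current = candidates
    cur_weights = None if weights is None else list(weights)
    pass_no = 0
    while len(current) >= 2 and len(results) < max_subsystems:
        start = config.start
        if pass_no == 0 and first_start is not None:
            start = first_start
        else:
            # fall back to auto when the configured seed is gone
            try:
                if isinstance(start, (tuple, list)):
                    for f in start:
                        _match_index(current.frequencies, f)
                elif start != "auto":
                    _match_index(current.frequencies, float(start))
            except ValueError:
                start = "auto"
        res = sfs_select(current, replace(config, start=start), weights=cur_weights)
        if res.estimate.mpe >= config.max_mpe:
            break
        results.append(res)
        keep = [
            i
            for i, f in enumerate(current.frequencies)
            if f not in res.selected_frequencies
        ]
        if not keep:
            break
        current = current.subset(keep)
        if cur_weights is not None:
            cur_weights = [cur_weights[i] for i in keep]
        pass_no += 1
    return results
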