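"""Enumeration of nonlinear distortion products of a multi-tone stimulus.

A polynomial nonlinearity of order ``R`` acting on a superposition of
carriers ``f_1 .. f_I`` emits combination tones at ``|sum_i a_i f_i|`` with
integer coefficients satisfying ``sum_i |a_i| <= R``.  This module
enumerates those products, keeps track of every coefficient vector that
generates a given output frequency, and predicts the initial phase of each
product from the carrier waveform and the carrier initial phases.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterator, Literal, Mapping, Sequence

import numpy as np

__all__ = [
    "StimulusComplex",
    "DistortionProduct",
    "DistortionSet",
    "enumerate_distortions",
    "predict_initial_phase",
    "homogeneous_output_frequencies",
]

TWO_PI = 2.0 * math.pi

#: Frequencies closer than this (Hz) are treated as identical products.
FREQ_MERGE_TOL = 1e-9


def _fold_phase(phi: float) -> float:
    """Map an angle to [0, 2*pi)."""
    out = math.fmod(phi, TWO_PI)
    if out < 0.0:
        out += TWO_PI
    # guard against 2*pi - eps rounding back up
    if out >= TWO_PI:
        out = 0.0
    return out


@dataclass(frozen=True)
class StimulusComplex:
    """A multi-tone stimulus: the input of the nonlinear system under study.

    Parameters
    ----------
    carriers
        Carrier frequencies in Hz, strictly positive and pairwise distinct.
    waveform
        ``"cosine"`` or ``"sine"``; the waveform shared by every carrier.
    initial_phases
        Initial phase of each carrier in radians, folded to [0, 2*pi).
        Defaults to all zeros.
    levels_db
        Optional per-carrier sound levels.  Metadata only; never used in
        any computation.
    onset_skip
        Interval (s) at the start of each presentation excluded from
        analysis.
    duration
        Stimulus duration in seconds; must exceed ``onset_skip``.
    """

    carriers: tuple[float, ...]
    waveform: Literal["cosine", "sine"] = "cosine"
    initial_phases: tuple[float, ...] = ()
    levels_db: tuple[float, ...] | None = None
    onset_skip: float = 0.0
    duration: float = math.inf

    def __post_init__(self) -> None:
        carriers = tuple(float(f) for f in self.carriers)
        if not carriers:
            raise ValueError("stimulus needs at least one carrier")
        if any(f <= 0.0 for f in carriers):
            raise ValueError("carrier frequencies must be strictly positive")
        if len({round(f / FREQ_MERGE_TOL) for f in carriers}) != len(carriers):
            raise ValueError("carrier frequencies must be pairwise distinct")
        if self.waveform not in ("cosine", "sine"):
            raise ValueError(f"unsupported waveform {self.waveform!r}")
        phases = self.initial_phases or tuple(0.0 for _ in carriers)
        phases = tuple(_fold_phase(float(p)) for p in phases)
        if len(phases) != len(carriers):
            raise ValueError("initial_phases length must match carriers")
        if self.levels_db is not None and len(self.levels_db) != len(carriers):
            raise ValueError("levels_db length must match carriers")
        if self.onset_skip < 0.0:
            raise ValueError("onset_skip must be >= 0")
        if self.duration <= self.onset_skip:
            raise ValueError("duration must exceed onset_skip")
        object.__setattr__(self, "carriers", carriers)
        object.__setattr__(self, "initial_phases", phases)

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)


@dataclass(frozen=True)
class DistortionProduct:
    """One combination tone: a signed-integer combination of the carriers.

    ``frequency = |sum_i coefficients[i] * carriers[i]|`` and
    ``order = sum_i |coefficients[i]|``.  ``predicted_phase`` is the initial
    phase of the product referenced to the carrier waveform (see
    :func:`predict_initial_phase`).
    """

    coefficients: tuple[int, ...]
    frequency: float
    order: int
    predicted_phase: float

    def __post_init__(self) -> None:
        if self.frequency <= 0.0:
            raise ValueError("product frequency must be positive")
        if self.order < 1:
            raise ValueError("product order must be >= 1")


@dataclass
class DistortionSet:
    """All distortion products of a stimulus up to a maximum order.

    ``products`` maps each output frequency to every coefficient vector
    that generates it (overlapping products are all recorded, possibly
    with different orders).
    """

    products: dict[float, list[DistortionProduct]]
    max_order: int
    stimulus: StimulusComplex = field(repr=False)

    @property
    def frequencies(self) -> tuple[float, ...]:
        return tuple(sorted(self.products))

    def min_order(self, frequency: float) -> int:
        """Lowest combination order that generates ``frequency``."""
        return min(p.order for p in self[frequency])

    def __getitem__(self, frequency: float) -> list[DistortionProduct]:
        for f, prods in self.products.items():
            if abs(f - frequency) <= FREQ_MERGE_TOL:
                return prods
        raise KeyError(frequency)

    def __contains__(self, frequency: float) -> bool:
        return any(abs(f - frequency) <= FREQ_MERGE_TOL for f in self.products)

    def __len__(self) -> int:
        return len(self.products)


def _coefficient_vectors(n: int, max_order: int) -> Iterator[tuple[int, ...]]:
    """Yield every signed integer vector with ``sum |a_i| <= max_order``."""
    rng = range(-max_order, max_order + 1)
    for vec in itertools.product(rng, repeat=n):
        s = sum(abs(a) for a in vec)
        if 1 <= s <= max_order:
            yield vec


def enumerate_distortions(
    stimulus: StimulusComplex,
    max_order: int,
    mode: Literal["all", "difference_only"] = "all",
    band_limit: float | None = None,
) -> DistortionSet:
    """Enumerate the distinct distortion frequencies of ``stimulus``.

    Parameters
    ----------
    stimulus
        The carrier complex.
    max_order
        Largest combination order ``sum |a_i|`` considered (>= 1).
    mode
        ``"all"`` enumerates every combination (harmonics, sums and
        differences); ``"difference_only"`` restricts the output to the
        pairwise difference tones (exactly one +1 and one -1 coefficient).
    band_limit
        If given, products above this frequency (Hz) are dropped.

    Returns
    -------
    DistortionSet
        Frequencies mapped to all generating coefficient vectors, each
        with its order and predicted initial phase.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    if mode not in ("all", "difference_only"):
        raise ValueError(f"unknown mode {mode!r}")

    carriers = np.asarray(stimulus.carriers)
    n = len(carriers)

    if mode == "difference_only":
        vectors: list[tuple[int, ...]] = []
        if max_order >= 2:
            for i, j in itertools.combinations(range(n), 2):
                vec = [0] * n
                vec[i], vec[j] = 1, -1
                vectors.append(tuple(vec))
        vec_iter: Iterator[tuple[int, ...]] | list[tuple[int, ...]] = vectors
    else:
        vec_iter = _coefficient_vectors(n, max_order)

    products: dict[float, list[DistortionProduct]] = {}
    seen: set[tuple[int, ...]] = set()
    for vec in vec_iter:
        freq = float(np.dot(vec, carriers))
        if freq < 0.0:
            # fold negative-frequency products onto the conjugate vector
            vec = tuple(-a for a in vec)
            freq = -freq
        if freq <= FREQ_MERGE_TOL or vec in seen:
            continue
        seen.add(vec)
        if band_limit is not None and freq > band_limit:
            continue
        order = sum(abs(a) for a in vec)
        phase = _predict_phase(vec, stimulus)
        product = DistortionProduct(vec, freq, order, phase)
        for key in products:
            if abs(key - freq) <= FREQ_MERGE_TOL:
                products[key].append(product)
                break
        else:
            products[freq] = [product]
    for prods in products.values():
        prods.sort(key=lambda p: (p.order, p.coefficients))
    return DistortionSet(dict(sorted(products.items())), max_order, stimulus)


def _carrier_phasors(stimulus: StimulusComplex) -> list[dict[float, complex]]:
    """Analytic line spectra {signed frequency: complex amplitude} of the
    carriers, in the ``exp(j*w*t)`` basis."""
    spectra = []
    for f, phi in zip(stimulus.carriers, stimulus.initial_phases):
        if stimulus.waveform == "cosine":
            amp = 0.5 * np.exp(1j * phi)
        else:  # sine
            amp = 0.5 * np.exp(1j * phi) / 1j
        spectra.append({f: amp, -f: np.conj(amp)})
    return spectra


def _predict_phase(coefficients: Sequence[int], stimulus: StimulusComplex) -> float:
    """Initial phase of the product with the given coefficient vector.

    The phase is computed numerically from the analytic line spectrum of
    the monomial ``prod_i x_i^{|a_i|}`` (a discrete Fourier projection of
    the exact polynomial product), not from a hard-coded table.  The
    returned value is referenced to the carrier waveform: for cosine
    carriers the product is ``A*cos(w*t + phase)``; for sine carriers it is
    ``A*sin(w*t + phase)``, which makes every even-order pure-difference
    product of zero-phase sines come out at pi/2.
    """
    if stimulus.waveform == "cosine":
        # positive real factors only: the combination phase is exactly linear
        return _fold_phase(
            float(np.dot(coefficients, stimulus.initial_phases))
        )
    spectra = _carrier_phasors(stimulus)
    # complex amplitude of the base monomial term for this coefficient vector
    amp = complex(1.0)
    for a, spec, f in zip(coefficients, spectra, stimulus.carriers):
        if a > 0:
            amp *= spec[f] ** a
        elif a < 0:
            amp *= spec[-f] ** (-a)
    # conjugate-pair paddings multiply the amplitude by a positive real
    # constant, so arg(amp) is the cosine-referenced phase of the product;
    # shift by pi/2 to reference it to the sine waveform of the carriers.
    return _fold_phase(float(np.angle(amp)) + math.pi / 2.0)


def predict_initial_phase(
    product: DistortionProduct, stimulus: StimulusComplex
) -> float:
    """Initial phase (radians, in [0, 2*pi)) of ``product`` for ``stimulus``.

    For cosine carriers this is the linear combination
    ``sum_i a_i * phi_i`` of the carrier initial phases; with all-zero
    phases every product starts at phase 0.  For sine carriers a
    waveform-dependent offset from {0, pi/2, pi, 3*pi/2} is added; in
    particular every even-order pure-difference product of zero-phase
    sines has initial phase pi/2.
    """
    if len(product.coefficients) != stimulus.n_carriers:
        raise ValueError("product does not match the stimulus carrier count")
    return _predict_phase(product.coefficients, stimulus)


def homogeneous_output_frequencies(
    stimulus: StimulusComplex,
    order: int,
    band_limit: float | None = None,
) -> tuple[float, ...]:
    """Output frequencies of the homogeneous polynomial ``x(t)**order``.

    A pure power of order ``r`` only emits combinations whose total order
    ``sum |a_i|`` has the same parity as ``r`` (and is at most ``r``); the
    fundamental frequencies, for instance, reappear in a cubic system.
    The DC term is excluded.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    dset = enumerate_distortions(stimulus, order, band_limit=band_limit)
    freqs = [
        f
        for f, prods in dset.products.items()
        if any(p.order % 2 == order % 2 for p in prods)
    ]
    return tuple(sorted(freqs))


def common_period(frequencies: Sequence[float], max_denominator: int = 10**6) -> float:
    """Smallest common multiple of the component periods ``1/f_i`` (s).

    Frequencies are interpreted as rationals (within ``1/max_denominator``);
    the common period is ``1 / gcd(f_i)``.
    """
    fracs = [Fraction(float(f)).limit_denominator(max_denominator) for f in frequencies]
    g = fracs[0]
    for fr in fracs[1:]:
        g = Fraction(math.gcd(g.numerator, fr.numerator), math.lcm(g.denominator, fr.denominator))
    return float(1 / g)
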