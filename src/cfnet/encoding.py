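"""Poisson rate coding of input samples.

A sample is a non-negative feature vector; each channel fires as an
independent Poisson point process whose rate is proportional to the feature
value. Rate vectors are L2-normalized to one spike per time unit, which
fixes the (otherwise arbitrary) time scale of the whole simulation and makes
classification depend on input direction only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class RateVector:
    """Per-channel non-negative firing rates (spikes per time unit).

    After :func:`normalize_rates` the L2 norm is 1; :func:`escalate_rates`
    scales the magnitude while preserving direction.
    """

    rates: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rates", np.asarray(self.rates, dtype=float))
        if self.rates.ndim != 1:
            raise ValueError("rates must be a 1-D vector")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")

    @property
    def dim(self) -> int:
        return self.rates.size

    @property
    def total_rate(self) -> float:
        return float(self.rates.sum())

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.rates))


def normalize_rates(raw: np.ndarray) -> RateVector:
    """Map a raw non-negative sample to a unit-L2 rate vector.

    Rates are proportional to the raw intensities (no offset), then scaled
    to an L2 magnitude of one spike per time unit.

    Raises
    ------
    ValueError
        If the sample has no strictly positive component ("silent sample").
    """
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise ValueError("raw sample must be non-negative")
    norm = np.linalg.norm(raw)
    if norm == 0:
        raise ValueError("silent sample: all-zero input cannot be rate-coded")
    return RateVector(raw / norm)


def escalate_rates(rates: RateVector, step: int, factor: float = 1.5) -> RateVector:
    """Scale rate magnitude by ``factor**step``, preserving direction.

    Used at inference (and in non-dopaminergic training) when a sample fails
    to elicit enough output spikes within a recognition window.
    """
    if step < 0:
        raise ValueError("escalation step must be >= 0")
    if step == 0:
        return rates
    return RateVector(rates.rates * factor**step)


def sample_interarrival(rate: float, rng: np.random.Generator) -> float:
    """Draw one exponential interarrival time for a Poisson channel.

    A zero rate returns ``+inf`` (the channel never spikes).
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if rate == 0:
        return float("inf")
    return float(rng.exponential(1.0 / rate))


def next_input_event(
    rates: RateVector, rng: np.random.Generator
) -> tuple[float, int]:
    """Time to, and channel of, the next spike of the pooled input process.

    By superposition the pooled process is Poisson with rate ``sum(rates)``
    and the spiking channel is chosen with probability proportional to its
    rate.
    """
    total = rates.total_rate
    if total <= 0:
        raise ValueError("no positive rates: pooled process never spikes")
    dt = float(rng.exponential(1.0 / total))
    channel = int(np.searchsorted(np.cumsum(rates.rates) / total, rng.random()))
    return dt, min(channel, rates.dim - 1)


class InputSpikeSampler:
    """Buffered sampler for the pooled input spike process.

    Draws uniforms in chunks and converts them to (interarrival, channel)
    pairs on demand; because uniforms are rate-independent, a rate change
    (escalation) only requires recomputing the channel CDF, keeping the
    random stream identical regardless of instrumentation.
    """

    def __init__(self, rates: RateVector, rng: np.random.Generator, chunk: int = 256):
        self._rng = rng
        self._chunk = chunk
        self._buf = np.empty(0)
        self._pos = 0
        self.set_rates(rates)

    def set_rates(self, rates: RateVector) -> None:
        total = rates.total_rate
        if total <= 0:
            raise ValueError("no positive rates: pooled process never spikes")
        self._total = total
        self._cdf = np.cumsum(rates.rates) / total
        self._dim = rates.dim

    def draw(self) -> tuple[float, int]:
        if self._pos + 2 > self._buf.size:
            self._buf = self._rng.random(self._chunk)
            self._pos = 0
        u_t, u_c = self._buf[self._pos], self._buf[self._pos + 1]
        self._pos += 2
        dt = -np.log1p(-u_t) / self._total
        channel = int(np.searchsorted(self._cdf, u_c))
        return float(dt), min(channel, self._dim - 1)
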