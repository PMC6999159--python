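"""Purely event-driven network simulation.

Time never advances in fixed steps. Because synapses deliver delta spikes
with exponential membrane decay, an output neuron can only fire at the
instant an input spike (or dopaminergic stimulation) arrives, so the
simulator jumps from event to event: it draws the next pooled-Poisson input
arrival, first checks whether the dopaminergic unit would have self-fired
earlier (it fires in the *absence* of layer activity), processes whichever
comes first, and decays all state lazily over the elapsed interval.

A sample presentation runs until the layer has produced the recognition
quota of output spikes (default five). In CFN training the input rate is
never escalated — the dopaminergic neuron takes care of unrecognized
inputs — whereas at inference (and in non-dopaminergic training) the rates
are multiplied up every recognition window until a sufficient response or
the escalation budget is exhausted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .encoding import InputSpikeSampler, RateVector, escalate_rates
from .neurons import DopamineUnit
from .plasticity import (
    AlphaState,
    HomeostasisState,
    PreTraceVector,
    cap_and_normalize,
    depress_dopaminergic_weight,
    stdp_stabilized,
    stdp_static_offset,
)

# Relative tolerance for threshold crossings under dopaminergic stimulation:
# the stimulation gain is constructed so the max-d neuron lands exactly on
# v_th, and one ulp of rounding must not turn that into a miss.
_CROSS_RTOL = 1e-9


@dataclass
class EventRecord:
    time: float
    kind: str  # "input" | "output" | "dopamine"
    unit: int


class EventStream:
    """Ordered capture of spike events for rasters and trigger statistics."""

    def __init__(self) -> None:
        self.records: list[EventRecord] = []

    def append(self, time: float, kind: str, unit: int) -> None:
        if self.records and time <= self.records[-1].time:
            # simultaneous cascade (e.g. dopamine -> stimulated output):
            # nudge to keep times strictly increasing
            time = np.nextafter(self.records[-1].time, math.inf)
        self.records.append(EventRecord(time, kind, unit))

    def __len__(self) -> int:
        return len(self.records)

    def times(self) -> np.ndarray:
        return np.array([r.time for r in self.records])

    def to_rows(self) -> list[tuple[float, int, str]]:
        return [(r.time, r.unit, r.kind) for r in self.records]


@dataclass
class SampleResult:
    """Outcome of one sample presentation."""

    spike_counts: np.ndarray
    dopamine_fires: int
    duration: float
    escalation_steps: int
    winners: list[int] = field(default_factory=list)
    fallback: bool = False
    final_potentials: np.ndarray | None = None

    @property
    def total_spikes(self) -> int:
        return int(self.spike_counts.sum())


class Network:
    """Single-layer CFN (or baseline) with N output neurons.

    Learnable state: the synaptic weight matrix ``W`` (rows unit-norm), the
    dopaminergic fan-out ``d`` (CFN only), and the homeostatic threshold
    offsets (homeostasis baseline only). Transient per-sample state —
    membrane potentials, pre-traces, the dopaminergic potential, boosted
    learning rates — is reset between samples. Freezing stops every
    learnable update (and disables the dopaminergic unit) while leaving
    membrane dynamics free for inference.
    """

    def __init__(self, config: RunConfig, rng: np.random.Generator):
        self.cfg = config
        self.rng = rng
        n, dim = config.n_neurons, config.input_dim
        # signed uniform draws rectified by the cap: diverse, roughly
        # half-sparse initial receptive fields
        self.W = np.empty((n, dim))
        for j in range(n):
            self.W[j] = cap_and_normalize(
                rng.uniform(-config.w_cap, config.w_cap, size=dim), config.w_cap
            )
        self.v = np.zeros(n)
        self.traces = PreTraceVector(dim, config.tau_pre)
        self.alphas = AlphaState(n, config.alpha_base, config.alpha_boost)
        if config.has_dopamine:
            d = 1.0 + 1e-6 * rng.standard_normal(n)
            self.d: np.ndarray | None = d / np.linalg.norm(d)
            self.dopamine: DopamineUnit | None = DopamineUnit(
                v_rest=config.dopamine_v_rest,
                v_th=config.dopamine_v_th,
                tau=config.tau_d,
                inhibit_amount=config.dopamine_inhibit,
            )
        else:
            self.d = None
            self.dopamine = None
        self.homeostasis = (
            HomeostasisState(n, config.theta_plus, config.tau_theta)
            if config.has_homeostasis
            else None
        )
        self.frozen = False
        self.fire_counts = np.zeros(n, dtype=int)  # cumulative training fires

    # -- lifecycle ---------------------------------------------------------

    @property
    def n_neurons(self) -> int:
        return self.cfg.n_neurons

    def freeze(self) -> None:
        self.frozen = True

    def unfreeze(self) -> None:
        self.frozen = False

    def reset_transient(self) -> None:
        """Between-sample reset: potentials, traces, dopamine, alphas."""
        self.v[:] = 0.0
        self.traces.reset()
        if self.dopamine is not None:
            self.dopamine.reset()
        self.alphas.reset_all()

    def effective_threshold(self) -> np.ndarray | float:
        if self.homeostasis is not None:
            return self.cfg.v_th + self.homeostasis.values
        return self.cfg.v_th

    def learnable_state_hash(self) -> int:
        """Hash of every learnable array, for freeze-soundness checks."""
        parts = [self.W.tobytes()]
        if self.d is not None:
            parts.append(self.d.tobytes())
        if self.homeostasis is not None:
            parts.append(self.homeostasis.values.tobytes())
        return hash(b"".join(parts))

    # -- event processing --------------------------------------------------

    def _advance(self, dt: float, plastic: bool) -> None:
        """Lazily decay transient state over an inter-event interval."""
        if dt <= 0:
            return
        self.v *= math.exp(-dt / self.cfg.tau_mem)
        if plastic:
            self.traces.update(dt)
            if self.homeostasis is not None:
                self.homeostasis.decay(dt)
        if self.dopamine is not None and not self.frozen:
            self.dopamine.advance(dt)

    def apply_lateral_inhibition(self, winner: int, plastic: bool) -> None:
        """Winner-take-all competition after an output fire.

        Hard mode resets every other potential to zero; subtractive mode
        subtracts a fixed amount. Either way the losers' boosted learning
        rates are reset and the dopaminergic unit receives one inhibitory
        spike.
        """
        if self.cfg.inhibition == "hard":
            self.v[:] = 0.0
        else:
            self.v -= self.cfg.inhibition_amount
            self.v[winner] = 0.0
        if plastic:
            keep = self.alphas.values[winner]
            self.alphas.reset_all()
            self.alphas.values[winner] = keep  # winner already reset by caller
        if self.dopamine is not None and not self.frozen:
            self.dopamine.inhibit()

    def _handle_fire(self, winner: int, plastic: bool) -> None:
        """STDP, dopaminergic depression, homeostasis, then inhibition."""
        if plastic:
            alpha = self.alphas.values[winner]
            if self.cfg.stdp_rule == "stabilized":
                self.W[winner] = stdp_stabilized(
                    self.W[winner], self.traces.values, alpha,
                    self.cfg.tau_pre, self.cfg.w_cap,
                )
            else:
                self.W[winner] = stdp_static_offset(
                    self.W[winner], self.traces.values, alpha,
                    self.cfg.static_offset, self.cfg.w_cap,
                )
            self.alphas.reset(winner)  # boosted update consumed on own fire
            if self.d is not None:
                self.d = depress_dopaminergic_weight(self.d, winner, self.cfg.eta)
            if self.homeostasis is not None:
                self.homeostasis.on_fire(winner)
            self.fire_counts[winner] += 1
        self.v[winner] = 0.0  # reset of the fired neuron
        self.apply_lateral_inhibition(winner, plastic)

    def _crossings(self, stimulated: bool = False) -> int | None:
        """Index of the firing neuron, lowest index first; None if no fire."""
        th = self.effective_threshold()
        if stimulated:
            th = th * (1.0 - _CROSS_RTOL)
        crossed = np.flatnonzero(self.v >= th)
        return int(crossed[0]) if crossed.size else None

    def integrate_input_spike(self, channel: int, plastic: bool) -> int | None:
        """Deliver one input delta spike to the whole layer; return winner."""
        if plastic:
            self.traces.values[channel] += 1.0
        self.v += self.W[:, channel]
        return self._crossings()

    def fire_dopamine(self, plastic: bool) -> int | None:
        """Dopaminergic fire: boost all learning rates and stimulate firing.

        Every output neuron receives an excitatory increment ``gain * d_j``
        with ``gain = kappa * v_th / max(d)``; at kappa = 1 the neuron with
        the largest dopaminergic weight (the least-fired one) is driven to
        threshold deterministically. The unit then resets, and — if no
        output fire results — will self-fire again after its rise time.
        """
        assert self.d is not None and self.dopamine is not None
        self.alphas.boost_all()
        gain = self.cfg.kappa * self.cfg.v_th / self.d.max()
        self.v += gain * self.d
        self.dopamine.reset()
        return self._crossings(stimulated=True)


def build_network(config: RunConfig, rng: np.random.Generator | int) -> Network:
    """Construct a network for the configured variant, deterministic per seed."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return Network(config, rng)


# ---------------------------------------------------------------------------
# Sample presentation


def present_sample(
    net: Network,
    rates: RateVector,
    mode: str = "train",
    capture: EventStream | None = None,
) -> SampleResult:
    """Present one rate-coded sample until recognized (or given up on).

    In ``train`` mode on an unfrozen CFN the dopaminergic unit is live and
    rates are never escalated; in ``infer`` mode (and in non-dopaminergic
    training) rates escalate multiplicatively each elapsed recognition
    window, up to the configured budget, after which the caller falls back
    to whatever spikes (or potentials) accumulated.
    """
    if mode not in ("train", "infer"):
        raise ValueError(f"unknown mode {mode!r}")
    cfg = net.cfg
    train = mode == "train"
    plastic = train and not net.frozen and cfg.variant != "random_weights"
    dopamine_on = plastic and cfg.has_dopamine
    escalating = not dopamine_on  # infer mode and all baseline training

    n_quota = cfg.recognize_spikes
    spike_counts = np.zeros(net.n_neurons, dtype=int)
    winners: list[int] = []
    dop_fires = 0
    esc_steps = 0
    fallback = False

    sampler = InputSpikeSampler(rates, net.rng)
    now = 0.0
    window_end = cfg.recognize_time
    # absolute time at which the dopaminergic unit would self-fire
    dop_at = now + net.dopamine.time_to_fire() if dopamine_on else math.inf
    pending_t, pending_ch = sampler.draw()
    pending_t += now

    while spike_counts.sum() < n_quota:
        if dopamine_on and dop_at < pending_t:
            # dopaminergic self-fire precedes the next input arrival
            net._advance(dop_at - now, plastic)
            now = dop_at
            dop_fires += 1
            if capture is not None:
                capture.append(now, "dopamine", -1)
            winner = net.fire_dopamine(plastic)
            if winner is not None:
                spike_counts[winner] += 1
                winners.append(winner)
                if capture is not None:
                    capture.append(now, "output", winner)
                net._handle_fire(winner, plastic)
            dop_at = now + net.dopamine.time_to_fire()
            continue
        if escalating and window_end <= pending_t:
            # recognition window elapsed without the spike quota
            if esc_steps >= cfg.max_escalation_steps:
                fallback = spike_counts.sum() < n_quota
                net._advance(window_end - now, plastic)
                now = window_end
                break
            net._advance(window_end - now, plastic)
            now = window_end
            esc_steps += 1
            sampler.set_rates(escalate_rates(rates, esc_steps, cfg.escalation_factor))
            window_end += cfg.recognize_time
            pending_t, pending_ch = sampler.draw()
            pending_t += now
            continue
        # ordinary input spike (ties with dopamine break input-first)
        net._advance(pending_t - now, plastic)
        now = pending_t
        if capture is not None:
            capture.append(now, "input", pending_ch)
        winner = net.integrate_input_spike(pending_ch, plastic)
        if winner is not None:
            spike_counts[winner] += 1
            winners.append(winner)
            if capture is not None:
                capture.append(now, "output", winner)
            net._handle_fire(winner, plastic)
            if dopamine_on:
                dop_at = now + net.dopamine.time_to_fire()
        pending_t, pending_ch = sampler.draw()
        pending_t += now

    final_v = net.v.copy()
    result = SampleResult(
        spike_counts=spike_counts,
        dopamine_fires=dop_fires,
        duration=now,
        escalation_steps=esc_steps,
        winners=winners,
        fallback=fallback,
        final_potentials=final_v,
    )
    net.reset_transient()
    return result


def run_spike_train(
    net: Network,
    spike_times: np.ndarray,
    spike_channels: np.ndarray,
    mode: str = "train",
    capture: EventStream | None = None,
    reset_after: bool = True,
) -> SampleResult:
    """Process a predetermined input spike train event-by-event.

    Used for reproducible micro-experiments and for cross-checking the
    event-driven engine against a time-stepped reference: the input spikes
    are given, so the only dynamics are the deterministic LIF/dopamine/
    plasticity updates.
    """
    if mode not in ("train", "infer"):
        raise ValueError(f"unknown mode {mode!r}")
    cfg = net.cfg
    train = mode == "train"
    plastic = train and not net.frozen and cfg.variant != "random_weights"
    dopamine_on = plastic and cfg.has_dopamine

    spike_times = np.asarray(spike_times, dtype=float)
    spike_channels = np.asarray(spike_channels, dtype=int)
    order = np.argsort(spike_times, kind="stable")
    spike_times, spike_channels = spike_times[order], spike_channels[order]

    spike_counts = np.zeros(net.n_neurons, dtype=int)
    winners: list[int] = []
    dop_fires = 0
    now = 0.0

    for t, ch in zip(spike_times, spike_channels):
        while dopamine_on:
            dop_at = now + net.dopamine.time_to_fire()
            if dop_at >= t:
                break
            net._advance(dop_at - now, plastic)
            now = dop_at
            dop_fires += 1
            if capture is not None:
                capture.append(now, "dopamine", -1)
            winner = net.fire_dopamine(plastic)
            if winner is not None:
                spike_counts[winner] += 1
                winners.append(winner)
                if capture is not None:
                    capture.append(now, "output", winner)
                net._handle_fire(winner, plastic)
        net._advance(t - now, plastic)
        now = t
        if capture is not None:
            capture.append(now, "input", int(ch))
        winner = net.integrate_input_spike(int(ch), plastic)
        if winner is not None:
            spike_counts[winner] += 1
            winners.append(winner)
            if capture is not None:
                capture.append(now, "output", winner)
            net._handle_fire(winner, plastic)

    result = SampleResult(
        spike_counts=spike_counts,
        dopamine_fires=dop_fires,
        duration=now,
        escalation_steps=0,
        winners=winners,
        final_potentials=net.v.copy(),
    )
    if reset_after:
        net.reset_transient()
    return result
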