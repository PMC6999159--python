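"""Continuous-time neuron dynamics.

Output neurons are leaky integrate-and-fire (LIF) units: the membrane
potential decays exponentially toward a zero resting potential
(dv/dt = -v / tau_mem), jumps by the synaptic weight at each incoming delta
spike, and fires (reset to zero, no refractory period) on reaching or
surpassing the static threshold.

The dopaminergic unit is the opposite: its resting potential sits *above*
its firing threshold, so left alone it charges up and self-fires; spikes
from the output layer knock its potential down, silencing it while the
layer is recognizing inputs. It therefore fires exactly when nothing else
does — a novelty detector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


def decay_potential(v, dt: float, tau: float):
    """Exponential decay of membrane potential(s) over ``dt`` time units."""
    if dt < 0:
        raise ValueError("cannot decay backwards in time (dt < 0)")
    if dt == 0:
        return v
    return v * math.exp(-dt / tau)


def integrate_spike(v: float, weight: float, v_th: float) -> tuple[float, bool]:
    """Add one weighted delta spike; fire (inclusive threshold) and reset.

    Returns the post-event potential and whether the neuron fired.
    """
    v = v + weight
    if v >= v_th:
        return 0.0, True
    return v, False


@dataclass
class DopamineUnit:
    """Self-firing dopaminergic neuron.

    With ``v_rest > v_th`` the potential relaxes upward toward ``v_rest``
    and crosses ``v_th`` on the way; the rise constant ``tau_d = 200/ln 2``
    together with ``v_rest = 2``, ``v_th = 1`` places the uninhibited fire
    exactly 200 time units after a reset from zero. Inhibitory spikes from
    the output layer subtract ``inhibit_amount`` (the potential may go
    negative, postponing the next self-fire).
    """

    v_rest: float = 2.0
    v_th: float = 1.0
    tau: float = 200.0 / math.log(2.0)
    inhibit_amount: float = 2.0
    v: float = 0.0

    def __post_init__(self) -> None:
        if not self.v_rest > self.v_th:
            raise ValueError("self-firing requires v_rest > v_th")

    def potential(self, dt: float) -> float:
        """Potential after ``dt`` time units of free relaxation."""
        if dt < 0:
            raise ValueError("cannot evolve backwards in time (dt < 0)")
        return self.v_rest - (self.v_rest - self.v) * math.exp(-dt / self.tau)

    def advance(self, dt: float) -> None:
        self.v = self.potential(dt)

    def time_to_fire(self) -> float:
        """Closed-form time until the threshold crossing from the current v.

        Zero if already at or above threshold. Always finite because
        ``v_rest > v_th``.
        """
        if self.v >= self.v_th:
            return 0.0
        return self.tau * math.log((self.v_rest - self.v) / (self.v_rest - self.v_th))

    def inhibit(self) -> float:
        """Apply one inhibitory spike from the output layer."""
        self.v -= self.inhibit_amount
        return self.v

    def reset(self) -> None:
        self.v = 0.0
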