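"""Plasticity rules: pre-synaptic traces, one-sided STDP, dopaminergic
weight adaptation, and the adaptive-threshold homeostasis baseline.

All learning happens at post-synaptic firing events. Each input channel
carries a trace that jumps by one at every spike on that channel and decays
exponentially with ``tau_pre``; at stationarity its expected value is
``lambda_i * tau_pre``, so ``trace / tau_pre`` is an unbiased stochastic
estimate of the input rate vector — the Hebbian target direction.

Two one-sided rules are provided. The static-offset form
``dw = alpha * (trace - offset)`` is unstable: it pushes weights toward the
axes (binarized when capped at zero). The stabilized form, an Oja-style
correction ``dw = alpha * (trace/tau_pre - w)``, has the input direction as
its fixed point and supports one-shot adoption at alpha = 1.
"""

from __future__ import annotations

import math

import numpy as np


class PreTraceVector:
    """Exponentially decaying trace of pre-synaptic spikes, one per channel."""

    def __init__(self, dim: int, tau_pre: float = 200.0):
        if tau_pre <= 0:
            raise ValueError("tau_pre must be positive")
        self.tau_pre = tau_pre
        self.values = np.zeros(dim)

    def update(self, dt: float, spiked_channel: int | None = None) -> np.ndarray:
        """Decay all traces over ``dt``, then add the unit spike increment."""
        if dt < 0:
            raise ValueError("cannot decay backwards in time (dt < 0)")
        if dt > 0:
            self.values *= math.exp(-dt / self.tau_pre)
        if spiked_channel is not None:
            self.values[spiked_channel] += 1.0
        return self.values

    def reset(self) -> None:
        self.values[:] = 0.0


def cap_and_normalize(w: np.ndarray, w_cap: float = 0.2) -> np.ndarray:
    """Clip each weight to [0, w_cap], then rescale to unit L2 norm.

    The cap keeps stochastic trace outliers from distorting the
    normalization during rapid (boosted) learning.
    """
    w = np.clip(w, 0.0, w_cap)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("degenerate weight vector: all weights clipped to zero")
    return w / norm


def stdp_stabilized(
    w: np.ndarray,
    traces: np.ndarray,
    alpha: float,
    tau_pre: float,
    w_cap: float = 0.2,
) -> np.ndarray:
    """Stabilized one-sided STDP update at a post-synaptic fire.

    ``dw = alpha * (trace/tau_pre - w)``; at alpha = 1 the weight vector is
    replaced outright by the current trace direction (one-shot adoption).
    The result is capped and L2-normalized.
    """
    target = traces / tau_pre
    return cap_and_normalize(w + alpha * (target - w), w_cap)


def stdp_static_offset(
    w: np.ndarray,
    traces: np.ndarray,
    alpha: float,
    offset: float,
    w_cap: float = 0.2,
) -> np.ndarray:
    """Classic static-offset one-sided STDP (no stabilization, no renorm).

    ``dw = alpha * (trace - offset)`` with weights clipped to [0, w_cap].
    Kept as the unstable comparison rule: under it weights migrate to the
    bounds instead of settling on the input direction.
    """
    return np.clip(w + alpha * (traces - offset), 0.0, w_cap)


class AlphaState:
    """Per-neuron learning rates with dopaminergic boosting.

    A dopamine fire boosts every neuron's alpha to ``alpha_boost``; a
    neuron's alpha falls back to ``alpha_base`` the next time it fires
    itself (after that one boosted update is applied) or receives lateral
    inhibition.
    """

    def __init__(self, n: int, alpha_base: float = 0.01, alpha_boost: float = 1.0):
        self.alpha_base = alpha_base
        self.alpha_boost = alpha_boost
        self.values = np.full(n, alpha_base)

    def boost_all(self) -> None:
        self.values[:] = self.alpha_boost

    def reset(self, j: int) -> None:
        self.values[j] = self.alpha_base

    def reset_all(self) -> None:
        self.values[:] = self.alpha_base


def depress_dopaminergic_weight(
    d: np.ndarray, fired: int, eta: float = 0.1
) -> np.ndarray:
    """Depress the fired neuron's dopaminergic weight and renormalize.

    ``d_fired *= (1 - eta)`` then the fan-out is rescaled to unit L2 norm;
    the rescale is the (relative-order-preserving) potentiation of every
    other weight. Weights stay strictly positive, and after any fire
    history the largest weight belongs to a least-fired neuron.
    """
    if not 0 < eta < 1:
        raise ValueError("eta must be in (0, 1)")
    d = d.copy()
    d[fired] *= 1.0 - eta
    return d / np.linalg.norm(d)


class HomeostasisState:
    """Adaptive-threshold homeostasis (baseline networks only).

    Each neuron's effective threshold is ``v_th + theta_j``; theta jumps by
    ``theta_plus`` when the neuron fires and decays with ``tau_theta``,
    spreading activity across the layer.
    """

    def __init__(self, n: int, theta_plus: float = 0.05, tau_theta: float = 1e5):
        self.theta_plus = theta_plus
        self.tau_theta = tau_theta
        self.values = np.zeros(n)

    def decay(self, dt: float) -> None:
        if dt < 0:
            raise ValueError("cannot decay backwards in time (dt < 0)")
        if dt > 0:
            self.values *= math.exp(-dt / self.tau_theta)

    def on_fire(self, j: int) -> None:
        self.values[j] += self.theta_plus
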