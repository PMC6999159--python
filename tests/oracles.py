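"""Independent time-stepped reference implementations.

These re-derive the network dynamics on a fixed time grid, written from the
model equations rather than from the event-driven engine, so they can serve
as an independent cross-check: exponential decay applied step by step,
spikes delivered at grid times, thresholds checked every step.
"""

from __future__ import annotations

import math

import numpy as np


def dopamine_crossing_time(
    v0: float,
    v_rest: float = 2.0,
    v_th: float = 1.0,
    tau: float = 200.0 / math.log(2.0),
    dt: float = 0.005,
    t_max: float = 5000.0,
) -> float:
    """First threshold crossing of the self-firing unit, stepped on a grid."""
    v = v0
    decay = math.exp(-dt / tau)
    t = 0.0
    while t < t_max:
        if v >= v_th:
            return t
        v = v_rest - (v_rest - v) * decay
        t += dt
    return math.inf


def time_stepped_network_run(
    cfg,
    W0: np.ndarray,
    d0: np.ndarray | None,
    spike_trains: list[tuple[np.ndarray, np.ndarray]],
    dt: float = 0.005,
):
    """Grid-based simulation of the full training dynamics.

    ``spike_trains`` is a list of (times, channels) input trains, one per
    sample presentation; transient state resets between presentations while
    weights and dopaminergic weights carry over. Returns the event log per
    sample (time, kind, unit), the final potentials per sample, and the
    final weights.
    """
    n, dim = W0.shape
    W = W0.copy()
    d = d0.copy() if d0 is not None else None
    decay_mem = math.exp(-dt / cfg.tau_mem)
    decay_pre = math.exp(-dt / cfg.tau_pre)
    decay_d = math.exp(-dt / cfg.tau_d)

    all_events, all_final_v = [], []

    for times, channels in spike_trains:
        order = np.argsort(times, kind="stable")
        times, channels = np.asarray(times)[order], np.asarray(channels)[order]
        v = np.zeros(n)
        traces = np.zeros(dim)
        alphas = np.full(n, cfg.alpha_base)
        v_d = 0.0
        events = []
        ptr = 0
        n_steps = int(math.ceil(times[-1] / dt)) + 1

        def fire(j, t_now):
            nonlocal v_d, d
            alpha = alphas[j]
            w = W[j] + alpha * (traces / cfg.tau_pre - W[j])
            w = np.clip(w, 0.0, cfg.w_cap)
            W[j] = w / np.linalg.norm(w)
            alphas[:] = cfg.alpha_base
            if d is not None:
                d = d.copy()
                d[j] *= 1.0 - cfg.eta
                d /= np.linalg.norm(d)
            v[:] = 0.0
            v_d -= cfg.dopamine_inhibit
            events.append((t_now, "output", j))

        for step in range(1, n_steps + 1):
            t = step * dt
            v *= decay_mem
            traces *= decay_pre
            v_d = cfg.dopamine_v_rest - (cfg.dopamine_v_rest - v_d) * decay_d
            if d is not None and v_d >= cfg.dopamine_v_th:
                events.append((t, "dopamine", -1))
                alphas[:] = cfg.alpha_boost
                v += cfg.kappa * cfg.v_th / d.max() * d
                v_d = 0.0
                crossed = np.flatnonzero(v >= cfg.v_th * (1 - 1e-9))
                if crossed.size:
                    fire(int(crossed[0]), t)
            while ptr < len(times) and times[ptr] <= t:
                ch = int(channels[ptr])
                traces[ch] += 1.0
                v += W[:, ch]
                events.append((t, "input", ch))
                crossed = np.flatnonzero(v >= cfg.v_th)
                if crossed.size:
                    fire(int(crossed[0]), t)
                ptr += 1
        all_events.append(events)
        all_final_v.append(v.copy())
    return all_events, all_final_v, W
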