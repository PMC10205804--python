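"""Independent dense-time numerical oracles used by the test suite.

These integrate the motivational dynamics and the gated caching-weight
growth with explicit fixed-step schemes, fully independently of the
closed-form propagation in the package.  The stomach-empty kink inside a
step is handled by splitting the step at the kink and applying Heun (second-order
Runge-Kutta) updates on both sub-steps, without borrowing any exponential
solution from the implementation under test.
"""

from __future__ import annotations

import numpy as np


def euler_motivation(s0, h0, c0, tau_s, tau_d, tau_h, c0_param,
                     eat_times, eat_amounts, cache_times,
                     t_end: float, dt: float, checkpoints):
    """Vectorized split-step Euler across draws.

    All state/parameter arguments are 1-D arrays over draws; ``eat_times``/
    ``cache_times`` are lists of (time, draw-index) pairs (sorted by time).
    Returns arrays (len(checkpoints), n_draws) for s, h, c sampled at the
    checkpoint times (rounded down to the grid).
    """
    s = np.array(s0, dtype=float)
    h = np.array(h0, dtype=float)
    c = np.array(c0, dtype=float)
    tau_s = np.asarray(tau_s, float)
    tau_d = np.asarray(tau_d, float)
    tau_h = np.asarray(tau_h, float)
    c0_param = np.asarray(c0_param, float)
    n_steps = int(round(t_end / dt))
    ev_eat = [(int(round(t / dt)), i, a) for (t, i), a in zip(eat_times, eat_amounts)]
    ev_eat.sort()
    ev_cache = sorted((int(round(t / dt)), i) for t, i in cache_times)
    cp_steps = [min(n_steps, int(round(t / dt))) for t in checkpoints]
    cp_iter = sorted(range(len(cp_steps)), key=lambda j: cp_steps[j])
    out_s = np.empty((len(checkpoints), len(s)))
    out_h = np.empty_like(out_s)
    out_c = np.empty_like(out_s)
    ie = ic = ip = 0
    for k in range(n_steps + 1):
        while ie < len(ev_eat) and ev_eat[ie][0] == k:
            _, i, a = ev_eat[ie]
            s[i] += a
            ie += 1
        while ic < len(ev_cache) and ev_cache[ic][0] == k:
            _, i = ev_cache[ic]
            c[i] -= c[i] * c0_param[i] / tau_d[i]
            if c[i] < 0.0:
                c[i] = 0.0
            ic += 1
        while ip < len(cp_iter) and cp_steps[cp_iter[ip]] == k:
            j = cp_iter[ip]
            out_s[j] = s
            out_h[j] = h
            out_c[j] = c
            ip += 1
        if k == n_steps:
            break
        # split the step at the stomach-empty kink where needed
        ds = dt / tau_s
        t_fed = np.clip(s * tau_s, 0.0, dt)  # time with s > 0 inside the step
        s = np.maximum(s - ds * (s > 0), 0.0)
        h = _heun_decay(h, t_fed, tau_d)
        h = _heun_relax(h, dt - t_fed, tau_h)
        c = _heun_relax(c, dt, tau_d)
    return out_s, out_h, out_c


def _heun_decay(h, step, tau):
    """Heun (second-order) update of dh/dt = -h / tau over ``step``."""
    k1 = -h / tau
    k2 = -(h + step * k1) / tau
    return h + 0.5 * step * (k1 + k2)


def _heun_relax(h, step, tau):
    """Heun update of dh/dt = (1 - h) / tau over ``step``."""
    k1 = (1.0 - h) / tau
    k2 = (1.0 - (h + step * k1)) / tau
    return h + 0.5 * step * (k1 + k2)


def euler_gated_growth(w0, h0, tau_d, tau_h, tau_hungry, theta,
                       eat_steps_amounts, tau_s, t_end: float, dt: float):
    """Euler integration of hunger plus hunger-gated weight growth.

    Same split-step hunger scheme as above (one food per draw); the weight
    obeys dw/dt = (1 - w)/tau_hungry while h > theta.  Returns final (h, w).
    """
    n_draws = len(w0)
    w = np.array(w0, float)
    h = np.array(h0, float)
    s = np.zeros(n_draws)
    tau_s = np.asarray(tau_s, float)
    tau_d = np.asarray(tau_d, float)
    tau_h = np.asarray(tau_h, float)
    tau_hungry = np.asarray(tau_hungry, float)
    n_steps = int(round(t_end / dt))
    ev = sorted(eat_steps_amounts)
    ie = 0
    for k in range(n_steps):
        while ie < len(ev) and ev[ie][0] == k:
            _, i, a = ev[ie]
            s[i] += a
            ie += 1
        w = w + (1.0 - w) / tau_hungry * dt * (h > theta)
        t_fed = np.clip(s * tau_s, 0.0, dt)
        s = np.maximum(s - dt / tau_s * (s > 0), 0.0)
        h = _heun_decay(h, t_fed, tau_d)
        h = _heun_relax(h, dt - t_fed, tau_h)
    return h, w
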