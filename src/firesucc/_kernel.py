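"""Compiled fixed-step RK4 integrator with fire events.

The loop advances the six cover fractions with classical 4th-order
Runge-Kutta at a fixed step (default 1/365 yr), couples the seed-bank
update (exact linear-ODE substep), accumulates the fire-hazard integral
along the evolving solution (time rescaling of a non-homogeneous
exponential clock) and applies fires as instantaneous state resets.

Kept deliberately free of Python objects so numba can compile it; the
friendly wrappers live in :mod:`firesucc.simulate`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: status codes returned by the kernel
OK = 0
SIMPLEX_VIOLATION = 1

_CLIP = 1e-12          # covers below this are treated as extinct
_SIMPLEX_TOL = 1e-6    # abort if total cover exceeds 1 by more than this


@njit(cache=True)
def _rhs(b, c, m, alpha, out):
    tot = 0.0
    for i in range(6):
        tot += b[i]
    free = 1.0 - tot
    cum = 0.0   # sum_{j<=i} b_j
    disp = 0.0  # sum_{j<i} c_j b_j
    for i in range(6):
        cum += b[i]
        out[i] = c[i] * b[i] * (1.0 - cum) - m[i] * b[i] - disp * b[i] \
            + alpha[i] * free
        disp += c[i] * b[i]


@njit(cache=True)
def simulate_kernel(b0, S0, c, m, r, l, gamma, C_conv, eps, flam,
                    n_steps, dt, stride,
                    fires_on, alpha_on, seed,
                    pine_maturity, pine_viability, prod, decay,
                    tau0, sched):
    """Run one realization; see module docstring.

    Parameters are plain float64 arrays/scalars.  ``sched`` is a sorted
    array of imposed fire times (yr); pass an empty array for stochastic
    fires (used when ``fires_on``) or for fire-free runs.

    Returns
    -------
    (times, B, Sout, fire_t, fire_interval, fire_pre, fire_post,
     n_fires, status)
    """
    n_samp = n_steps // stride + 1
    times = np.empty(n_samp)
    B = np.empty((n_samp, 6))
    Sout = np.empty((n_samp, 4))
    n_sched = sched.shape[0]
    max_fires = int(n_steps * dt / 2.0) + n_sched + 4
    fire_t = np.empty(max_fires)
    fire_interval = np.empty(max_fires)
    fire_pre = np.empty((max_fires, 6))
    fire_post = np.empty((max_fires, 6))
    n_fires = 0
    status = OK

    np.random.seed(seed)
    b = b0.copy()
    S = S0.copy()
    alpha = np.zeros(6)
    k1 = np.empty(6)
    k2 = np.empty(6)
    k3 = np.empty(6)
    k4 = np.empty(6)
    btmp = np.empty(6)

    tau = tau0            # time since last fire (biological stand age)
    burned = tau0 < 1e11  # has this stand ever burned?
    t_prev_fire = 0.0     # reference for the logged interval
    acc = 0.0             # hazard integral since last fire
    target = np.random.exponential(1.0)
    next_sched = 0

    times[0] = 0.0
    B[0] = b
    Sout[0] = S
    isamp = 1

    for step in range(n_steps):
        # pine bank viability window
        if tau > pine_viability:
            S[0] = 0.0

        # establishment rates from the seed banks; the term represents
        # post-fire recruitment, so it stays off until the stand has
        # burned at least once (tau0 < 1e11 marks a previously burned
        # stand)
        if alpha_on and burned:
            wsum = 0.0
            for k in range(4):
                wsum += gamma[k + 1] * S[k]
            if wsum > 0.0:
                for k in range(4):
                    alpha[k + 1] = C_conv * gamma[k + 1] * S[k] / wsum
            else:
                for k in range(4):
                    alpha[k + 1] = 0.0

        # RK4 step on the covers (alpha held over the step)
        _rhs(b, c, m, alpha, k1)
        for i in range(6):
            btmp[i] = b[i] + 0.5 * dt * k1[i]
        _rhs(btmp, c, m, alpha, k2)
        for i in range(6):
            btmp[i] = b[i] + 0.5 * dt * k2[i]
        _rhs(btmp, c, m, alpha, k3)
        for i in range(6):
            btmp[i] = b[i] + dt * k3[i]
        _rhs(btmp, c, m, alpha, k4)
        tot = 0.0
        for i in range(6):
            b[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
            if b[i] < _CLIP:
                b[i] = 0.0
            tot += b[i]
        if tot > 1.0 + _SIMPLEX_TOL:
            status = SIMPLEX_VIOLATION

        # shrub seed banks: exact update of dS/dt = prod*b - decay*S
        if decay > 0.0:
            e = np.exp(-decay * dt)
            for k in range(1, 4):
                S[k] = S[k] * e + (prod * b[k + 1] / decay) * (1.0 - e)
        else:
            for k in range(1, 4):
                S[k] += prod * b[k + 1] * dt

        t = (step + 1) * dt
        tau += dt

        # fire events
        burn = False
        if fires_on:
            lam = eps
            for i in range(6):
                lam += flam * l[i] * b[i]
            acc += lam * dt
            # 2-yr minimum return time: defer the event until the stand
            # (and the log interval) reach 2 yr
            if acc >= target and tau >= 2.0 and t - t_prev_fire >= 2.0:
                burn = True
        elif next_sched < n_sched and t >= sched[next_sched] - 1e-12:
            burn = True
            next_sched += 1

        if burn:
            if n_fires < max_fires:
                fire_t[n_fires] = t
                fire_interval[n_fires] = t - t_prev_fire
                for i in range(6):
                    fire_pre[n_fires, i] = b[i]
            pre_pine = b[1]
            for i in range(6):
                b[i] *= r[i]
            S[0] = pre_pine if tau >= pine_maturity else 0.0
            if n_fires < max_fires:
                for i in range(6):
                    fire_post[n_fires, i] = b[i]
            n_fires += 1
            tau = 0.0
            burned = True
            t_prev_fire = t
            acc = 0.0
            target = np.random.exponential(1.0)

        if (step + 1) % stride == 0:
            times[isamp] = t
            B[isamp] = b
            Sout[isamp] = S
            isamp += 1

        if status != OK:
            return (times[:isamp], B[:isamp], Sout[:isamp],
                    fire_t[:n_fires], fire_interval[:n_fires],
                    fire_pre[:n_fires], fire_post[:n_fires],
                    n_fires, status)

    return (times, B, Sout,
            fire_t[:n_fires], fire_interval[:n_fires],
            fire_pre[:n_fires], fire_post[:n_fires],
            n_fires, status)
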