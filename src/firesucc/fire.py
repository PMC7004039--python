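"""Stochastic fire occurrence, instantaneous fire effects and seed banks.

Fires are random instantaneous events.  The waiting time to the next fire
is exponential with a mean return time that shortens as flammable cover
accumulates:

    T_f = (flam_mult * sum_i l_i b_i + epsilon)^(-1)

Because covers evolve between events the hazard is non-homogeneous; events
are drawn by time rescaling (draw E ~ Exp(1), fire when the hazard integral
along the running solution reaches E).  A floor of 2 yr between fires is
enforced by deferring the event, and bare ground still burns about once per
1/epsilon = 10^4 yr.

At a fire, seeders lose all cover and resprouters keep a fraction ``r_i``.
Seeders re-establish afterwards from seed banks: the pine's aerial bank is
released by the fire itself (only if the stand was old enough to carry
mature pines) and stays viable ~2 yr; shrub soil banks are fed by standing
cover and decay gradually between fires.  Establishment rates split a fixed
total ``C_conv`` across seeders in proportion to germinable seed mass:

    alpha_i = C_conv * gamma_i S_i / sum_k gamma_k S_k    (seeders only)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import N_TYPES, EcosystemState, PlantTypeSet, validate_cover

#: position of the pine bank within the seed-bank vector S (types P,R,U,C)
PINE = 0
#: positions of the shrub banks (R, U, C) within S
SHRUBS = (1, 2, 3)


@dataclass(frozen=True)
class SeedBankRules:
    """Seed-bank process constants.

    pine_maturity_age : yr a pine stand must have grown since the last fire
        to carry a canopy seed bank (default 10).
    pine_seed_viability : yr the released pine bank stays germinable after a
        fire (default 2).
    shrub_production_rate : seed-units produced per unit shrub cover per yr.
    shrub_decay_rate : 1/yr decay of shrub soil banks between fires.
    """

    pine_maturity_age: float = 10.0
    pine_seed_viability: float = 2.0
    shrub_production_rate: float = 1.0
    shrub_decay_rate: float = 0.2

    def __post_init__(self):
        for name in ("pine_maturity_age", "pine_seed_viability",
                     "shrub_production_rate", "shrub_decay_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class FireEvent:
    """One realized fire: time, covers just before/after, return interval."""

    t: float
    pre_cover: np.ndarray
    post_cover: np.ndarray
    interval: float


def fire_hazard(b: np.ndarray, params: PlantTypeSet) -> float:
    """Instantaneous fire hazard lambda (1/yr); mean return time is 1/lambda."""
    b = validate_cover(b)
    return float(params.flam_mult * np.dot(params.l, b) + params.epsilon)


def sample_next_fire(hazard, rng: np.random.Generator, t_last_fire: float,
                     dt: float = 1 / 365, t_max: float = 1e7) -> float:
    """Draw the next fire time for a (possibly time-varying) hazard.

    Time rescaling: accumulate ``integral of hazard(t) dt`` from
    ``t_last_fire`` until it reaches an Exp(1) draw.  The realized interval
    is clamped to the 2-yr minimum by deferring the event.

    Parameters
    ----------
    hazard : callable t -> rate (1/yr), evaluated along the running solution
    rng : numpy Generator
    t_last_fire : time of the previous fire (yr)
    dt : quadrature step (yr)
    t_max : give-up horizon; returns ``inf`` if no fire by then

    Returns
    -------
    float : absolute time of the next fire (yr)
    """
    target = rng.exponential(1.0)
    acc = 0.0
    t = t_last_fire
    while acc < target:
        acc += hazard(t) * dt
        t += dt
        if t - t_last_fire > t_max:
            return np.inf
    return max(t, t_last_fire + 2.0)


def apply_fire(state: EcosystemState, params: PlantTypeSet,
               rules: SeedBankRules) -> EcosystemState:
    """Instantaneous fire effects on covers and the pine bank.

    Covers: ``b_i <- r_i b_i`` (seeders to zero, resprouters keep a
    fraction).  The pine aerial bank is released — set to the pre-fire pine
    cover — only if the stand age ``tau_fire`` reached pine maturity;
    otherwise no pine ever seeded and the bank is empty.  Shrub soil banks
    pass through a fire unchanged.  Resets ``tau_fire`` to 0.
    """
    new = state.copy()
    pre_pine = state.b[1]
    new.b = state.b * np.asarray(params.r)
    new.S = state.S.copy()
    new.S[PINE] = pre_pine if state.tau_fire >= rules.pine_maturity_age else 0.0
    new.tau_fire = 0.0
    return new


def seedbank_step(state: EcosystemState, rules: SeedBankRules,
                  dt: float) -> np.ndarray:
    """Advance the seed banks by ``dt`` years; returns the new S vector.

    Shrub banks follow the linear ODE ``dS/dt = production * b - decay * S``
    (integrated exactly over the step, holding cover fixed).  The pine bank
    is a step function of time-since-fire: constant while viable, zero
    after ``pine_seed_viability`` years post-fire.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    S = state.S.copy()
    d = rules.shrub_decay_rate
    p = rules.shrub_production_rate
    for k in SHRUBS:
        b_k = state.b[k + 1]          # S index k maps to type index k+1
        if d > 0:
            decay = np.exp(-d * dt)
            S[k] = S[k] * decay + (p * b_k / d) * (1.0 - decay)
        else:
            S[k] = S[k] + p * b_k * dt
    if state.tau_fire + dt > rules.pine_seed_viability:
        S[PINE] = 0.0
    return S


def postfire_alpha(S: np.ndarray, params: PlantTypeSet) -> np.ndarray:
    """Post-fire establishment rates alpha (1/yr) from the seed banks.

    The four seeders share the fixed total ``C_conv`` in proportion to
    ``gamma_i S_i``; resprouters get 0.  All-zero banks give all-zero alpha.
    """
    S = np.asarray(S, dtype=float)
    if S.shape != (4,):
        raise ValueError("S must have shape (4,)")
    if np.any(S < 0):
        raise ValueError("seed banks must be non-negative")
    gam = np.asarray(params.gamma)[1:5]
    weights = gam * S
    total = weights.sum()
    alpha = np.zeros(N_TYPES)
    if total > 0:
        alpha[1:5] = params.C_conv * weights / total
    return alpha
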