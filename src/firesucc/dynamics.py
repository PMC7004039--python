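"""Deterministic hierarchical competition dynamics.

The cover of type *i* (indices in competitive order, 1 = strongest) obeys

    db_i/dt = c_i b_i (1 - sum_{j<=i} b_j)          colonization of the space
                                                    not held by i or betters
            - m_i b_i                               mortality
            - sum_{j<i} c_j b_j b_i                 displacement by betters
            + alpha_i (1 - sum_{j=1..6} b_j)        post-fire establishment
                                                    into free space

a competition-colonization hierarchy in the tradition of Tilman's
metapopulation models: a superior competitor grows into any space not
already its own or a better's, and colonization by a superior displaces
inferiors in place.  The alpha term is nonzero only for the four seeder
types and only through their seed banks (see :mod:`firesucc.fire`).
"""

from __future__ import annotations

import numpy as np

from .params import N_TYPES, PlantTypeSet, validate_cover


def competition_rhs(b: np.ndarray, params: PlantTypeSet,
                    alpha: np.ndarray | None = None) -> np.ndarray:
    """Time-derivatives of the six cover fractions (1/yr).

    Parameters
    ----------
    b : array_like, shape (6,)
        Cover fractions (validated against the simplex invariants).
    params : PlantTypeSet
    alpha : array_like, shape (6,), optional
        Post-fire establishment rates (1/yr).  Defaults to all zero.
        Resprouters (types 1 and 6) must carry alpha = 0; this is a
        structural property of the model, not a tunable.

    Returns
    -------
    ndarray, shape (6,)
        db/dt.  Pure function: no state is mutated.
    """
    b = validate_cover(b)
    if alpha is None:
        alpha = np.zeros(N_TYPES)
    else:
        alpha = np.asarray(alpha, dtype=float)
        if alpha.shape != (N_TYPES,):
            raise ValueError(f"alpha must have shape ({N_TYPES},)")
        if alpha[0] != 0.0 or alpha[5] != 0.0:
            raise ValueError("resprouters (indices 1 and 6) must have alpha = 0")
    c = np.asarray(params.c)
    m = np.asarray(params.m)
    free = 1.0 - b.sum()
    cum = np.cumsum(b)                       # sum_{j<=i} b_j
    cb = c * b
    disp = np.concatenate(([0.0], np.cumsum(cb)[:-1]))   # sum_{j<i} c_j b_j
    return c * b * (1.0 - cum) - m * b - disp * b + alpha * free


def equilibrium_no_fire(params: PlantTypeSet) -> np.ndarray:
    """Closed-form equilibrium of the fire-free competition model.

    Solved sequentially down the hierarchy: the top competitor settles at
    ``b_1* = 1 - m_1/c_1`` independent of everyone below; each next type
    fills what the betters leave, discounted by their colonization pressure,

        b_i* = max(0, 1 - m_i/c_i - sum_{j<i, b_j*>0} b_j* (1 + c_j/c_i))

    Types driven to zero are excluded from subsequent sums.  Serves as the
    analytic oracle for long fire-free integrations.
    """
    c = np.asarray(params.c)
    m = np.asarray(params.m)
    if np.any(c <= 0):
        raise ValueError("all colonization rates must be positive")
    b = np.zeros(N_TYPES)
    for i in range(N_TYPES):
        occ = sum(b[j] * (1.0 + c[j] / c[i]) for j in range(i) if b[j] > 0)
        b[i] = max(0.0, 1.0 - m[i] / c[i] - occ)
    return b
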