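"""Shared test utilities: seed spawning and random well-separated
parameter draws for equilibrium-oracle checks."""

from __future__ import annotations

import numpy as np

from firesucc import PlantTypeSet, equilibrium_no_fire


def spawn_seeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


def draw_regular_params(rng: np.random.Generator,
                        margin: float = 0.05) -> PlantTypeSet:
    """Random valid parameter set whose equilibrium is well-separated from
    the extinction boundary (every type clearly present or clearly absent),
    so a 1000-yr integration can resolve it to 1e-3."""
    while True:
        c = rng.uniform(0.02, 0.3, 6)
        m = rng.uniform(0.002, 0.08, 6)
        p = PlantTypeSet(c=tuple(c), m=tuple(m))
        eq = equilibrium_no_fire(p)
        # require every type's growth balance to sit away from the zero
        # boundary AND its relaxation rate (~ c_i * |balance|) to be fast
        # enough that 1000 yr resolves the equilibrium to < 1e-3
        gaps = []
        rates = []
        for i in range(6):
            occ = sum(eq[j] * (1.0 + c[j] / c[i]) for j in range(i)
                      if eq[j] > 0)
            gap = abs(1.0 - m[i] / c[i] - occ)
            gaps.append(gap)
            rates.append(c[i] * gap)
        if min(gaps) > margin and min(rates) > 0.009:
            return p
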