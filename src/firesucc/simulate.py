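"""Run configuration and the integration front-end.

`integrate` is the single entry point every experiment goes through: it
assembles plain arrays for the compiled kernel, runs one realization and
wraps the output in a `Trajectory` (yearly-sampled cover and seed-bank
series) and a `FireLog` (one row per realized fire).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .fire import FireEvent, SeedBankRules
from .params import NAMES, PlantTypeSet, validate_cover

#: initial covers of a recently abandoned field (the fire-regime example run)
ABANDONED_FIELD = (0.0039, 0.01, 0.01, 0.01, 0.01, 0.02)

#: small mixed community at abandonment, used for fire-free succession and
#: calibration runs (covers of order 0.01 per type, a little more grass)
SMALL_MIXED = (0.01, 0.01, 0.01, 0.01, 0.01, 0.02)

COVER_COLS = [f"cover_{n}" for n in NAMES]
BANK_COLS = ["S_P", "S_R", "S_U", "S_C"]


@dataclass
class RunConfig:
    """Configuration of one model run.

    Attributes
    ----------
    duration : simulated span (yr).
    dt : integration step (yr); 1/365 reproduces the reference scheme.
    b0 : initial cover fractions (defaults to a recently abandoned field).
    S0 : initial seed banks; by default shrub banks start at the steady
        state implied by ``b0`` and the bank rules, the pine bank at 0.
    fires : stochastic fires on/off.
    scheduled_fires : optional imposed fire times (yr); overrides ``fires``.
    seed : RNG seed for the fire clock (int < 2**31).
    tau0 : stand age at t = 0 (yr since last fire); ``inf`` = never burned.
    sample_every : trajectory sampling stride (yr).
    """

    duration: float = 1000.0
    dt: float = 1 / 365
    b0: tuple = ABANDONED_FIELD
    S0: tuple | None = None
    fires: bool = True
    scheduled_fires: tuple | None = None
    seed: int = 0
    tau0: float = math.inf
    sample_every: float = 1.0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        validate_cover(np.asarray(self.b0, dtype=float))
        if self.scheduled_fires is not None:
            sched = tuple(sorted(float(t) for t in self.scheduled_fires))
            if sched and (sched[0] <= 0 or sched[-1] > self.duration):
                raise ValueError("scheduled fire times must lie in (0, duration]")
            self.scheduled_fires = sched


@dataclass
class Trajectory:
    """Yearly-sampled run output: covers and seed banks versus time."""

    df: pd.DataFrame

    @property
    def times(self) -> np.ndarray:
        return self.df["t"].to_numpy()

    def covers(self) -> np.ndarray:
        """(n_samples, 6) cover matrix."""
        return self.df[COVER_COLS].to_numpy()

    def cover(self, name: str) -> np.ndarray:
        return self.df[f"cover_{name}"].to_numpy()

    def at(self, t: float | np.ndarray) -> np.ndarray:
        """Covers linearly interpolated at time(s) t -> (6,) or (n, 6)."""
        scalar = np.isscalar(t) or np.ndim(t) == 0
        tt = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.column_stack([
            np.interp(tt, self.times, self.df[c].to_numpy()) for c in COVER_COLS
        ])
        return out[0] if scalar else out

    def mean_cover(self, t0: float, t1: float) -> np.ndarray:
        """Per-type mean cover over samples with t0 <= t <= t1."""
        sel = (self.df["t"] >= t0) & (self.df["t"] <= t1)
        if not sel.any():
            raise ValueError(f"no samples in window [{t0}, {t1}]")
        return self.df.loc[sel, COVER_COLS].to_numpy().mean(axis=0)

    def final_cover(self, fraction: float = 0.2) -> np.ndarray:
        """Mean cover over the last ``fraction`` of the run."""
        t_end = self.df["t"].iloc[-1]
        return self.mean_cover((1 - fraction) * t_end, t_end)

    def first_crossing(self, name: str, threshold: float) -> float | None:
        """First sampled time the named type's cover exceeds ``threshold``."""
        cov = self.cover(name)
        above = np.nonzero(cov > threshold)[0]
        return None if above.size == 0 else float(self.times[above[0]])


@dataclass
class FireLog:
    """Realized fire events of one run."""

    df: pd.DataFrame

    def __len__(self) -> int:
        return len(self.df)

    @property
    def times(self) -> np.ndarray:
        return self.df["t"].to_numpy()

    @property
    def intervals(self) -> np.ndarray:
        return self.df["interval"].to_numpy()

    def events(self) -> list[FireEvent]:
        pre_cols = [f"pre_{n}" for n in NAMES]
        post_cols = [f"post_{n}" for n in NAMES]
        return [
            FireEvent(t=row["t"], interval=row["interval"],
                      pre_cover=row[pre_cols].to_numpy(dtype=float),
                      post_cover=row[post_cols].to_numpy(dtype=float))
            for _, row in self.df.iterrows()
        ]


class SimplexViolationError(RuntimeError):
    """Total cover exceeded 1 beyond numerical slack during a run."""


def default_seedbanks(b0, rules: SeedBankRules) -> np.ndarray:
    """Shrub banks at their steady state for covers ``b0``; pine bank 0."""
    b0 = np.asarray(b0, dtype=float)
    S0 = np.zeros(4)
    if rules.shrub_decay_rate > 0:
        S0[1:] = rules.shrub_production_rate * b0[2:5] / rules.shrub_decay_rate
    return S0


def integrate(config: RunConfig, params: PlantTypeSet | None = None,
              rules: SeedBankRules | None = None) -> tuple[Trajectory, FireLog]:
    """Run one realization of the model.

    Stochastic fires use exponential waiting times on the cover-dependent
    hazard (time rescaling along the solution, 2-yr minimum interval);
    ``config.scheduled_fires`` instead imposes fires at fixed times (used
    for experimental-burn plots).  The seed-bank establishment term
    represents post-fire recruitment: it activates once the stand has
    burned (immediately, if ``tau0`` is finite).  Fire-free runs reduce to
    the pure competition model.

    Bit-reproducible for a given ``config.seed``.
    """
    params = params or PlantTypeSet()
    rules = rules or SeedBankRules()
    b0 = np.asarray(config.b0, dtype=float)
    S0 = (np.asarray(config.S0, dtype=float) if config.S0 is not None
          else default_seedbanks(b0, rules))
    if S0.shape != (4,) or np.any(S0 < 0):
        raise ValueError("S0 must be 4 non-negative bank levels")

    scheduled = config.scheduled_fires is not None
    sched = np.asarray(config.scheduled_fires if scheduled else (), dtype=float)
    fires_on = bool(config.fires) and not scheduled
    alpha_on = fires_on or scheduled

    n_steps = int(round(config.duration / config.dt))
    stride = max(1, int(round(config.sample_every / config.dt)))
    arr = params.as_arrays()
    tau0 = 1e12 if math.isinf(config.tau0) else float(config.tau0)

    (times, B, S, fire_t, fire_int, fire_pre, fire_post, n_fires,
     status) = _kernel.simulate_kernel(
        b0, S0, arr["c"], arr["m"], arr["r"], arr["l"], arr["gamma"],
        params.C_conv, params.epsilon, params.flam_mult,
        n_steps, config.dt, stride,
        fires_on, alpha_on, int(config.seed) % (2**32),
        rules.pine_maturity_age, rules.pine_seed_viability,
        rules.shrub_production_rate, rules.shrub_decay_rate,
        tau0, sched)

    if status == _kernel.SIMPLEX_VIOLATION:
        raise SimplexViolationError(
            f"total cover exceeded 1 + 1e-6 at t = {times[-1]:.3f} yr "
            f"(covers {B[-1]})")

    traj = Trajectory(pd.DataFrame(
        {"t": times, **{c: B[:, i] for i, c in enumerate(COVER_COLS)},
         **{c: S[:, i] for i, c in enumerate(BANK_COLS)}}))
    log = FireLog(pd.DataFrame({
        "t": fire_t, "interval": fire_int,
        **{f"pre_{n}": fire_pre[:, i] for i, n in enumerate(NAMES)},
        **{f"post_{n}": fire_post[:, i] for i, n in enumerate(NAMES)},
    }))
    return traj, log
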