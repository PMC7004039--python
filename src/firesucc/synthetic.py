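"""Synthetic observation sets with the structure the calibration expects.

Emulates the two field datasets the calibration was designed around:

* an old-field chronosequence — 73 sites, 1-100 yr since abandonment,
  no fire since — as noisy point samples of the fire-free competition
  trajectory (space-for-time substitution run in reverse: the generator
  *is* the common trajectory the substitution assumes);
* four experimental fire-plot series — plots burned once or twice at
  known times, sampled annually — as noisy samples of runs with imposed
  fires.

Generating parameters are recorded in ``ObservationSet.meta`` so recovery
tests can compare estimates against truth.  What the generator does NOT
emulate: between-site environmental heterogeneity (bedrock, precipitation,
aridity gradients), spatial autocorrelation, or observer bias — synthetic
noise is independent truncated-Gaussian per record and type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import COVER_COLS, ObservationSet
from .fire import SeedBankRules
from .params import PlantTypeSet
from .simulate import SMALL_MIXED, RunConfig, integrate

#: default burn schedules of the four synthetic fire plots (yr): one or
#: two experimental burns within the first 15 yr
DEFAULT_BURN_SCHEDULES = ((5.0,), (4.0, 9.0), (6.0,), (3.0, 12.0))


@dataclass
class SynthSpec:
    """Specification of a synthetic observation set.

    Old-field variant: ``n_sites`` site ages drawn uniformly over
    ``age_range``.  Fire-plot variant: ``n_fireplots`` plots with burn
    times ``burn_schedules`` sampled at ``sampling_times``.
    ``noise_sigma`` is the truncated-Gaussian cover noise sd per type.
    """

    n_sites: int = 73
    age_range: tuple[float, float] = (1.0, 100.0)
    noise_sigma: float = 0.05
    params: PlantTypeSet = field(default_factory=PlantTypeSet)
    rules: SeedBankRules = field(default_factory=SeedBankRules)
    b0: tuple = SMALL_MIXED
    seed: int = 0
    dt: float = 1 / 52
    n_fireplots: int = 4
    burn_schedules: tuple = DEFAULT_BURN_SCHEDULES
    sampling_times: tuple = tuple(float(t) for t in range(0, 21))

    def __post_init__(self):
        if self.n_sites < 1 or self.n_fireplots < 1:
            raise ValueError("need at least one site")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        lo, hi = self.age_range
        if not (0 <= lo <= hi):
            raise ValueError("invalid age range")
        if len(self.burn_schedules) < self.n_fireplots:
            raise ValueError("need a burn schedule per fire plot")


def _add_noise(cov: np.ndarray, sigma: float, rng: np.random.Generator
               ) -> np.ndarray:
    """Truncated-Gaussian cover noise: clip to [0,1], renormalize sums > 1."""
    if sigma > 0:
        cov = np.clip(cov + rng.normal(0.0, sigma, cov.shape), 0.0, 1.0)
    tot = cov.sum(axis=1)
    over = tot > 1.0
    cov[over] /= tot[over, None]
    return cov


def generate_oldfield(spec: SynthSpec) -> ObservationSet:
    """Synthetic old-field chronosequence (noisy fire-free trajectory)."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.age_range
    ages = np.sort(rng.uniform(lo, hi, spec.n_sites))
    cfg = RunConfig(duration=hi + 1.0, dt=spec.dt, b0=spec.b0, fires=False)
    traj, _ = integrate(cfg, spec.params, spec.rules)
    cov = _add_noise(traj.at(ages).copy(), spec.noise_sigma, rng)
    df = pd.DataFrame({
        "site": [f"of{k:03d}" for k in range(spec.n_sites)],
        "kind": "old-field", "time_yr": ages,
        **{c: cov[:, i] for i, c in enumerate(COVER_COLS)},
    })
    return ObservationSet(df=df, kind="old-field", meta={
        "true_params": spec.params, "noise_sigma": spec.noise_sigma,
        "b0": spec.b0, "seed": spec.seed})


def generate_fireplots(spec: SynthSpec) -> ObservationSet:
    """Synthetic fire-plot series (noisy runs with imposed burn times)."""
    rng = np.random.default_rng(spec.seed + 1)
    t_max = max(spec.sampling_times)
    frames = []
    burns_by_site: dict[str, tuple] = {}
    for p in range(spec.n_fireplots):
        burns = tuple(float(t) for t in spec.burn_schedules[p])
        if burns and (min(burns) <= 0 or max(burns) > t_max):
            raise ValueError(
                f"burn times {burns} outside the sampling window (0, {t_max}]")
        site = f"fp{p}"
        burns_by_site[site] = burns
        cfg = RunConfig(duration=t_max + 1.0, dt=spec.dt, b0=spec.b0,
                        scheduled_fires=burns, fires=False)
        traj, _ = integrate(cfg, spec.params, spec.rules)
        times = np.asarray(spec.sampling_times, dtype=float)
        cov = _add_noise(traj.at(times).copy(), spec.noise_sigma, rng)
        frames.append(pd.DataFrame({
            "site": site, "kind": "fire-plot", "time_yr": times,
            **{c: cov[:, i] for i, c in enumerate(COVER_COLS)},
        }))
    df = pd.concat(frames, ignore_index=True)
    return ObservationSet(df=df, kind="fire-plot",
                          burn_schedules=burns_by_site,
                          meta={"true_params": spec.params,
                                "noise_sigma": spec.noise_sigma,
                                "b0": spec.b0, "seed": spec.seed})
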