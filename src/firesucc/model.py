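"""Model / Results facade over the simulation machinery.

`FireVegetationModel` bundles a parameter set and seed-bank rules;
`simulate` returns a `SimulationResults` object carrying the trajectory,
the fire log, summary statistics and a plot method — the shape familiar
from statistical modelling packages, applied to a mechanistic simulator.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .dynamics import equilibrium_no_fire
from .experiments import ScenarioSpec, summarize_run
from .fire import SeedBankRules
from .params import NAMES, PlantTypeSet
from .simulate import FireLog, RunConfig, Trajectory, integrate


class FireVegetationModel:
    """Six-type Mediterranean vegetation model with stochastic fires.

    Parameters
    ----------
    params : PlantTypeSet, optional
        Per-type rates and global constants; defaults to the standard
        calibrated set.
    rules : SeedBankRules, optional
        Seed-bank process constants.

    Examples
    --------
    >>> model = FireVegetationModel()
    >>> res = model.simulate(duration=1000, seed=1)
    >>> res.final_cover().round(2)[0] > 0.5
    True
    """

    def __init__(self, params: PlantTypeSet | None = None,
                 rules: SeedBankRules | None = None):
        self.params = params or PlantTypeSet()
        self.rules = rules or SeedBankRules()

    @classmethod
    def from_table(cls, path, rules: SeedBankRules | None = None
                   ) -> "FireVegetationModel":
        """Build from a tab-separated plant-type parameter table."""
        return cls(PlantTypeSet.from_table(path), rules)

    def with_scenario(self, scenario: ScenarioSpec) -> "FireVegetationModel":
        """A copy of the model under an aridity scenario."""
        return FireVegetationModel(scenario.apply(self.params), self.rules)

    def equilibrium(self) -> np.ndarray:
        """Closed-form fire-free equilibrium covers."""
        return equilibrium_no_fire(self.params)

    def simulate(self, duration: float = 10_000.0, seed: int = 0,
                 b0: Sequence[float] | None = None, fires: bool = True,
                 dt: float = 1 / 365, **kwargs) -> "SimulationResults":
        """Run one realization and wrap it in a results object.

        Extra keyword arguments are forwarded to :class:`RunConfig`
        (``scheduled_fires``, ``S0``, ``tau0``, ``sample_every``).
        """
        cfg_kw = dict(duration=duration, seed=seed, fires=fires, dt=dt)
        if b0 is not None:
            cfg_kw["b0"] = tuple(b0)
        cfg_kw.update(kwargs)
        config = RunConfig(**cfg_kw)
        traj, log = integrate(config, self.params, self.rules)
        return SimulationResults(self, config, traj, log)


class SimulationResults:
    """One realized run: trajectory, fire log, and summaries."""

    def __init__(self, model: FireVegetationModel, config: RunConfig,
                 trajectory: Trajectory, fire_log: FireLog):
        self.model = model
        self.config = config
        self.trajectory = trajectory
        self.fire_log = fire_log

    # -- summary statistics ------------------------------------------------

    def final_cover(self, fraction: float = 0.2) -> np.ndarray:
        """Mean cover per type over the last ``fraction`` of the run."""
        return self.trajectory.final_cover(fraction)

    def classify(self) -> str:
        """forest / open shrubland / mixed, from the final covers."""
        return self.run_summary().state

    def run_summary(self, stats_window: tuple[float, float] | None = None):
        return summarize_run(self.trajectory, self.fire_log, stats_window)

    def mean_fire_interval(self, window: tuple[float, float] | None = None
                           ) -> float:
        from .experiments import fire_interval_stats
        if window is None:
            t_end = float(self.trajectory.times[-1])
            window = (0.8 * t_end, t_end)
        return fire_interval_stats(self.fire_log, window)[0]

    def summary(self) -> str:
        """Human-readable run report."""
        s = self.run_summary()
        lines = [
            "Fire-vegetation simulation",
            "==========================",
            f"duration: {self.config.duration:g} yr   dt: {self.config.dt:g} yr"
            f"   seed: {self.config.seed}",
            f"fires realized: {len(self.fire_log)}",
            f"state (mean cover, last 20%): {s.state}",
            "",
            "type   final cover",
        ]
        for i, n in enumerate(NAMES):
            lines.append(f"  {n}    {s.final_cover[i]:.4f}")
        lines.append(f"  free space {1 - s.final_cover.sum():.4f}")
        if np.isfinite(s.mean_fire_interval):
            lines.append(f"mean fire return interval (last 20%): "
                         f"{s.mean_fire_interval:.1f} yr")
        if s.time_to_dominance is not None:
            lines.append(f"time to oak dominance (cover > 0.5): "
                         f"{s.time_to_dominance:.0f} yr")
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------

    def plot(self, ax=None, show_fires: bool = True):
        """Cover-versus-time diagnostic plot (one line per type)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        t = self.trajectory.times
        for n in NAMES:
            ax.plot(t, self.trajectory.cover(n), label=n, lw=1)
        if show_fires and len(self.fire_log):
            for ft in self.fire_log.times:
                ax.axvline(ft, color="0.85", lw=0.5, zorder=0)
        ax.set_xlabel("time (yr)")
        ax.set_ylabel("cover fraction")
        ax.set_ylim(0, 1)
        ax.legend(ncol=6, fontsize=8)
        return ax
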