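"""Aridity-scenario factory and long-/short-term experiment runners.

Aridity acts on the model through three knobs, combined full-factorially
into 48 scenarios: the oak's post-fire resprouting fraction ``r1``
(0.9 -> 0.6), the oak colonization rate ``c1`` (0.047 -> 0.011 /yr) and a
flammability multiplier on all types (1 -> 3).  The baseline cell is the
standard calibrated parameter set.

Long-term runs (10,000 yr) characterize the attractors: final state =
mean cover over the last 20% of the run, classified as oak forest, open
shrubland or mixed.  Short-term runs (100 yr x 100 replicates) give the
probabilistic, management-scale picture: distributions of oak and
shrub+grass cover averaged over years 80-100 and threshold probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .params import NAMES, PlantTypeSet
from .fire import SeedBankRules
from .simulate import ABANDONED_FIELD, FireLog, RunConfig, Trajectory, integrate

#: default scenario grids; the endpoints are the published aridity ranges,
#: the interior values 0.023/0.035 and 1.2/1.5 are those of the published
#: bistable and short-term example scenarios
R1_GRID = (0.9, 0.75, 0.6)
C1_GRID = (0.047, 0.035, 0.023, 0.011)
FLAM_GRID = (1.0, 1.2, 1.5, 3.0)

#: named initial communities (stand-ins where the study tables are
#: supplementary-only; `mixed` is the printed 15%-per-type community)
INITIAL_COMMUNITIES: dict[str, tuple] = {
    "forest": (0.9, 0.0, 0.0, 0.0, 0.0, 0.05),
    "shrubland": (0.01, 0.0, 0.1, 0.1, 0.2, 0.2),
    "mixed": (0.15, 0.15, 0.15, 0.15, 0.15, 0.15),
    "abandoned_field": ABANDONED_FIELD,
    "oak_seedlings": (0.05, 0.0, 0.0, 0.0, 0.0, 0.0),
    "pine_stand": (0.01, 0.5, 0.05, 0.05, 0.05, 0.05),
}

#: 0-based indices of the shrub + grass group (R, U, C, B)
SHRUB_GRASS_IDX = (2, 3, 4, 5)

#: oak-dominance threshold used throughout
DOMINANCE_THRESHOLD = 0.5


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the aridity factorial."""

    r1: float = 0.9
    c1: float = 0.047
    flam_mult: float = 1.0
    c_override: tuple | None = None

    def apply(self, base: PlantTypeSet) -> PlantTypeSet:
        return base.with_scenario(r1=self.r1, c1=self.c1,
                                  flam_mult=self.flam_mult,
                                  c=self.c_override)

    @property
    def label(self) -> str:
        return f"r1={self.r1:g}_c1={self.c1:g}_f={self.flam_mult:g}"


#: the bistable example cell (intermediate aridity)
BISTABLE_SCENARIO = ScenarioSpec(r1=0.6, c1=0.023, flam_mult=1.2)


def scenario_grid(base: PlantTypeSet | None = None,
                  r1_values: Sequence[float] = R1_GRID,
                  c1_values: Sequence[float] = C1_GRID,
                  flam_values: Sequence[float] = FLAM_GRID) -> list[ScenarioSpec]:
    """Full factorial of aridity scenarios (default 3 x 4 x 4 = 48 cells).

    The first cell is the baseline (historical climate).  ``base`` is
    accepted for interface symmetry; the grid itself is parameter-free.
    """
    return [ScenarioSpec(r1=r1, c1=c1, flam_mult=f)
            for r1 in r1_values for c1 in c1_values for f in flam_values]


@dataclass
class RunSummary:
    """End-of-run summary statistics of one realization."""

    final_cover: np.ndarray          # mean cover, last 20% of run
    mean_fire_interval: float        # over the stats window (nan if no fires)
    n_fires: int                     # fires inside the stats window
    time_to_dominance: float | None  # first t with oak cover > 0.5
    state: str                       # forest | open shrubland | mixed

    @property
    def oak(self) -> float:
        return float(self.final_cover[0])


def classify_state(final_cover: np.ndarray | RunSummary,
                   forest_threshold: float = DOMINANCE_THRESHOLD,
                   absence_threshold: float = 0.05) -> str:
    """Label a final cover vector: forest / open shrubland / mixed.

    Forest: oak above 0.5.  Open shrubland: oak essentially absent
    (< 0.05) while shrubs+grass persist (> 0.05).  Anything else is mixed.
    """
    if isinstance(final_cover, RunSummary):
        final_cover = final_cover.final_cover
    final_cover = np.asarray(final_cover, dtype=float)
    oak = final_cover[0]
    shrub_grass = final_cover[list(SHRUB_GRASS_IDX)].sum()
    if oak > forest_threshold:
        return "forest"
    if oak < absence_threshold and shrub_grass > absence_threshold:
        return "open shrubland"
    return "mixed"


def fire_interval_stats(log: FireLog, window: tuple[float, float]
                        ) -> tuple[float, int]:
    """Mean and count of fire return intervals with event time in window."""
    t0, t1 = window
    sel = (log.times >= t0) & (log.times <= t1)
    n = int(sel.sum())
    mean = float(log.intervals[sel].mean()) if n else float("nan")
    return mean, n


def summarize_run(traj: Trajectory, log: FireLog,
                  stats_window: tuple[float, float] | None = None,
                  final_fraction: float = 0.2) -> RunSummary:
    """Condense one run into a :class:`RunSummary`."""
    t_end = float(traj.times[-1])
    if stats_window is None:
        stats_window = ((1 - final_fraction) * t_end, t_end)
    final = traj.final_cover(final_fraction)
    mean_int, n = fire_interval_stats(log, stats_window)
    ttd = traj.first_crossing("Q", DOMINANCE_THRESHOLD)
    return RunSummary(final_cover=final, mean_fire_interval=mean_int,
                      n_fires=n, time_to_dominance=ttd,
                      state=classify_state(final))


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


def run_long_term(scenarios: Iterable[ScenarioSpec],
                  initial_conditions: Mapping[str, Sequence[float]] | None = None,
                  n_replicates: int = 1,
                  duration: float = 10_000.0,
                  dt: float = 1 / 365,
                  seed: int = 0,
                  base: PlantTypeSet | None = None,
                  rules: SeedBankRules | None = None,
                  n_random_initial: int = 0,
                  fires: bool = True) -> pd.DataFrame:
    """Long-term factorial: one row per scenario x initial condition x rep.

    ``n_random_initial`` additionally draws that many random initial cover
    vectors (uniform on the simplex, total cover <= 1) per scenario — the
    scaled-down Monte-Carlo over initial conditions.

    Returns a DataFrame with the scenario knobs, the initial-condition
    label, final covers, classified state, fire-interval statistics over
    the last 20% of the run and time to oak dominance.
    """
    base = base or PlantTypeSet()
    rules = rules or SeedBankRules()
    if initial_conditions is None:
        initial_conditions = INITIAL_COMMUNITIES
    scenarios = list(scenarios)

    rows = []
    master_rng = np.random.default_rng(seed)
    for i_s, scen in enumerate(scenarios):
        params = scen.apply(base)
        ics: list[tuple[str, np.ndarray]] = [
            (name, np.asarray(b0, dtype=float))
            for name, b0 in initial_conditions.items()]
        for k in range(n_random_initial):
            raw = master_rng.dirichlet(np.ones(7))  # 7th slot = free space
            ics.append((f"random_{k}", raw[:6]))
        seeds = _spawn_seeds(seed + 1000003 * i_s, len(ics) * n_replicates)
        for i_ic, (ic_name, b0) in enumerate(ics):
            for rep in range(n_replicates):
                cfg = RunConfig(duration=duration, dt=dt, b0=tuple(b0),
                                fires=fires,
                                seed=seeds[i_ic * n_replicates + rep])
                traj, log = integrate(cfg, params, rules)
                s = summarize_run(traj, log)
                rows.append({
                    "r1": scen.r1, "c1": scen.c1, "flam_mult": scen.flam_mult,
                    "initial": ic_name, "replicate": rep,
                    **{f"final_{n}": s.final_cover[i]
                       for i, n in enumerate(NAMES)},
                    "free_space": 1.0 - s.final_cover.sum(),
                    "state": s.state,
                    "mean_fire_interval": s.mean_fire_interval,
                    "n_fires_window": s.n_fires,
                    "time_to_dominance": s.time_to_dominance,
                })
    return pd.DataFrame(rows)


def run_short_term(scenarios: Iterable[ScenarioSpec],
                   initial_communities: Mapping[str, Sequence[float]] | None = None,
                   n_runs: int = 100,
                   duration: float = 100.0,
                   dt: float = 1 / 365,
                   seed: int = 0,
                   base: PlantTypeSet | None = None,
                   rules: SeedBankRules | None = None,
                   window: tuple[float, float] = (80.0, 100.0)
                   ) -> pd.DataFrame:
    """Probabilistic short-term runs: ``n_runs`` replicates per cell.

    For each scenario x initial community, every replicate's oak cover and
    shrub+grass cover are averaged over the last-20-yr window; the returned
    frame has one row per replicate plus the per-cell threshold
    probabilities P(oak < 0.5), P(oak < 0.65) and P(oak > 0.3) repeated on
    each row for convenience.
    """
    base = base or PlantTypeSet()
    rules = rules or SeedBankRules()
    if initial_communities is None:
        initial_communities = {k: INITIAL_COMMUNITIES[k]
                               for k in ("forest", "shrubland", "mixed")}
    scenarios = list(scenarios)

    frames = []
    for i_s, scen in enumerate(scenarios):
        params = scen.apply(base)
        for i_ic, (ic_name, b0) in enumerate(initial_communities.items()):
            seeds = _spawn_seeds(seed + 7919 * i_s + 104729 * i_ic, n_runs)
            oak = np.empty(n_runs)
            shrub_grass = np.empty(n_runs)
            for rep in range(n_runs):
                cfg = RunConfig(duration=duration, dt=dt, b0=tuple(b0),
                                fires=True, seed=seeds[rep])
                traj, _ = integrate(cfg, params, rules)
                mean_cov = traj.mean_cover(*window)
                oak[rep] = mean_cov[0]
                shrub_grass[rep] = mean_cov[list(SHRUB_GRASS_IDX)].sum()
            frames.append(pd.DataFrame({
                "r1": scen.r1, "c1": scen.c1, "flam_mult": scen.flam_mult,
                "initial": ic_name, "replicate": np.arange(n_runs),
                "oak_cover": oak, "shrub_grass_cover": shrub_grass,
                "p_oak_below_050": np.mean(oak < 0.5),
                "p_oak_below_065": np.mean(oak < 0.65),
                "p_oak_above_030": np.mean(oak > 0.3),
            }))
    return pd.concat(frames, ignore_index=True)


def run_gradual_aridity(target: ScenarioSpec,
                        b0: Sequence[float],
                        duration: float = 100.0,
                        dt: float = 1 / 365,
                        seed: int = 0,
                        base: PlantTypeSet | None = None,
                        rules: SeedBankRules | None = None,
                        segment: float = 1.0) -> tuple[Trajectory, FireLog]:
    """One run in which aridity ramps linearly from baseline to ``target``.

    (r1, c1, flam_mult) are interpolated in time and held piecewise
    constant over ``segment``-yr slices; state (covers, seed banks, stand
    age) carries across slices.  Restarting the exponential fire clock at
    slice boundaries is statistically neutral (memorylessness), only the
    hazard level changes with the parameters.
    """
    base = base or PlantTypeSet()
    rules = rules or SeedBankRules()
    n_seg = int(round(duration / segment))
    seeds = _spawn_seeds(seed, n_seg)
    b = np.asarray(b0, dtype=float)
    S = None
    tau = np.inf
    traj_parts, log_parts = [], []
    baseline = ScenarioSpec()
    for k in range(n_seg):
        frac = (k + 0.5) / n_seg      # midpoint interpolation per slice
        scen = ScenarioSpec(
            r1=baseline.r1 + frac * (target.r1 - baseline.r1),
            c1=baseline.c1 + frac * (target.c1 - baseline.c1),
            flam_mult=baseline.flam_mult
            + frac * (target.flam_mult - baseline.flam_mult))
        cfg = RunConfig(duration=segment, dt=dt, b0=tuple(b),
                        S0=None if S is None else tuple(S),
                        fires=True, seed=seeds[k], tau0=tau)
        traj, log = integrate(cfg, scen.apply(base), rules)
        t_off = k * segment
        tdf = traj.df.copy()
        tdf["t"] += t_off
        ldf = log.df.copy()
        ldf["t"] += t_off
        traj_parts.append(tdf if k == 0 else tdf.iloc[1:])
        log_parts.append(ldf)
        b = traj.covers()[-1]
        S = traj.df[["S_P", "S_R", "S_U", "S_C"]].to_numpy()[-1]
        last_fires = log.times
        tau = (tau + segment) if len(last_fires) == 0 \
            else segment - float(last_fires[-1])
    full_traj = Trajectory(pd.concat(traj_parts, ignore_index=True))
    full_log = FireLog(pd.concat(log_parts, ignore_index=True))
    # recompute return intervals across slice boundaries
    if len(full_log.df):
        t = full_log.df["t"].to_numpy()
        full_log.df["interval"] = np.diff(np.concatenate(([0.0], t)))
    return full_traj, full_log
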