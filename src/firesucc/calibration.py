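"""Parameter estimation against cover observations.

The colonization rates ``c1..c5`` are fitted to old-field chronosequence
data (sites of different age since abandonment read as one successional
time series) by running the fire-free competition model and minimizing the
squared model-data deviation normalized by the per-type data variance.
The goodness of fit

    H2 = 1 - SSE_norm / N_norm

is a pooled Nash-Sutcliffe-style efficiency: 1 for a perfect fit, 0 for a
predictor no better than each type's mean.  ``C_conv``, ``r6`` and ``c6``
are fitted to experimental fire-plot series, simulating each plot's
imposed burn schedule.  The minimizer is simulated annealing (random
box-bounded proposals, Metropolis acceptance, geometric cooling); data
uncertainty is propagated by re-calibrating on site-bootstrap resamples
with added cover noise (Monte-Carlo trajectory envelopes).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fire import SeedBankRules
from .params import NAMES, PlantTypeSet
from .simulate import SMALL_MIXED, RunConfig, Trajectory, integrate

COVER_COLS = [f"cover_{n}" for n in NAMES]
OBS_COLUMNS = ["site", "kind", "time_yr", *COVER_COLS]

#: default free-parameter boxes
OLDFIELD_BOUNDS: dict[str, tuple[float, float]] = {
    f"c{i}": (0.005, 0.3) for i in range(1, 6)}
FIREPLOT_BOUNDS: dict[str, tuple[float, float]] = {
    "C_conv": (0.001, 0.1), "r6": (0.0, 1.0), "c6": (0.01, 0.5)}


# ---------------------------------------------------------------------------
# observations
# ---------------------------------------------------------------------------

@dataclass
class ObservationSet:
    """Tabular cover observations (real or synthetic).

    ``df`` columns: site, kind (old-field | fire-plot), time_yr (years
    since abandonment or since the series start), cover_Q .. cover_B.
    ``burn_schedules`` maps fire-plot site ids to imposed burn times (yr).
    ``meta`` carries provenance, e.g. generating parameters of synthetic
    data (used by recovery tests).
    """

    df: pd.DataFrame
    kind: str = "old-field"
    burn_schedules: dict = dc_field(default_factory=dict)
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in OBS_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"observation table missing columns {missing}")
        if len(self.df) == 0:
            raise ValueError("empty observation set")
        if (self.df["time_yr"] < 0).any():
            raise ValueError("times must be non-negative")
        cov = self.df[COVER_COLS].to_numpy(dtype=float)
        if (cov < 0).any() or (cov > 1).any():
            raise ValueError("covers must lie in [0, 1]")
        tot = cov.sum(axis=1)
        if (tot > 1.05).any():
            raise ValueError("record total cover exceeds 1 by more than 5%")
        over = tot > 1.0
        if over.any():  # renormalize mild violations on ingest
            cov[over] /= tot[over, None]
            self.df.loc[:, COVER_COLS] = cov

    def __len__(self) -> int:
        return len(self.df)

    def sites(self) -> list:
        return list(self.df["site"].unique())

    # -- delimited-file round trip ----------------------------------------

    def to_file(self, path: str | Path) -> None:
        lines = []
        for site, burns in self.burn_schedules.items():
            stamp = ";".join(format(t, "g") for t in burns)
            lines.append(f"# burns\t{site}\t{stamp}")
        lines.append("\t".join(OBS_COLUMNS))
        for _, row in self.df.iterrows():
            lines.append("\t".join(
                [str(row["site"]), str(row["kind"]),
                 format(row["time_yr"], ".10g")]
                + [format(row[c], ".10g") for c in COVER_COLS]))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "ObservationSet":
        burns: dict = {}
        rows = []
        header: list[str] | None = None
        for line in Path(path).read_text().splitlines():
            if line.startswith("# burns\t"):
                _, site, stamp = line.split("\t")
                burns[site] = tuple(float(x) for x in stamp.split(";") if x)
                continue
            if line.startswith("#") or not line.strip():
                continue
            if header is None:
                header = line.split("\t")
                continue
            rows.append(line.split("\t"))
        if header is None or not rows:
            raise ValueError(f"no observation records in {path}")
        df = pd.DataFrame(rows, columns=header)
        df["time_yr"] = df["time_yr"].astype(float)
        for c in COVER_COLS:
            df[c] = df[c].astype(float)
        kind = df["kind"].iloc[0]
        return cls(df=df, kind=kind, burn_schedules=burns)


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------

def _apply_free(base: PlantTypeSet, names: Sequence[str],
                values: Sequence[float]) -> PlantTypeSet:
    """Parameter set with the named free entries replaced by ``values``."""
    c = list(base.c)
    r = list(base.r)
    C_conv = base.C_conv
    for name, v in zip(names, values):
        if name.startswith("c") and name[1:].isdigit():
            c[int(name[1:]) - 1] = float(v)
        elif name.startswith("r") and name[1:].isdigit():
            r[int(name[1:]) - 1] = float(v)
        elif name == "C_conv":
            C_conv = float(v)
        else:
            raise ValueError(f"unknown free parameter {name!r}")
    from dataclasses import replace
    return replace(base, c=tuple(c), r=tuple(r), C_conv=C_conv)


def _norm_sse(obs_df: pd.DataFrame, predict: Callable[[pd.DataFrame], np.ndarray]
              ) -> tuple[float, int]:
    """Variance-normalized SSE and the number of contributing residuals."""
    cov = obs_df[COVER_COLS].to_numpy(dtype=float)
    pred = predict(obs_df)
    sse = 0.0
    n = 0
    for j in range(len(COVER_COLS)):
        var = cov[:, j].var()      # population variance of the type's data
        if var <= 0:
            continue
        sse += float(((pred[:, j] - cov[:, j]) ** 2).sum()) / var
        n += cov.shape[0]
    return sse, n


def objective(free_values: Sequence[float], free_names: Sequence[str],
              obs: ObservationSet,
              base: PlantTypeSet | None = None,
              rules: SeedBankRules | None = None,
              b0: Sequence[float] = SMALL_MIXED,
              dt: float = 1 / 52) -> float:
    """Variance-normalized squared deviation of model from observations.

    Old-field observations are compared against the fire-free competition
    model started from the abandonment covers ``b0``; fire-plot
    observations against runs with each plot's imposed burn schedule.
    Lower is better; 0 is a perfect fit.
    """
    base = base or PlantTypeSet()
    rules = rules or SeedBankRules()
    params = _apply_free(base, free_names, free_values)
    t_max = float(obs.df["time_yr"].max()) + 1.0

    if obs.kind == "old-field":
        cfg = RunConfig(duration=t_max, dt=dt, b0=tuple(b0), fires=False)
        traj, _ = integrate(cfg, params, rules)

        def predict(df):
            return traj.at(df["time_yr"].to_numpy())

        sse, _ = _norm_sse(obs.df, predict)
        return sse

    # fire-plot data: simulate each plot under its scheduled burns
    sse = 0.0
    for site, sub in obs.df.groupby("site", sort=True):
        burns = obs.burn_schedules.get(str(site), obs.burn_schedules.get(site, ()))
        dur = float(sub["time_yr"].max()) + 1.0
        cfg = RunConfig(duration=dur, dt=dt, b0=tuple(b0),
                        scheduled_fires=tuple(t for t in burns if t <= dur),
                        fires=False)
        traj, _ = integrate(cfg, params, rules)
        part, _ = _norm_sse(sub, lambda df, tr=traj: tr.at(df["time_yr"].to_numpy()))
        sse += part
    return sse


def goodness_h2(objective_value: float, obs: ObservationSet) -> float:
    """Pooled efficiency H2 = 1 - SSE_norm / N_norm (<= 1; 0 = mean model)."""
    cov = obs.df[COVER_COLS].to_numpy(dtype=float)
    n = sum(cov.shape[0] for j in range(cov.shape[1]) if cov[:, j].var() > 0)
    if n == 0:
        raise ValueError("observations carry no variance")
    return 1.0 - objective_value / n


# ---------------------------------------------------------------------------
# simulated annealing
# ---------------------------------------------------------------------------

@dataclass
class AnnealSchedule:
    """Cooling schedule: T_k = t0 * cooling**k over n_steps proposals.

    Each proposal perturbs one uniformly chosen coordinate by a Gaussian
    of sd ``step_frac`` times the box width, scaled down with sqrt(T/T0)
    (floored at 2% of the initial step) so the search refines as it
    cools — plain fixed-width proposals stall far from the minimum in
    more than a couple of dimensions."""

    n_steps: int = 20_000
    t0: float = 1.0
    cooling: float = 0.995
    step_frac: float = 0.05
    step_floor: float = 0.02


@dataclass
class AnnealResult:
    x: np.ndarray
    fun: float
    trace: pd.DataFrame
    n_accepted: int


def anneal(fun: Callable[[np.ndarray], float],
           bounds: Sequence[tuple[float, float]],
           seed: int = 0,
           schedule: AnnealSchedule | None = None,
           x0: Sequence[float] | None = None,
           trace_every: int = 100) -> AnnealResult:
    """Minimize ``fun`` over a box by simulated annealing.

    Standard Kirkpatrick-style annealing: Gaussian proposals clipped to
    the box, Metropolis acceptance exp(-delta/T), geometric cooling.
    Returns the best point ever visited.  Reproducible given ``seed``.
    """
    schedule = schedule or AnnealSchedule()
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    width = hi - lo
    x = (np.asarray(x0, dtype=float) if x0 is not None
         else lo + rng.uniform(size=len(bounds)) * width)
    f = float(fun(x))
    if not np.isfinite(f):
        raise ValueError("objective is not finite at the starting point")
    best_x, best_f = x.copy(), f
    T = schedule.t0
    n_acc = 0
    rows = []
    for k in range(schedule.n_steps):
        scale = max(np.sqrt(T / schedule.t0), schedule.step_floor)
        j = int(rng.integers(len(bounds)))
        prop = x.copy()
        prop[j] = np.clip(
            x[j] + rng.normal(0.0, schedule.step_frac * width[j] * scale),
            lo[j], hi[j])
        fp = float(fun(prop))
        delta = fp - f
        if delta <= 0 or rng.uniform() < np.exp(-delta / max(T, 1e-300)):
            x, f = prop, fp
            n_acc += 1
            if f < best_f:
                best_x, best_f = x.copy(), f
        if k % trace_every == 0:
            rows.append({"step": k, "T": T, "f": f, "best": best_f})
        T *= schedule.cooling
    rows.append({"step": schedule.n_steps, "T": T, "f": f, "best": best_f})
    return AnnealResult(x=best_x, fun=best_f,
                        trace=pd.DataFrame(rows), n_accepted=n_acc)


# ---------------------------------------------------------------------------
# calibration facade (Model / Results shape)
# ---------------------------------------------------------------------------

class OldFieldCalibration:
    """Fit colonization rates to old-field chronosequence data.

    Parameters
    ----------
    obs : ObservationSet (kind "old-field", or "fire-plot" with
        ``free``/``bounds`` overridden accordingly)
    free : names of the free parameters (default c1..c5)
    bounds : box bounds per free parameter
    base : fixed remainder of the parameter set
    b0 : assumed covers at abandonment
    dt : integration step used inside the objective (yr)
    """

    def __init__(self, obs: ObservationSet,
                 free: Sequence[str] = ("c1", "c2", "c3", "c4", "c5"),
                 bounds: Mapping[str, tuple[float, float]] | None = None,
                 base: PlantTypeSet | None = None,
                 rules: SeedBankRules | None = None,
                 b0: Sequence[float] = SMALL_MIXED,
                 dt: float = 1 / 52):
        self.obs = obs
        self.free = tuple(free)
        defaults = {**OLDFIELD_BOUNDS, **FIREPLOT_BOUNDS, **(bounds or {})}
        self.bounds = [defaults[n] for n in self.free]
        self.base = base or PlantTypeSet()
        self.rules = rules or SeedBankRules()
        self.b0 = tuple(b0)
        self.dt = dt

    def _objective(self, x: np.ndarray) -> float:
        return objective(x, self.free, self.obs, self.base, self.rules,
                         self.b0, self.dt)

    def fit(self, seed: int = 0, schedule: AnnealSchedule | None = None
            ) -> "CalibrationResults":
        res = anneal(self._objective, self.bounds, seed=seed,
                     schedule=schedule)
        params = _apply_free(self.base, self.free, res.x)
        h2 = goodness_h2(res.fun, self.obs)
        return CalibrationResults(self, params, res, h2)


class FirePlotCalibration(OldFieldCalibration):
    """Fit (C_conv, r6, c6) to experimental fire-plot series."""

    def __init__(self, obs: ObservationSet, base: PlantTypeSet | None = None,
                 rules: SeedBankRules | None = None,
                 b0: Sequence[float] = SMALL_MIXED, dt: float = 1 / 52):
        super().__init__(obs, free=("C_conv", "r6", "c6"), base=base,
                         rules=rules, b0=b0, dt=dt)


class CalibrationResults:
    """Fitted parameters, objective value, H2 and the optimizer trace."""

    def __init__(self, calibration: OldFieldCalibration, params: PlantTypeSet,
                 anneal_result: AnnealResult, h2: float):
        self.calibration = calibration
        self.params = params
        self.anneal_result = anneal_result
        self.h2 = h2

    @property
    def theta(self) -> dict[str, float]:
        return dict(zip(self.calibration.free, self.anneal_result.x))

    @property
    def objective_value(self) -> float:
        return self.anneal_result.fun

    def trajectory(self, duration: float | None = None) -> Trajectory:
        """Fire-free model trajectory under the fitted parameters."""
        dur = duration or float(self.calibration.obs.df["time_yr"].max()) + 1
        cfg = RunConfig(duration=dur, dt=self.calibration.dt,
                        b0=self.calibration.b0, fires=False)
        traj, _ = integrate(cfg, self.params, self.calibration.rules)
        return traj

    def summary(self) -> str:
        lines = [
            "Old-field / fire-plot calibration (simulated annealing)",
            "=======================================================",
            f"observations: {len(self.calibration.obs)} records, "
            f"{len(self.calibration.obs.sites())} sites "
            f"({self.calibration.obs.kind})",
            f"objective (variance-normalized SSE): "
            f"{self.objective_value:.4f}",
            f"goodness of fit H2: {self.h2:.3f}",
            "",
            "parameter   estimate",
        ]
        for name, v in self.theta.items():
            lines.append(f"  {name:<8}  {v:.5f}")
        lines.append(f"accepted moves: {self.anneal_result.n_accepted}")
        return "\n".join(lines)


def mc_uncertainty(obs: ObservationSet, n_draws: int, seed: int = 0,
                   calibration: OldFieldCalibration | None = None,
                   schedule: AnnealSchedule | None = None,
                   noise_sigma: float = 0.05,
                   times: np.ndarray | None = None) -> dict:
    """Monte-Carlo calibration envelope under data uncertainty.

    Repeats the calibration on ``n_draws`` site-level bootstrap resamples
    with additive truncated-Gaussian cover noise (sd ``noise_sigma``,
    clipped to [0, 1] and renormalized), and returns the pointwise min/max
    envelope of the fitted fire-free trajectories.

    Returns a dict with keys ``times`` (T,), ``lo``/``hi`` (T, 6),
    ``best`` (T, 6) and ``thetas`` (n_draws, n_free).
    """
    if n_draws < 2:
        raise ValueError("n_draws must be at least 2")
    calibration = calibration or OldFieldCalibration(obs)
    rng = np.random.default_rng(seed)
    if times is None:
        times = np.arange(0.0, float(obs.df["time_yr"].max()) + 1.0)

    best = calibration.fit(seed=int(rng.integers(2**31)),
                           schedule=schedule)
    best_traj = best.trajectory(duration=float(times[-1]) + 1).at(times)

    trajs = []
    thetas = []
    sites = obs.sites()
    for _ in range(n_draws):
        chosen = rng.choice(sites, size=len(sites), replace=True)
        parts = []
        for k, s in enumerate(chosen):
            sub = obs.df[obs.df["site"] == s].copy()
            sub["site"] = f"bs{k}"
            parts.append(sub)
        bdf = pd.concat(parts, ignore_index=True)
        cov = bdf[COVER_COLS].to_numpy(dtype=float)
        if noise_sigma > 0:
            cov = np.clip(cov + rng.normal(0, noise_sigma, cov.shape), 0, 1)
            tot = cov.sum(axis=1)
            over = tot > 1
            cov[over] /= tot[over, None]
        bdf.loc[:, COVER_COLS] = cov
        bobs = ObservationSet(df=bdf, kind=obs.kind,
                              burn_schedules=obs.burn_schedules)
        cal = OldFieldCalibration(
            bobs, free=calibration.free,
            bounds=dict(zip(calibration.free, calibration.bounds)),
            base=calibration.base, rules=calibration.rules,
            b0=calibration.b0, dt=calibration.dt)
        fitres = cal.fit(seed=int(rng.integers(2**31)), schedule=schedule)
        thetas.append(fitres.anneal_result.x)
        trajs.append(fitres.trajectory(duration=float(times[-1]) + 1).at(times))

    stack = np.stack([best_traj] + trajs)   # envelope always contains best fit
    return {"times": times, "lo": stack.min(axis=0), "hi": stack.max(axis=0),
            "best": best_traj, "thetas": np.stack(thetas)}
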