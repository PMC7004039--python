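"""Configuration loading, result writing and run manifests.

Config files are JSON or YAML mappings of the sections below; every key
is optional and defaults to the standard parameter set and the study's
experiment settings.  Unknown keys are rejected with a field-level
message so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .calibration import AnnealSchedule
from .experiments import C1_GRID, FLAM_GRID, R1_GRID
from .fire import SeedBankRules
from .params import PlantTypeSet
from .simulate import ABANDONED_FIELD, SMALL_MIXED

_SCHEMA: dict[str, tuple[str, ...]] = {
    "params": ("c", "m", "r", "l", "gamma", "C_conv", "epsilon", "flam_mult"),
    "rules": ("pine_maturity_age", "pine_seed_viability",
              "shrub_production_rate", "shrub_decay_rate"),
    "run": ("duration", "dt", "seed", "b0", "S0", "fires", "tau0",
            "sample_every", "replicates"),
    "scenario": ("r1", "c1", "flam_mult"),
    "grid": ("r1_values", "c1_values", "flam_values"),
    "calibration": ("n_steps", "t0", "cooling", "step_frac", "dt", "b0",
                    "noise_sigma", "n_draws"),
    "synthetic": ("n_sites", "age_range", "noise_sigma", "seed", "dt",
                  "n_fireplots", "burn_schedules", "sampling_times"),
}


@dataclass
class Config:
    """Validated full configuration with defaults filled in."""

    params: PlantTypeSet
    rules: SeedBankRules
    run: dict
    scenario: dict
    grid: dict
    calibration: dict
    synthetic: dict
    raw: dict = field(default_factory=dict)

    def anneal_schedule(self) -> AnnealSchedule:
        c = self.calibration
        return AnnealSchedule(n_steps=int(c["n_steps"]), t0=c["t0"],
                              cooling=c["cooling"], step_frac=c["step_frac"])


def _check_keys(section: str, mapping: Mapping[str, Any]) -> None:
    allowed = _SCHEMA[section]
    for key in mapping:
        if key not in allowed:
            raise ValueError(
                f"unknown key {section}.{key!r}; allowed: {sorted(allowed)}")


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None) -> Config:
    """Read and validate a JSON/YAML config file (or just the defaults).

    ``overrides`` (same nested structure) take precedence over the file.
    Raises ``ValueError`` naming the offending field on schema violations.
    """
    data: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text) or {}
    for section, values in (overrides or {}).items():
        data.setdefault(section, {}).update(values)

    for section in data:
        if section not in _SCHEMA:
            raise ValueError(
                f"unknown config section {section!r}; "
                f"allowed: {sorted(_SCHEMA)}")
        if not isinstance(data[section], Mapping):
            raise ValueError(f"config section {section!r} must be a mapping")
        _check_keys(section, data[section])

    params = PlantTypeSet(**data.get("params", {}))
    rules = SeedBankRules(**data.get("rules", {}))

    scenario = {"r1": params.r[0], "c1": params.c[0],
                "flam_mult": params.flam_mult, **data.get("scenario", {})}
    if not (0 <= scenario["r1"] <= 1):
        raise ValueError(f"scenario.r1 = {scenario['r1']} out of [0, 1]")
    if scenario["c1"] <= 0:
        raise ValueError("scenario.c1 must be positive")
    if scenario["flam_mult"] < 0:
        raise ValueError("scenario.flam_mult must be non-negative")

    run = {"duration": 10_000.0, "dt": 1 / 365, "seed": 0,
           "b0": ABANDONED_FIELD, "S0": None, "fires": True,
           "tau0": float("inf"), "sample_every": 1.0, "replicates": 1,
           **data.get("run", {})}
    grid = {"r1_values": list(R1_GRID), "c1_values": list(C1_GRID),
            "flam_values": list(FLAM_GRID), **data.get("grid", {})}
    calibration = {"n_steps": 20_000, "t0": 1.0, "cooling": 0.995,
                   "step_frac": 0.05, "dt": 1 / 52, "b0": SMALL_MIXED,
                   "noise_sigma": 0.05, "n_draws": 20,
                   **data.get("calibration", {})}
    synthetic = {"n_sites": 73, "age_range": (1.0, 100.0),
                 "noise_sigma": 0.05, "seed": 0,
                 **data.get("synthetic", {})}

    return Config(params=params, rules=rules, run=run, scenario=scenario,
                  grid=grid, calibration=calibration, synthetic=synthetic,
                  raw=data)


@dataclass
class RunManifest:
    """Provenance record written next to every output set."""

    command: str
    seed: int
    config_snapshot: dict
    outputs: list[str] = field(default_factory=list)
    package_version: str = __version__
    timestamp: str = field(
        default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def write(self, outdir: str | Path) -> Path:
        path = Path(outdir) / "manifest.json"
        path.write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")
        return path


def write_results(tables: Mapping[str, pd.DataFrame], manifest: RunManifest,
                  outdir: str | Path) -> list[Path]:
    """Write each table as CSV (deterministic column order, 6 significant
    digits) plus the manifest; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.6g")
        manifest.outputs.append(p.name)
        paths.append(p)
    paths.append(manifest.write(outdir))
    return paths


def read_table(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for tables written by :func:`write_results`."""
    return pd.read_csv(path)
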