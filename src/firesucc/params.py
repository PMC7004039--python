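"""Plant-type parameter sets and ecosystem state containers.

Six plant types of Western Mediterranean old-field succession, indexed in
competitive (inverse successional) order:

=====  =========================  ========  ===========
index  type                       acronym   fire strategy
=====  =========================  ========  ===========
1      *Quercus* spp. (oak)       Q         resprouter
2      *Pinus halepensis*         P         seeder
3      *Rosmarinus officinalis*   R         seeder
4      *Ulex parviflorus*         U         seeder
5      *Cistus* spp.              C         seeder
6      *Brachypodium retusum*     B         resprouter
=====  =========================  ========  ===========

Index order *is* the competition hierarchy: type 1 outcompetes everything
below it.  Cover fractions ``b_1..b_6`` live on the simplex
``b_i >= 0, sum(b) <= 1``; the remainder is unoccupied space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

N_TYPES = 6
NAMES = ("Q", "P", "R", "U", "C", "B")
STRATEGIES = ("resprouter", "seeder", "seeder", "seeder", "seeder", "resprouter")
#: indices (0-based) of the four seeder types P, R, U, C
SEEDER_IDX = (1, 2, 3, 4)

# Standard (calibrated) parameter set.
_C_DEFAULT = (0.047, 0.053, 0.045, 0.067, 0.11, 0.22)
_M_DEFAULT = (1 / 400, 1 / 125, 1 / 50, 1 / 25, 1 / 15, 1 / 40)
_R_DEFAULT = (0.9, 0.0, 0.0, 0.0, 0.0, 0.4)
_L_DEFAULT = (1 / 400, 1 / 20, 1 / 15, 1 / 10, 1 / 10, 1 / 10)
_GAMMA_DEFAULT = (0.0, 0.040, 0.0016, 0.0029, 0.00078, 0.0)


@dataclass(frozen=True)
class PlantTypeSet:
    """The six plant types with per-type rates and the global constants.

    Parameters
    ----------
    c : array_like of float
        Colonization rates (1/yr): fraction of the space available to type
        *i* that its standing population occupies per capita per year.
    m : array_like of float
        Mortality rates (1/yr), inverse life spans.
    r : array_like of float
        Fraction of cover retained through a fire (resprouting); seeders
        have ``r = 0``.
    l : array_like of float
        Flammabilities (1/yr): per-type contribution to the fire hazard.
        ``1 / l_i`` is the mean fire return time under a type-*i* monoculture.
    gamma : array_like of float
        Post-fire germination/establishment fractions; meaningful only for
        seeders (resprouters carry 0).
    C_conv : float
        Conversion parameter (1/yr) scaling total post-fire seeder
        establishment.
    epsilon : float
        Baseline fire hazard (1/yr) on bare ground.
    flam_mult : float
        Scalar multiplier on all flammabilities (aridity scenarios).
    """

    c: tuple = _C_DEFAULT
    m: tuple = _M_DEFAULT
    r: tuple = _R_DEFAULT
    l: tuple = _L_DEFAULT
    gamma: tuple = _GAMMA_DEFAULT
    C_conv: float = 0.014
    epsilon: float = 1e-4
    flam_mult: float = 1.0
    names: tuple = NAMES
    strategy: tuple = STRATEGIES

    def __post_init__(self):
        for attr in ("c", "m", "r", "l", "gamma"):
            vec = tuple(float(x) for x in getattr(self, attr))
            if len(vec) != N_TYPES:
                raise ValueError(f"{attr} must have length {N_TYPES}, got {len(vec)}")
            if any(x < 0 for x in vec):
                raise ValueError(f"{attr} must be non-negative, got {vec}")
            object.__setattr__(self, attr, vec)
        if any(x > 1 for x in self.r):
            raise ValueError(f"r must lie in [0, 1], got {self.r}")
        if self.C_conv < 0 or self.epsilon < 0 or self.flam_mult < 0:
            raise ValueError("C_conv, epsilon and flam_mult must be non-negative")

    # -- convenience -------------------------------------------------------

    def as_arrays(self) -> dict:
        """Rate vectors as float64 numpy arrays (keys c, m, r, l, gamma)."""
        return {a: np.asarray(getattr(self, a), dtype=float)
                for a in ("c", "m", "r", "l", "gamma")}

    def with_scenario(self, r1: float | None = None, c1: float | None = None,
                      flam_mult: float | None = None,
                      c: tuple | None = None) -> "PlantTypeSet":
        """Return a copy with aridity-scenario overrides applied."""
        kw = {}
        if c is not None:
            kw["c"] = tuple(c)
        if c1 is not None:
            base = kw.get("c", self.c)
            kw["c"] = (float(c1),) + tuple(base[1:])
        if r1 is not None:
            kw["r"] = (float(r1),) + tuple(self.r[1:])
        if flam_mult is not None:
            kw["flam_mult"] = float(flam_mult)
        return replace(self, **kw)

    # -- table I/O ---------------------------------------------------------

    def to_table(self, path: str | Path) -> None:
        """Write the per-type parameters as a tab-separated table."""
        lines = ["type\tstrategy\tc\tm\tr\tl\tgamma"]
        for i in range(N_TYPES):
            lines.append("\t".join([
                self.names[i], self.strategy[i],
                *(format(v, ".17g") for v in
                  (self.c[i], self.m[i], self.r[i], self.l[i], self.gamma[i])),
            ]))
        lines.append(f"# C_conv\t{self.C_conv:.17g}")
        lines.append(f"# epsilon\t{self.epsilon:.17g}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_table(cls, path: str | Path) -> "PlantTypeSet":
        """Read a parameter table written by :meth:`to_table`."""
        rows, consts = [], {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("type\t"):
                continue
            if line.startswith("#"):
                key, val = line.lstrip("# ").split("\t")
                consts[key] = float(val)
                continue
            rows.append(line.split("\t"))
        if len(rows) != N_TYPES:
            raise ValueError(f"expected {N_TYPES} plant-type rows, got {len(rows)}")
        cols = list(zip(*rows))
        return cls(
            names=tuple(cols[0]), strategy=tuple(cols[1]),
            c=tuple(map(float, cols[2])), m=tuple(map(float, cols[3])),
            r=tuple(map(float, cols[4])), l=tuple(map(float, cols[5])),
            gamma=tuple(map(float, cols[6])),
            C_conv=consts.get("C_conv", 0.014),
            epsilon=consts.get("epsilon", 1e-4),
        )

    @classmethod
    def default(cls) -> "PlantTypeSet":
        """The standard calibrated parameter set (packaged table)."""
        with resources.as_file(
            resources.files("firesucc.data") / "plant_types.tsv"
        ) as p:
            return cls.from_table(p)


#: sentinel stand age for "never burned"
NEVER_BURNED = math.inf


@dataclass
class EcosystemState:
    """Instantaneous model state.

    Attributes
    ----------
    b : ndarray, shape (6,)
        Cover fractions of the six types.
    S : ndarray, shape (4,)
        Seed-bank levels of the seeders (P, R, U, C), arbitrary seed-mass
        units; only their ratios matter for post-fire establishment.
    tau_fire : float
        Time since the last fire (yr); ``inf`` if never burned.
    t : float
        Absolute time (yr).
    """

    b: np.ndarray
    S: np.ndarray = field(default_factory=lambda: np.zeros(4))
    tau_fire: float = NEVER_BURNED
    t: float = 0.0

    def __post_init__(self):
        self.b = np.asarray(self.b, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        validate_cover(self.b)
        if self.S.shape != (4,):
            raise ValueError("S must have shape (4,)")
        if np.any(self.S < 0):
            raise ValueError("seed banks must be non-negative")

    def copy(self) -> "EcosystemState":
        return EcosystemState(self.b.copy(), self.S.copy(), self.tau_fire, self.t)


def validate_cover(b: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Check a cover vector against the simplex invariants.

    Raises ``ValueError`` on wrong dimension, covers below ``-tol`` or total
    cover above ``1 + tol``.  Returns the vector as float64.
    """
    b = np.asarray(b, dtype=float)
    if b.shape != (N_TYPES,):
        raise ValueError(f"cover vector must have shape ({N_TYPES},), got {b.shape}")
    if np.any(b < -tol):
        raise ValueError(f"negative cover beyond tolerance: {b}")
    if b.sum() > 1 + tol:
        raise ValueError(f"total cover {b.sum():.6f} exceeds 1")
    return b
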