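"""Domain types, unit conversion, and error metrics.

The quantities handled throughout the package are isothermal (298.2 K,
0.1 MPa) mole-fraction solubilities ``x`` of a solute in a binary solvent
made of an alcohol (methanol or ethanol) and ethyl acetate.  Compositions
are always given on the solute-free basis: ``x2`` is the mole fraction of
ethyl acetate in the solvent, and the alcohol fraction is ``x1 = 1 - x2``.

Three error metrics used by every model in the package live here:

* ``ard`` — absolute relative deviation in percent, ``|x - x_ref|/|x_ref|*100``;
* ``rmsd_log`` — root-mean-square deviation of solubility residuals, by
  default on the natural-log scale (solubility errors are multiplicative,
  and all model fitting in this package is done on ``ln x``);
* ``r_squared`` — ordinary coefficient of determination on whatever scale
  the caller supplies (the cosolvency fits pass ``ln x``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

__all__ = [
    "SolventSpec",
    "SolubilityMeasurement",
    "BinarySolubilityProfile",
    "WATER",
    "METHANOL",
    "ETHANOL",
    "ETHYL_ACETATE",
    "BUILTIN_SOLVENTS",
    "mole_fraction_to_molarity",
    "ard",
    "rmsd_log",
    "r_squared",
]

#: Reference temperature and pressure of the whole study.
T_REF_K = 298.2
P_REF_KPA = 100.0


@dataclass(frozen=True)
class SolventSpec:
    """A pure solvent: name, molar mass (g/mol) and density at 298.15 K (g/cm3)."""

    name: str
    molar_mass: float
    density_298K: float

    def __post_init__(self) -> None:
        if not self.name:
            raise DomainError("solvent name must be non-empty")
        if not (self.molar_mass > 0):
            raise DomainError(f"molar_mass must be > 0, got {self.molar_mass}")
        if not (self.density_298K > 0):
            raise DomainError(f"density_298K must be > 0, got {self.density_298K}")


# 298.15 K densities (g/cm3) are bundled implementation constants; the
# conversion function accepts a user-supplied density for sensitivity checks.
WATER = SolventSpec("water", 18.015, 0.99705)
METHANOL = SolventSpec("methanol", 32.04, 0.7866)
ETHANOL = SolventSpec("ethanol", 46.07, 0.7849)
ETHYL_ACETATE = SolventSpec("ethyl acetate", 88.11, 0.894)

BUILTIN_SOLVENTS: dict[str, SolventSpec] = {
    s.name: s for s in (WATER, METHANOL, ETHANOL, ETHYL_ACETATE)
}


@dataclass(frozen=True)
class SolubilityMeasurement:
    """One equilibrium solubility point in a (binary) solvent.

    ``x2_ethyl_acetate`` is the solute-free ester mole fraction of the
    solvent mixture; ``x`` is the mole-fraction solubility of the solute.
    """

    solute: str
    x2_ethyl_acetate: float
    x: float
    temperature: float = T_REF_K
    pressure: float = P_REF_KPA

    def __post_init__(self) -> None:
        if not (0.0 <= self.x2_ethyl_acetate <= 1.0):
            raise DomainError(
                f"x2_ethyl_acetate must be in [0, 1], got {self.x2_ethyl_acetate}"
            )
        if not (0.0 < self.x < 1.0):
            raise DomainError(f"mole-fraction solubility must be in (0, 1), got {self.x}")
        if not (self.temperature > 0 and self.pressure > 0):
            raise DomainError("temperature and pressure must be positive")

    @property
    def x1_alcohol(self) -> float:
        return 1.0 - self.x2_ethyl_acetate


@dataclass(frozen=True)
class BinarySolubilityProfile:
    """A solubility curve of one solute across an alcohol + ethyl acetate mixture.

    ``x1_pure`` / ``x2_pure`` are the solubilities in pure alcohol and pure
    ester; when the measured points include the endpoint compositions they
    must agree with these stored values.
    """

    solute: str
    alcohol: SolventSpec
    ester: SolventSpec
    points: tuple[SolubilityMeasurement, ...]
    x1_pure: float
    x2_pure: float
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.x1_pure < 1.0 and 0.0 < self.x2_pure < 1.0):
            raise DomainError("pure-solvent solubilities must be in (0, 1)")
        object.__setattr__(self, "points", tuple(self.points))
        comps = [p.x2_ethyl_acetate for p in self.points]
        if any(b <= a for a, b in zip(comps, comps[1:])):
            raise DomainError(
                "profile points must be strictly sorted by x2_ethyl_acetate "
                "with no duplicate compositions"
            )
        for p in self.points:
            if p.x2_ethyl_acetate == 0.0 and not math.isclose(
                p.x, self.x1_pure, rel_tol=1e-9
            ):
                raise DomainError(
                    f"point at x2=0 ({p.x}) disagrees with x1_pure ({self.x1_pure})"
                )
            if p.x2_ethyl_acetate == 1.0 and not math.isclose(
                p.x, self.x2_pure, rel_tol=1e-9
            ):
                raise DomainError(
                    f"point at x2=1 ({p.x}) disagrees with x2_pure ({self.x2_pure})"
                )

    @property
    def x2_grid(self) -> np.ndarray:
        return np.array([p.x2_ethyl_acetate for p in self.points])

    @property
    def x_values(self) -> np.ndarray:
        return np.array([p.x for p in self.points])

    @classmethod
    def from_arrays(
        cls,
        solute: str,
        alcohol: SolventSpec,
        ester: SolventSpec,
        x2: np.ndarray,
        x: np.ndarray,
        x1_pure: float | None = None,
        x2_pure: float | None = None,
        **meta,
    ) -> "BinarySolubilityProfile":
        """Build a profile from parallel composition/solubility arrays.

        Pure-solvent values default to the measured endpoints, which must
        then be present in the arrays.
        """
        x2 = np.asarray(x2, dtype=float)
        x = np.asarray(x, dtype=float)
        if x2.shape != x.shape:
            raise DomainError("x2 and x must have the same length")
        order = np.argsort(x2)
        x2, x = x2[order], x[order]
        if x1_pure is None:
            if x2[0] != 0.0:
                raise DomainError("x1_pure not given and no point at x2 = 0")
            x1_pure = float(x[0])
        if x2_pure is None:
            if x2[-1] != 1.0:
                raise DomainError("x2_pure not given and no point at x2 = 1")
            x2_pure = float(x[-1])
        pts = tuple(
            SolubilityMeasurement(solute, float(c), float(v)) for c, v in zip(x2, x)
        )
        return cls(solute, alcohol, ester, pts, x1_pure, x2_pure, dict(meta))


def mole_fraction_to_molarity(
    x: float, solvent: SolventSpec, density: float | None = None
) -> float:
    """Convert mole-fraction solubility to molarity (mol/L).

    Uses the dilute-solution approximation ``C = x * 1000 * rho / M`` with
    the solvent's 298.15 K density: the solute's contribution to the
    solution volume is neglected, so one mole of solution occupies the
    molar volume of the solvent.  ``density`` (g/cm3) overrides the bundled
    constant for sensitivity analyses.
    """
    if not (0.0 <= x < 1.0):
        raise DomainError(f"mole fraction must be in [0, 1), got {x}")
    rho = solvent.density_298K if density is None else density
    if not (rho > 0):
        raise DomainError(f"density must be > 0, got {rho}")
    return x * 1000.0 * rho / solvent.molar_mass


def ard(x: float, x_ref: float) -> float:
    """Absolute relative deviation in percent: ``|x - x_ref| / |x_ref| * 100``."""
    if x_ref == 0:
        raise DomainError("ARD undefined for x_ref = 0")
    return abs(x - x_ref) / abs(x_ref) * 100.0


def rmsd_log(observed, predicted, *, log_scale: bool = True) -> float:
    """Root-mean-square deviation between two solubility series.

    By default residuals are taken on the natural-log scale,
    ``sqrt(mean((ln x_cal - ln x)^2))``, matching the scale on which the
    cosolvency model is fitted; ``log_scale=False`` computes the raw-scale
    RMSD instead.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.size == 0 or obs.shape != pred.shape:
        raise DomainError("observed and predicted must be equal-length and non-empty")
    if log_scale:
        if np.any(obs <= 0) or np.any(pred <= 0):
            raise DomainError("log-scale RMSD requires strictly positive values")
        res = np.log(pred) - np.log(obs)
    else:
        res = pred - obs
    return float(np.sqrt(np.mean(res**2)))


def r_squared(observed, predicted) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot``.

    Operates on the values as given; callers fitting on ``ln x`` must pass
    log-transformed series.  Requires at least 3 points and a non-constant
    observed series.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 3:
        raise DomainError("need equal-length series with at least 3 points")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise DomainError("R^2 undefined for a constant observed series")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot
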