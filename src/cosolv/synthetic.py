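"""Seeded generators emulating the statistical structure of the study data,
plus loaders for the bundled reference tables.

Three generators cover the three modelling stages:

* ``simulate_binary_profile`` inverts the CNIBS/R-K model: a solubility
  curve is built from pure-solvent endpoints and Redlich-Kister constants,
  then multiplicative log-normal noise is applied to the interior points
  (solubility errors scale with magnitude, matching the log-scale fit).
  Endpoints stay noise-free: pure-solvent values enter the model as data.
* ``simulate_kat_parameters`` produces monotone composition curves for the
  solvatochromic parameters: alpha, beta and dH2 interpolate from the
  alcohol endpoint to the ester endpoint (pure ethyl acetate has alpha = 0)
  with a small, smooth, per-parameter curvature that emulates preferential
  solvation; pi* is held constant, as observed for these mixtures.
* ``simulate_partition_dataset`` inverts the Abraham LFER: log10 partitions
  are the model value plus additive Gaussian noise.

All generators take an integer seed and are bit-reproducible.

``load_reference_table`` returns the transcribed in-study tables
(pure-solvent solubilities, literature comparison values, fitted CNIBS
constants, reported KAT fits, water solubilities, solvent constants) as
validated DataFrames; solubility columns printed in the 1e-5 display
convention are rescaled to plain mole fractions on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .abraham import PartitionObservation, SoluteDescriptors, SolventLFERCoefficients
from .core import (
    BinarySolubilityProfile,
    ETHANOL,
    ETHYL_ACETATE,
    SolventSpec,
)
from .cosolvency import cnibs_predict
from .errors import DomainError, FixtureLookupError
from .kat import KATParameters

__all__ = [
    "ProfileSimSpec",
    "KAT_METHANOL",
    "KAT_ETHANOL",
    "KAT_ETHYL_ACETATE",
    "DEFAULT_CURVATURE",
    "simulate_binary_profile",
    "simulate_kat_parameters",
    "simulate_partition_dataset",
    "load_reference_table",
    "reference_profile",
]

#: Default composition grid of the measurements: 0.0, 0.1, ..., 1.0.
DEFAULT_GRID = tuple(np.round(np.linspace(0.0, 1.0, 11), 10))

#: Default interior log-noise (standard deviation of ln x), a realistic
#: repeatability for UV-quantified equilibrium solubility.
DEFAULT_NOISE_SIGMA = 0.03


@dataclass(frozen=True)
class ProfileSimSpec:
    """Specification of one simulated binary solubility profile."""

    x1_pure: float
    x2_pure: float
    s_coeffs: tuple[float, ...]
    grid: tuple[float, ...] = DEFAULT_GRID
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    seed: int = 0
    solute: str = "synthetic solute"

    def __post_init__(self) -> None:
        if not (0.0 < self.x1_pure < 1.0 and 0.0 < self.x2_pure < 1.0):
            raise DomainError("endpoints must be in (0, 1)")
        if self.noise_sigma < 0:
            raise DomainError("noise_sigma must be >= 0")
        if len(self.s_coeffs) not in (1, 2, 3, 4):
            raise DomainError("s_coeffs must have 1..4 entries (order 0..3)")
        g = np.asarray(self.grid, dtype=float)
        if np.any((g < 0) | (g > 1)) or np.any(np.diff(g) <= 0):
            raise DomainError("grid must be sorted within [0, 1] without duplicates")


def simulate_binary_profile(
    spec: ProfileSimSpec,
    alcohol: SolventSpec = ETHANOL,
    ester: SolventSpec = ETHYL_ACETATE,
) -> BinarySolubilityProfile:
    """Generate a solubility profile from the CNIBS/R-K model plus log noise.

    With ``noise_sigma = 0`` the curve is the exact model; interior points
    otherwise get a multiplicative factor ``exp(eps)``,
    ``eps ~ N(0, noise_sigma^2)``, drawn from ``default_rng(seed)``.
    """
    rng = np.random.default_rng(spec.seed)
    grid = np.asarray(spec.grid, dtype=float)
    x = cnibs_predict(grid, spec.s_coeffs, spec.x1_pure, spec.x2_pure)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    # pure-solvent values are data, not model output: keep them bit-exact
    x[grid == 0.0] = spec.x1_pure
    x[grid == 1.0] = spec.x2_pure
    interior = (grid > 0) & (grid < 1)
    eps = rng.normal(0.0, spec.noise_sigma, size=int(interior.sum()))
    x[interior] *= np.exp(eps)
    return BinarySolubilityProfile.from_arrays(
        spec.solute,
        alcohol,
        ester,
        grid,
        x,
        x1_pure=spec.x1_pure,
        x2_pure=spec.x2_pure,
        seed=spec.seed,
        noise_sigma=spec.noise_sigma,
    )


# Pure-solvent solvatochromic endpoints (literature Kamlet-Taft scales and
# Hildebrand parameters; dH in MPa^0.5 squared to J/cm3).
KAT_METHANOL = KATParameters(0.0, alpha=0.98, beta=0.66, pi_star=0.60, deltaH2=29.6**2)
KAT_ETHANOL = KATParameters(0.0, alpha=0.86, beta=0.75, pi_star=0.54, deltaH2=26.5**2)
KAT_ETHYL_ACETATE = KATParameters(
    1.0, alpha=0.0, beta=0.45, pi_star=0.55, deltaH2=18.2**2
)

#: Default curvature (amplitude, skew) of the mixture parameter curves.
#: Amplitudes are small enough to keep every curve monotone on the default
#: endpoints; distinct skews emulate parameter-specific preferential
#: solvation so the curves are not exact linear blends of one another.
DEFAULT_CURVATURE: dict[str, tuple[float, float]] = {
    "alpha": (0.06, 0.3),
    "beta": (0.04, -0.3),
    "deltaH2": (-18.0, 0.2),
}


def _bump(x2: np.ndarray, amplitude: float, skew: float) -> np.ndarray:
    # Smooth interior bump, zero at both endpoints, unit peak height.
    return amplitude * 4.0 * x2 * (1.0 - x2) * (1.0 + skew * (2.0 * x2 - 1.0))


def simulate_kat_parameters(
    grid=DEFAULT_GRID,
    alcohol_endpoint: KATParameters = KAT_ETHANOL,
    ester_endpoint: KATParameters = KAT_ETHYL_ACETATE,
    curvature: dict[str, tuple[float, float]] | None = None,
) -> list[KATParameters]:
    """Composition curves of alpha, beta, pi*, dH2 across the binary mixture.

    alpha, beta and dH2 interpolate linearly between the endpoints plus an
    optional smooth curvature bump that vanishes at both ends (so the pure
    ester keeps alpha = 0 exactly); pi* is held constant at the endpoint
    mean.  ``curvature=None`` uses :data:`DEFAULT_CURVATURE`; pass ``{}``
    for exactly linear curves.
    """
    curv = DEFAULT_CURVATURE if curvature is None else curvature
    grid = np.asarray(grid, dtype=float)
    pi_const = 0.5 * (alcohol_endpoint.pi_star + ester_endpoint.pi_star)
    out = []
    for x2 in grid:
        values = {}
        for name in ("alpha", "beta", "deltaH2"):
            a = getattr(alcohol_endpoint, name)
            b = getattr(ester_endpoint, name)
            v = (1.0 - x2) * a + x2 * b
            if name in curv:
                amp, skew = curv[name]
                v += float(_bump(np.asarray(x2), amp, skew))
            values[name] = v
        out.append(
            KATParameters(
                x2_ethyl_acetate=float(x2),
                alpha=values["alpha"],
                beta=values["beta"],
                pi_star=pi_const,
                deltaH2=values["deltaH2"],
            )
        )
    return out


def simulate_partition_dataset(
    true_descriptors: SoluteDescriptors,
    coefficient_sets: list[SolventLFERCoefficients],
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> list[PartitionObservation]:
    """Generate log10 partitions from the Abraham model plus Gaussian noise."""
    if not coefficient_sets:
        raise DomainError("need at least one coefficient set")
    if noise_sigma < 0:
        raise DomainError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    obs = []
    for k in coefficient_sets:
        value = k.c + float(k.as_array() @ true_descriptors.as_array())
        value += rng.normal(0.0, noise_sigma) if noise_sigma > 0 else 0.0
        obs.append(
            PartitionObservation(
                solute=true_descriptors.solute or "synthetic solute",
                solvent=k.solvent or "solvent",
                log10_partition=value,
            )
        )
    return obs


def simulate_kat_response_profile(
    params: list[KATParameters],
    coefficients: dict[str, float],
    noise_sigma: float = 0.0,
    seed: int = 0,
    solute: str = "synthetic solute",
    alcohol: SolventSpec = ETHANOL,
    ester: SolventSpec = ETHYL_ACETATE,
) -> BinarySolubilityProfile:
    """Solubility profile generated from a planted KAT term model.

    ``coefficients`` maps term names (e.g. ``"beta^2"``, ``"dh2^2"``) to
    their values; the response is the linear combination of those terms at
    each composition, times multiplicative log-normal noise.  Used for
    selection-consistency experiments on the elimination procedure.
    """
    from .kat import KATModelSpec, kat_design_matrix

    spec = KATModelSpec(tuple(coefficients))
    X = kat_design_matrix(params, spec)
    beta = np.array([coefficients[t] for t in spec.included_terms])
    mu = X.to_numpy() @ beta
    if np.any(mu <= 0):
        raise DomainError("planted model must give positive solubilities")
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        mu = mu * np.exp(rng.normal(0.0, noise_sigma, size=mu.size))
    grid = np.array([p.x2_ethyl_acetate for p in params])
    return BinarySolubilityProfile.from_arrays(solute, alcohol, ester, grid, mu)


_FIXTURES = {
    "pure_solubility": "pure_solubility.csv",
    "literature_comparison": "literature_comparison.csv",
    "cnibs_coefficients": "cnibs_coefficients.csv",
    "kat_fits": "kat_fits.csv",
    "water_solubility": "water_solubility.csv",
    "solvent_constants": "solvent_constants.csv",
    "lfer_coefficients": "lfer_coefficients.csv",
    "solute_descriptors_synthetic": "solute_descriptors_synthetic.csv",
}

# Columns stored in the 1e-5 mole-fraction display convention.
_X1E5_COLUMNS = {"x_1e5"}


def load_reference_table(name: str) -> pd.DataFrame:
    """Load a bundled reference table by short name.

    Known names: ``pure_solubility``, ``literature_comparison``,
    ``cnibs_coefficients``, ``kat_fits``, ``water_solubility``,
    ``solvent_constants``, ``lfer_coefficients``,
    ``solute_descriptors_synthetic``.  Solubilities stored as ``x_1e5``
    gain a plain mole-fraction column ``x``.  Every row carries a
    ``source`` provenance tag.
    """
    try:
        fname = _FIXTURES[name]
    except KeyError:
        raise FixtureLookupError(
            f"unknown reference table {name!r}; known: {sorted(_FIXTURES)}"
        ) from None
    with resources.files("cosolv.data").joinpath(fname).open("r") as fh:
        df = pd.read_csv(fh)
    if "source" not in df.columns:
        raise DomainError(f"reference table {name} lacks a source column")
    for col in _X1E5_COLUMNS & set(df.columns):
        df["x"] = df[col] * 1e-5
    num_cols = df.select_dtypes("number")
    if num_cols.isna().any().any():
        raise DomainError(f"reference table {name} contains missing numeric cells")
    return df


def reference_profile(
    solute: str, alcohol_name: str, noise_sigma: float = 0.0, seed: int = 0
) -> BinarySolubilityProfile:
    """Reconstruct a binary solubility profile of one study system.

    Uses the transcribed pure-solvent endpoints and the fitted CNIBS/R-K
    constants of that system; the result is the fitted curve sampled on
    the 0.0..1.0 grid (a model reconstruction, not the raw measurements),
    optionally with simulated noise.
    """
    pure = load_reference_table("pure_solubility")
    coef = load_reference_table("cnibs_coefficients")
    row = coef[(coef.solute == solute) & (coef.alcohol == alcohol_name)]
    if row.empty:
        raise FixtureLookupError(f"no CNIBS constants for {solute}/{alcohol_name}")
    row = row.iloc[0]

    def _pure(solvent: str) -> float:
        sel = pure[(pure.solute == solute) & (pure.solvent == solvent)]
        if sel.empty:
            raise FixtureLookupError(f"no pure solubility for {solute}/{solvent}")
        return float(sel.iloc[0]["x"])

    from .core import BUILTIN_SOLVENTS

    spec = ProfileSimSpec(
        x1_pure=_pure(alcohol_name),
        x2_pure=_pure("ethyl acetate"),
        s_coeffs=(float(row.S0), float(row.S1)),
        noise_sigma=noise_sigma,
        seed=seed,
        solute=solute,
    )
    return simulate_binary_profile(
        spec, alcohol=BUILTIN_SOLVENTS[alcohol_name], ester=ETHYL_ACETATE
    )
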