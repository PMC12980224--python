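"""Excess solubility and CNIBS/Redlich-Kister cosolvency modelling.

For a solute in a binary alcohol (1) + ethyl acetate (2) solvent, the
ideal-mixing (log-linear) baseline and the measured curve define the
excess solubility::

    ln xE = ln x - [x1*ln(x1_0) + x2*ln(x2_0)]

and the Combined Nearly Ideal Binary Solvent / Redlich-Kister model adds a
polynomial correction to the baseline::

    ln x = x1*ln(x1_0) + x2*ln(x2_0) + x1*x2 * sum_i S_i * (x2 - x1)**i,
    i = 0..n,  n <= 3

The endpoints x1_0, x2_0 (pure-solvent solubilities) are data, not fitted
parameters, so the model passes through them exactly for any S_i: the
x1*x2 prefactor vanishes at both ends.  Fitting is ordinary least squares
of ``ln x - baseline`` on the Redlich-Kister basis over the interior
compositions (endpoint residuals are identically zero and carry no
information about the S_i).

The module also locates the solubility maximum of a profile or fitted
curve and reports the percent enhancement over each pure solvent --
the quantitative signature of the synergistic "maximum solubility effect".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .core import (
    BinarySolubilityProfile,
    SolubilityMeasurement,
    r_squared,
    rmsd_log,
)
from .errors import DomainError

__all__ = [
    "CNIBSFit",
    "OrderSelection",
    "MaximumLocation",
    "ideal_ln_solubility",
    "excess_solubility",
    "excess_profile",
    "redlich_kister_term",
    "cnibs_predict",
    "fit_cnibs",
    "select_order",
    "locate_maximum",
]


def ideal_ln_solubility(x2, x1_pure: float, x2_pure: float):
    """Log-linear ideal-mixing baseline ``x1*ln(x1_0) + x2*ln(x2_0)``."""
    if not (0.0 < x1_pure < 1.0 and 0.0 < x2_pure < 1.0):
        raise DomainError("pure-solvent endpoints must be in (0, 1)")
    x2 = np.asarray(x2, dtype=float)
    if np.any((x2 < 0) | (x2 > 1)):
        raise DomainError("x2 must be in [0, 1]")
    out = (1.0 - x2) * np.log(x1_pure) + x2 * np.log(x2_pure)
    return out if out.ndim else float(out)


def excess_solubility(m, x1_pure: float, x2_pure: float) -> float:
    """Excess log solubility ``ln xE = ln x - ideal`` of one measurement.

    Accepts a :class:`SolubilityMeasurement` or an ``(x2, x)`` pair.
    """
    if isinstance(m, SolubilityMeasurement):
        x2, x = m.x2_ethyl_acetate, m.x
    else:
        x2, x = m
    if not (x > 0):
        raise DomainError("solubility must be positive")
    return float(np.log(x) - ideal_ln_solubility(x2, x1_pure, x2_pure))


def excess_profile(profile: BinarySolubilityProfile) -> pd.DataFrame:
    """Excess solubility curve of a whole profile (one row per point)."""
    ln_xe = np.log(profile.x_values) - ideal_ln_solubility(
        profile.x2_grid, profile.x1_pure, profile.x2_pure
    )
    return pd.DataFrame(
        {
            "solute": profile.solute,
            "x2_ethyl_acetate": profile.x2_grid,
            "x": profile.x_values,
            "ln_xE": ln_xe,
        }
    )


def redlich_kister_term(x2, s_coeffs):
    """The correction ``x1*x2 * sum_i S_i (x2 - x1)^i`` of the cosolvency model."""
    x2 = np.asarray(x2, dtype=float)
    s = np.asarray(s_coeffs, dtype=float)
    x1 = 1.0 - x2
    d = x2 - x1
    poly = sum(si * d**i for i, si in enumerate(s))
    out = x1 * x2 * poly
    return out if out.ndim else float(out)


def cnibs_predict(x2, s_coeffs, x1_pure: float, x2_pure: float):
    """Mole-fraction solubility predicted by the CNIBS/R-K model.

    Exact at both endpoints for any coefficients: returns ``x1_pure`` at
    ``x2 = 0`` and ``x2_pure`` at ``x2 = 1``.
    """
    ln_x = ideal_ln_solubility(x2, x1_pure, x2_pure) + redlich_kister_term(
        x2, s_coeffs
    )
    out = np.exp(ln_x)
    return out if np.ndim(out) else float(out)


@dataclass
class CNIBSFit:
    """A fitted CNIBS/R-K model: coefficients, 95 % half-widths (k = 2),
    and goodness of fit (R^2, RMSD) on the ln-solubility scale."""

    order: int
    s_coeffs: np.ndarray
    ci_halfwidths: np.ndarray
    r2: float
    rmsd: float
    x1_pure: float
    x2_pure: float
    n_points: int = 0
    rss_interior: float = 0.0

    def __post_init__(self) -> None:
        self.s_coeffs = np.asarray(self.s_coeffs, dtype=float)
        self.ci_halfwidths = np.asarray(self.ci_halfwidths, dtype=float)
        if len(self.s_coeffs) != self.order + 1:
            raise DomainError("coefficient count must equal order + 1")

    def predict(self, x2):
        return cnibs_predict(x2, self.s_coeffs, self.x1_pure, self.x2_pure)


def fit_cnibs(profile: BinarySolubilityProfile, order: int = 1) -> CNIBSFit:
    """OLS fit of the CNIBS/R-K model of the given polynomial order.

    Endpoints are held fixed at the measured pure-solvent solubilities;
    the regression runs on the interior points only.  Confidence
    half-widths use a coverage factor k = 2 on the coefficient standard
    errors (infinite when there are no residual degrees of freedom).
    R^2 and RMSD are evaluated on ln x over all profile points.
    """
    if order not in (0, 1, 2, 3):
        raise DomainError(f"order must be in {{0, 1, 2, 3}}, got {order}")
    x2 = profile.x2_grid
    interior = (x2 > 0) & (x2 < 1)
    n_int = int(interior.sum())
    if n_int < order + 1:
        raise DomainError(
            f"need at least {order + 1} interior points for order {order}, "
            f"got {n_int}"
        )
    xi = x2[interior]
    y = np.log(profile.x_values[interior]) - ideal_ln_solubility(
        xi, profile.x1_pure, profile.x2_pure
    )
    x1 = 1.0 - xi
    d = xi - x1
    X = np.column_stack([x1 * xi * d**i for i in range(order + 1)])

    coeffs, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coeffs
    rss = float(resid @ resid)
    dof = n_int - (order + 1)
    if dof > 0:
        sigma2 = rss / dof
        cov = sigma2 * np.linalg.inv(X.T @ X)
        ci = 2.0 * np.sqrt(np.diag(cov))
    else:
        ci = np.full(order + 1, np.inf)

    pred_all = cnibs_predict(x2, coeffs, profile.x1_pure, profile.x2_pure)
    fit = CNIBSFit(
        order=order,
        s_coeffs=coeffs,
        ci_halfwidths=ci,
        r2=r_squared(np.log(profile.x_values), np.log(pred_all)),
        rmsd=rmsd_log(profile.x_values, pred_all),
        x1_pure=profile.x1_pure,
        x2_pure=profile.x2_pure,
        n_points=len(x2),
        rss_interior=rss,
    )
    return fit


@dataclass
class OrderSelection:
    """Result of comparing CNIBS orders on one profile."""

    best: CNIBSFit
    table: pd.DataFrame
    criterion: str = "aicc"


def _aicc(rss: float, n: int, n_params: int) -> float:
    """Corrected Akaike information criterion for a Gaussian OLS fit.

    ``n_params`` counts the regression coefficients; the residual variance
    adds one more estimated parameter.
    """
    k = n_params + 1
    if n - k - 1 <= 0:
        return np.inf
    rss = max(rss, 1e-300)  # guard exact fits
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def select_order(
    profile: BinarySolubilityProfile,
    candidate_orders=(0, 1, 2, 3),
    criterion: str = "aicc",
) -> OrderSelection:
    """Fit every candidate order and rank them.

    Default criterion is AICc on the interior log-scale residuals; the
    returned table also carries R^2 and RMSD per order so an informal
    goodness-of-fit comparison can be read off directly.
    """
    if criterion not in ("aicc", "rmsd"):
        raise DomainError(f"unknown selection criterion {criterion!r}")
    rows, fits = [], {}
    for order in candidate_orders:
        fit = fit_cnibs(profile, order)
        fits[order] = fit
        n_int = int(((profile.x2_grid > 0) & (profile.x2_grid < 1)).sum())
        rows.append(
            {
                "order": order,
                "n_constants": order + 1,
                "rss_interior": fit.rss_interior,
                "aicc": _aicc(fit.rss_interior, n_int, order + 1),
                "r2": fit.r2,
                "rmsd": fit.rmsd,
            }
        )
    table = pd.DataFrame(rows).set_index("order")
    key = "aicc" if criterion == "aicc" else "rmsd"
    best_order = int(table[key].idxmin())
    return OrderSelection(best=fits[best_order], table=table, criterion=criterion)


@dataclass
class MaximumLocation:
    """Location and size of the solubility maximum of a profile or fit."""

    x2_at_max: float
    x_max: float
    enhancement_vs_alcohol: float
    enhancement_vs_ester: float
    source: str = "profile"
    notes: list = field(default_factory=list)


def locate_maximum(obj) -> MaximumLocation:
    """Find the solubility maximum and enhancement over the pure solvents.

    For a measured profile the maximum is the grid arg-max (ties break
    toward the lower ester fraction); for a fitted model the curve is
    maximised continuously on [0, 1] by dense-grid bracketing (step 1e-4)
    followed by bounded scalar refinement.  Enhancements are
    ``(x_max - x_pure) / x_pure * 100`` for each pure solvent.
    """
    if isinstance(obj, BinarySolubilityProfile):
        x = obj.x_values
        idx = int(np.argmax(x))  # first occurrence = lowest x2 on a sorted grid
        x2_at, x_at = float(obj.x2_grid[idx]), float(x[idx])
        x1_pure, x2_pure = obj.x1_pure, obj.x2_pure
        source = "profile"
    elif isinstance(obj, CNIBSFit):
        grid = np.arange(0.0, 1.0 + 1e-9, 1e-4)
        vals = obj.predict(grid)
        idx = int(np.argmax(vals))
        lo = max(grid[idx] - 2e-4, 0.0)
        hi = min(grid[idx] + 2e-4, 1.0)
        res = minimize_scalar(
            lambda t: -obj.predict(t), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10},
        )
        x2_at, x_at = float(res.x), float(obj.predict(res.x))
        if vals[idx] >= x_at:  # keep the grid point if refinement did not improve
            x2_at, x_at = float(grid[idx]), float(vals[idx])
        x1_pure, x2_pure = obj.x1_pure, obj.x2_pure
        source = "fit"
    else:
        raise DomainError("locate_maximum expects a profile or a CNIBSFit")
    return MaximumLocation(
        x2_at_max=x2_at,
        x_max=x_at,
        enhancement_vs_alcohol=(x_at - x1_pure) / x1_pure * 100.0,
        enhancement_vs_ester=(x_at - x2_pure) / x2_pure * 100.0,
        source=source,
    )
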