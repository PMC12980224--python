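"""Abraham solvation model (LFER) for solvent/water partition prediction.

The model correlates the base-10 logarithm of a solute's partition between
an organic solvent and water, on the molarity scale, with five solute
descriptors::

    log10(Cs / Cw) = c + e*E + s*S + a*A + b*B + v*V

where E is the excess molar refraction, S the dipolarity/polarizability,
A and B the hydrogen-bond acidity and basicity, and V the McGowan
characteristic volume (in (cm3/mol)/100).  The lowercase coefficients are
properties of the (dry) organic solvent.

Besides the forward prediction this module provides

* conversion of measured mole-fraction solubilities into experimental
  partitions (via the dilute molarity conversion in :mod:`cosolv.core`),
* an evaluation report of predicted vs. experimental partitions with
  per-pair ARD and solute/solvent group means,
* a per-descriptor contribution breakdown, and
* the inverse problem — regressing unknown solute descriptors from a small
  set of experimental partitions, with an explicit structured failure when
  the system is under-determined or the solution is unphysical (the
  "no convergence" outcome rather than a silently clamped fit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import SolventSpec, WATER, mole_fraction_to_molarity, ard
from .errors import DomainError

__all__ = [
    "SoluteDescriptors",
    "SolventLFERCoefficients",
    "PartitionObservation",
    "PartitionEvaluation",
    "DescriptorFitResult",
    "DESCRIPTOR_NAMES",
    "predict_log_partition",
    "experimental_log_partition",
    "evaluate_predictions",
    "term_contributions",
    "fit_solute_descriptors",
]

DESCRIPTOR_NAMES = ("E", "S", "A", "B", "V")


@dataclass(frozen=True)
class SoluteDescriptors:
    """Abraham descriptors of one solute."""

    E: float
    S: float
    A: float
    B: float
    V: float
    solute: str = ""

    def __post_init__(self) -> None:
        for name in DESCRIPTOR_NAMES:
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise DomainError(f"descriptor {name} missing or non-finite")
        if not (self.V > 0):
            raise DomainError(f"McGowan volume V must be > 0, got {self.V}")
        if self.A < 0 or self.B < 0:
            raise DomainError("hydrogen-bond acidity/basicity must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.E, self.S, self.A, self.B, self.V])


@dataclass(frozen=True)
class SolventLFERCoefficients:
    """Abraham regression coefficients of one organic solvent (dry convention)."""

    c: float
    e: float
    s: float
    a: float
    b: float
    v: float
    solvent: str = ""

    def __post_init__(self) -> None:
        for name in ("c", "e", "s", "a", "b", "v"):
            val = getattr(self, name)
            if val is None or not np.isfinite(val):
                raise DomainError(f"coefficient {name} missing or non-finite")

    def as_array(self) -> np.ndarray:
        """Descriptor-facing coefficients (e, s, a, b, v), intercept excluded."""
        return np.array([self.e, self.s, self.a, self.b, self.v])


@dataclass(frozen=True)
class PartitionObservation:
    """An experimental log10 solvent/water partition for a solute/solvent pair."""

    solute: str
    solvent: str
    log10_partition: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.log10_partition):
            raise DomainError("log10_partition must be finite")


def predict_log_partition(
    d: SoluteDescriptors, k: SolventLFERCoefficients
) -> float:
    """Forward LFER prediction ``c + eE + sS + aA + bB + vV`` (log10)."""
    return float(k.c + k.as_array() @ d.as_array())


def experimental_log_partition(
    x_solvent: float,
    solvent: SolventSpec,
    x_water: float,
    water: SolventSpec = WATER,
) -> float:
    """Experimental log10(Cs/Cw) from the two measured mole-fraction solubilities."""
    if not (0.0 < x_solvent < 1.0 and 0.0 < x_water < 1.0):
        raise DomainError("solubilities must be in (0, 1)")
    c_s = mole_fraction_to_molarity(x_solvent, solvent)
    c_w = mole_fraction_to_molarity(x_water, water)
    return float(np.log10(c_s / c_w))


@dataclass
class PartitionEvaluation:
    """ARD report of predicted vs. experimental partitions.

    ``pairs`` has one row per solute/solvent pair with observed, predicted
    and ARD; the group means are plain dicts keyed by solute / solvent name.
    """

    pairs: pd.DataFrame
    by_solute: dict[str, float]
    by_solvent: dict[str, float]
    grand_mean: float
    scale: str = "log"


def evaluate_predictions(
    observations: list[PartitionObservation],
    predictions: list[float],
    *,
    scale: str = "log",
) -> PartitionEvaluation:
    """Compare predicted with experimental partitions pair by pair.

    ``scale="log"`` computes ARD directly on the log10 partition values
    (the default; LFER errors are naturally additive in log units);
    ``scale="linear"`` compares the antilogged partition coefficients.
    """
    if scale not in ("log", "linear"):
        raise DomainError(f"unknown ARD scale {scale!r}")
    if len(observations) == 0 or len(observations) != len(predictions):
        raise DomainError("observations and predictions must be matched, non-empty")
    rows = []
    for obs, pred in zip(observations, predictions):
        if scale == "log":
            pair_ard = ard(pred, obs.log10_partition)
        else:
            pair_ard = ard(10.0**pred, 10.0**obs.log10_partition)
        rows.append(
            {
                "solute": obs.solute,
                "solvent": obs.solvent,
                "observed": obs.log10_partition,
                "predicted": float(pred),
                "ard": pair_ard,
            }
        )
    pairs = pd.DataFrame(rows)
    return PartitionEvaluation(
        pairs=pairs,
        by_solute=pairs.groupby("solute")["ard"].mean().to_dict(),
        by_solvent=pairs.groupby("solvent")["ard"].mean().to_dict(),
        grand_mean=float(pairs["ard"].mean()),
        scale=scale,
    )


def term_contributions(
    d: SoluteDescriptors,
    k: SolventLFERCoefficients,
    *,
    include_intercept: bool = False,
) -> dict[str, float]:
    """Percentage contribution of each LFER term to the predicted partition.

    Each product term eE, sS, aA, bB, vV contributes ``|term| / sum(|terms|)
    * 100``.  The intercept is excluded by default (it is a solvent property,
    not a solute-solvent interaction term); ``include_intercept=True`` adds
    ``c`` to the normalisation under the key ``"c"``.
    """
    terms = dict(zip(DESCRIPTOR_NAMES, k.as_array() * d.as_array()))
    if include_intercept:
        terms["c"] = k.c
    total = sum(abs(t) for t in terms.values())
    if total == 0:
        raise DomainError("all LFER terms are zero; contributions undefined")
    return {name: abs(t) / total * 100.0 for name, t in terms.items()}


@dataclass
class DescriptorFitResult:
    """Outcome of the inverse descriptor regression.

    ``status`` is one of ``"ok"``, ``"under_determined"``,
    ``"invariant_violation"``; only ``"ok"`` carries a usable descriptor
    set.  The failure statuses mirror the non-convergence outcome of
    regressing descriptors from too few pure-solvent partitions.
    """

    status: str
    free_descriptors: tuple[str, ...]
    descriptors: SoluteDescriptors | None = None
    fitted_values: dict[str, float] = field(default_factory=dict)
    residuals: np.ndarray | None = None
    max_abs_residual: float = float("nan")
    message: str = ""

    @property
    def converged(self) -> bool:
        return self.status == "ok"


def fit_solute_descriptors(
    observations: list[PartitionObservation],
    coefficient_sets: list[SolventLFERCoefficients],
    free_descriptors,
    *,
    fixed: dict[str, float] | None = None,
    solute: str = "",
) -> DescriptorFitResult:
    """Least-squares regression of unknown Abraham descriptors.

    ``free_descriptors`` selects the subset of {E, S, A, B, V} to estimate;
    the rest are held at ``fixed`` values (default 0).  Observations and
    coefficient sets are matched positionally (one solvent per observation).

    Rather than raising, ill-posed problems return a structured failure:
    fewer observations than free descriptors (or a rank-deficient design)
    yield ``status="under_determined"``, and solutions violating the
    descriptor invariants (A < 0, B < 0, V <= 0) yield
    ``status="invariant_violation"``.
    """
    free = tuple(free_descriptors)
    if not free or any(f not in DESCRIPTOR_NAMES for f in free):
        raise DomainError(f"free_descriptors must be a subset of {DESCRIPTOR_NAMES}")
    if len(observations) != len(coefficient_sets) or not observations:
        raise DomainError("need one coefficient set per observation")
    fixed = dict(fixed or {})
    fixed_full = {name: fixed.get(name, 0.0) for name in DESCRIPTOR_NAMES}

    n_obs, n_free = len(observations), len(free)
    coef_mat = np.array([k.as_array() for k in coefficient_sets])  # (n_obs, 5)
    intercepts = np.array([k.c for k in coefficient_sets])
    y = np.array([o.log10_partition for o in observations])

    fixed_idx = [i for i, n in enumerate(DESCRIPTOR_NAMES) if n not in free]
    free_idx = [i for i, n in enumerate(DESCRIPTOR_NAMES) if n in free]
    offset = intercepts + coef_mat[:, fixed_idx] @ np.array(
        [fixed_full[DESCRIPTOR_NAMES[i]] for i in fixed_idx]
    )
    design = coef_mat[:, free_idx]

    if n_obs < n_free or np.linalg.matrix_rank(design) < n_free:
        return DescriptorFitResult(
            status="under_determined",
            free_descriptors=free,
            message=(
                f"{n_obs} observations cannot determine {n_free} free "
                f"descriptors (design rank {np.linalg.matrix_rank(design)})"
            ),
        )

    sol, *_ = np.linalg.lstsq(design, y - offset, rcond=None)
    fitted = dict(fixed_full)
    fitted.update({DESCRIPTOR_NAMES[i]: float(v) for i, v in zip(free_idx, sol)})
    residuals = design @ sol + offset - y

    violations = []
    if fitted["A"] < 0:
        violations.append(f"A = {fitted['A']:.4g} < 0")
    if fitted["B"] < 0:
        violations.append(f"B = {fitted['B']:.4g} < 0")
    if fitted["V"] <= 0:
        violations.append(f"V = {fitted['V']:.4g} <= 0")
    if violations:
        return DescriptorFitResult(
            status="invariant_violation",
            free_descriptors=free,
            fitted_values=fitted,
            residuals=residuals,
            max_abs_residual=float(np.max(np.abs(residuals))),
            message="unphysical solution: " + "; ".join(violations),
        )

    return DescriptorFitResult(
        status="ok",
        free_descriptors=free,
        descriptors=SoluteDescriptors(solute=solute, **fitted),
        fitted_values=fitted,
        residuals=residuals,
        max_abs_residual=float(np.max(np.abs(residuals))),
        message="converged",
    )
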