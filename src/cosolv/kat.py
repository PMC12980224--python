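"""Kamlet-Abboud-Taft (KAT) solvatochromic correlation of solubility.

The classical KAT-LSER model is linear in the mixture's solvatochromic
parameters::

    ln x = C0 + C1*alpha + C2*beta + C3*pi_star + C4*(dH2/1000)

with alpha the hydrogen-bond donor acidity, beta the acceptor basicity,
pi* the dipolarity/polarizability index and dH2 the squared Hildebrand
solubility parameter (J/cm3) of the solvent mixture; dH2 always enters
scaled by 1/1000 so all regressors are of order one.

Solubility curves with an interior maximum cannot be captured by a model
that is linear in monotone parameter curves, so the package also fits a
quadratic family in which the response is the mole-fraction solubility x
itself and every parameter may enter linearly and squared (up to nine
coefficients).  A backward-elimination procedure prunes that family term
by term using per-term t-tests, recording the full trace so that the
surviving model form can be audited for over- or under-fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import BinarySolubilityProfile
from .errors import CollinearityError, DomainError

__all__ = [
    "KATParameters",
    "KATModelSpec",
    "KATFit",
    "EliminationStep",
    "EliminationResult",
    "TERM_NAMES",
    "FULL_QUADRATIC_SPEC",
    "REDUCED_QUADRATIC_SPEC",
    "CLASSICAL_TERMS",
    "classical_kat_predict",
    "kat_design_matrix",
    "fit_kat",
    "eliminate_terms",
]


@dataclass(frozen=True)
class KATParameters:
    """Solvatochromic parameters of the solvent mixture at one composition.

    ``deltaH2`` is stored unscaled (J/cm3); the 1/1000 scaling is applied
    when design matrices are built.
    """

    x2_ethyl_acetate: float
    alpha: float
    beta: float
    pi_star: float
    deltaH2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.x2_ethyl_acetate <= 1.0):
            raise DomainError("x2_ethyl_acetate must be in [0, 1]")
        if self.alpha < 0 or self.beta < 0:
            raise DomainError("alpha and beta must be >= 0")
        if not (self.deltaH2 > 0):
            raise DomainError("deltaH2 must be > 0")


# Canonical term vocabulary, in the order of the full quadratic family.
TERM_NAMES = (
    "intercept",
    "pi_star",
    "pi_star^2",
    "beta",
    "beta^2",
    "alpha",
    "alpha^2",
    "dh2",
    "dh2^2",
)

#: Classical (linear, ln-x) model terms.
CLASSICAL_TERMS = ("intercept", "alpha", "beta", "pi_star", "dh2")


def _term_value(term: str, p: KATParameters) -> float:
    h = p.deltaH2 / 1000.0
    base = {
        "intercept": 1.0,
        "pi_star": p.pi_star,
        "pi_star^2": p.pi_star**2,
        "beta": p.beta,
        "beta^2": p.beta**2,
        "alpha": p.alpha,
        "alpha^2": p.alpha**2,
        "dh2": h,
        "dh2^2": h**2,
    }
    try:
        return base[term]
    except KeyError:
        raise DomainError(f"unknown KAT term {term!r}") from None


@dataclass(frozen=True)
class KATModelSpec:
    """An ordered subset of the quadratic KAT term family.

    The intercept is always included (and is inserted first if omitted).
    """

    included_terms: tuple[str, ...]

    def __post_init__(self) -> None:
        terms = tuple(self.included_terms)
        if any(t not in TERM_NAMES for t in terms):
            bad = [t for t in terms if t not in TERM_NAMES]
            raise DomainError(f"unknown terms: {bad}")
        if len(set(terms)) != len(terms):
            raise DomainError("duplicate terms in model spec")
        if "intercept" not in terms:
            terms = ("intercept",) + terms
        else:
            terms = ("intercept",) + tuple(t for t in terms if t != "intercept")
        if not terms:
            raise DomainError("model spec must include at least the intercept")
        object.__setattr__(self, "included_terms", terms)

    def drop(self, term: str) -> "KATModelSpec":
        if term == "intercept":
            raise DomainError("cannot drop the intercept")
        return KATModelSpec(tuple(t for t in self.included_terms if t != term))

    @property
    def non_intercept_terms(self) -> tuple[str, ...]:
        return tuple(t for t in self.included_terms if t != "intercept")


FULL_QUADRATIC_SPEC = KATModelSpec(TERM_NAMES)
REDUCED_QUADRATIC_SPEC = KATModelSpec(
    ("intercept", "beta", "beta^2", "alpha", "alpha^2", "dh2", "dh2^2")
)


def classical_kat_predict(p: KATParameters, coefficients) -> float:
    """Classical linear KAT-LSER prediction of ln x.

    ``coefficients`` are (C0, C1, C2, C3, C4) multiplying
    (1, alpha, beta, pi*, dH2/1000).
    """
    c = np.asarray(coefficients, dtype=float)
    if c.shape != (5,) or not np.all(np.isfinite(c)):
        raise DomainError("need 5 finite coefficients (C0..C4)")
    return float(
        c[0]
        + c[1] * p.alpha
        + c[2] * p.beta
        + c[3] * p.pi_star
        + c[4] * p.deltaH2 / 1000.0
    )


def kat_design_matrix(
    params_by_composition: list[KATParameters], spec: KATModelSpec
) -> pd.DataFrame:
    """One row per composition, one column per included term (spec order)."""
    if not params_by_composition:
        raise DomainError("need at least one composition")
    if not spec.included_terms:
        raise DomainError("empty model spec")
    rows = [
        [_term_value(t, p) for t in spec.included_terms]
        for p in params_by_composition
    ]
    idx = [p.x2_ethyl_acetate for p in params_by_composition]
    return pd.DataFrame(rows, columns=list(spec.included_terms), index=idx)


@dataclass
class KATFit:
    """A fitted KAT model with per-term significance diagnostics.

    ``diagnostics`` has one row per term: coefficient, standard error,
    t statistic and two-sided p value.  ``rmsd`` is on the response scale
    (x by default, ln x in classical mode).
    """

    spec: KATModelSpec
    coefficients: dict[str, float]
    rmsd: float
    diagnostics: pd.DataFrame
    rss: float
    response: str = "x"
    n_obs: int = 0

    def predict(self, params_by_composition: list[KATParameters]) -> np.ndarray:
        X = kat_design_matrix(params_by_composition, self.spec).to_numpy()
        beta = np.array([self.coefficients[t] for t in self.spec.included_terms])
        return X @ beta


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Name the columns responsible for rank deficiency (QR with pivoting)."""
    from scipy.linalg import qr

    rank = np.linalg.matrix_rank(X)
    if rank >= X.shape[1]:
        return []
    _, _, piv = qr(X, pivoting=True)
    return sorted(names[j] for j in piv[rank:])


def _align_response(
    profile: BinarySolubilityProfile, params: list[KATParameters]
) -> np.ndarray:
    comp_to_x = {round(p.x2_ethyl_acetate, 9): p.x for p in profile.points}
    y = []
    for kp in params:
        key = round(kp.x2_ethyl_acetate, 9)
        if key not in comp_to_x:
            raise DomainError(
                f"no solubility point at composition x2 = {kp.x2_ethyl_acetate}"
            )
        y.append(comp_to_x[key])
    return np.array(y)


def fit_kat(
    profile: BinarySolubilityProfile,
    params: list[KATParameters],
    spec: KATModelSpec,
    *,
    response: str = "x",
) -> KATFit:
    """Multiple linear regression of solubility on the KAT design matrix.

    ``response="x"`` fits the mole-fraction solubility itself (the
    quadratic family); ``response="lnx"`` fits ln x (classical mode).
    Raises :class:`CollinearityError` naming the offending terms when the
    design is rank deficient.
    """
    if response not in ("x", "lnx"):
        raise DomainError(f"unknown response {response!r}")
    y = _align_response(profile, params)
    if response == "lnx":
        y = np.log(y)
    Xdf = kat_design_matrix(params, spec)
    X = Xdf.to_numpy()
    names = list(Xdf.columns)
    if len(y) < len(names):
        raise DomainError(
            f"{len(y)} rows cannot fit {len(names)} terms"
        )
    bad = _collinear_columns(X, names)
    if bad:
        raise CollinearityError(bad)

    model = sm.OLS(y, X)
    res = model.fit()
    diagnostics = pd.DataFrame(
        {
            "term": names,
            "coef": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
        }
    ).set_index("term")
    return KATFit(
        spec=spec,
        coefficients=dict(zip(names, (float(v) for v in res.params))),
        rmsd=float(np.sqrt(np.mean(res.resid**2))),
        diagnostics=diagnostics,
        rss=float(res.ssr),
        response=response,
        n_obs=len(y),
    )


@dataclass
class EliminationStep:
    """One step of the elimination trace."""

    spec: KATModelSpec
    fit: KATFit | None
    dropped: str | None
    reason: str


@dataclass
class EliminationResult:
    """Final model plus the full elimination trace."""

    final: KATFit
    trace: list[EliminationStep]
    mode: str = "backward"

    @property
    def dropped_terms(self) -> list[str]:
        return [s.dropped for s in self.trace if s.dropped is not None]


def _prescreen(
    params: list[KATParameters], spec: KATModelSpec
) -> tuple[KATModelSpec, list[EliminationStep]]:
    """Remove uninformative terms before iterating.

    Terms whose design column is constant across compositions (a parameter
    that does not vary carries no information about the composition
    dependence of solubility) are eliminated first, then any residual
    exactly-collinear columns.
    """
    steps: list[EliminationStep] = []
    X = kat_design_matrix(params, spec)
    for t in spec.non_intercept_terms:
        col = X[t].to_numpy()
        if np.ptp(col) < 1e-12 * max(1.0, np.max(np.abs(col))):
            spec = spec.drop(t)
            steps.append(
                EliminationStep(spec, None, t, "constant across compositions")
            )
    X = kat_design_matrix(params, spec).to_numpy()
    names = list(spec.included_terms)
    bad = [t for t in _collinear_columns(X, names) if t != "intercept"]
    for t in bad:
        spec = spec.drop(t)
        steps.append(EliminationStep(spec, None, t, "collinear with other terms"))
    return spec, steps


def eliminate_terms(
    profile: BinarySolubilityProfile,
    params: list[KATParameters],
    start_spec: KATModelSpec = REDUCED_QUADRATIC_SPEC,
    *,
    threshold: float = 0.05,
    response: str = "x",
    mode: str = "backward",
) -> EliminationResult:
    """Prune the KAT term family down to the significant terms.

    Backward mode repeatedly refits and drops the least-significant term
    (largest p value above ``threshold``), stopping when every remaining
    term is significant or only the intercept plus one term remain.
    Constant-in-composition terms (e.g. pi* in these mixtures) are
    eliminated before iteration begins and recorded in the trace.

    Exhaustive mode instead scores every subset of the (pre-screened)
    start terms by AICc and returns the best one; the trace then contains
    one entry per evaluated subset ordered from worst to best.
    """
    if mode not in ("backward", "exhaustive"):
        raise DomainError(f"unknown elimination mode {mode!r}")
    spec, steps = _prescreen(params, start_spec)

    if mode == "exhaustive":
        return _eliminate_exhaustive(profile, params, spec, steps, response)

    fit = fit_kat(profile, params, spec, response=response)
    steps.append(EliminationStep(spec, fit, None, "initial fit"))
    while len(spec.non_intercept_terms) > 1:
        pvals = fit.diagnostics["p"].drop("intercept")
        worst = pvals.idxmax()
        if pvals.loc[worst] <= threshold:
            break
        spec = spec.drop(worst)
        fit = fit_kat(profile, params, spec, response=response)
        steps.append(
            EliminationStep(
                spec, fit, worst, f"p = {pvals.loc[worst]:.3g} > {threshold}"
            )
        )
    return EliminationResult(final=fit, trace=steps, mode="backward")


def _eliminate_exhaustive(profile, params, spec, steps, response):
    n = _align_response(profile, params).size
    scored = []
    candidates = spec.non_intercept_terms
    for r in range(1, len(candidates) + 1):
        for subset in combinations(candidates, r):
            sub = KATModelSpec(("intercept",) + subset)
            try:
                fit = fit_kat(profile, params, sub, response=response)
            except (CollinearityError, DomainError):
                continue
            k = len(sub.included_terms) + 1
            if n - k - 1 <= 0:
                aicc = np.inf
            else:
                aicc = (
                    n * np.log(max(fit.rss, 1e-300) / n)
                    + 2 * k
                    + 2 * k * (k + 1) / (n - k - 1)
                )
            scored.append((aicc, fit))
    if not scored:
        raise DomainError("no fittable subset of the start spec")
    scored.sort(key=lambda t: -t[0])
    for aicc, fit in scored:
        steps.append(
            EliminationStep(fit.spec, fit, None, f"exhaustive AICc = {aicc:.4g}")
        )
    return EliminationResult(final=scored[-1][1], trace=steps, mode="exhaustive")
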