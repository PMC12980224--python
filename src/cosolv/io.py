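"""CSV/JSON readers and writers, run configuration, and the full pipeline.

The on-disk schemas are plain UTF-8 CSV with a decimal point:

* ``solubility.csv`` — solute, alcohol, ester, x2_ethyl_acetate, x, T_K, P_kPa
* ``kat_params.csv`` — x2_ethyl_acetate, alpha, beta, pi_star, deltaH2
* ``descriptors.csv`` — solute, E, S, A, B, V
* ``lfer_coefficients.csv`` — solvent, c, e, s, a, b, v

``run_full_analysis`` ties the stages together for every profile in the
input: excess-solubility curve, CNIBS fit (fixed order or AICc-selected),
maximum location and enhancements, and — when solvatochromic parameters
and/or Abraham inputs are supplied — the KAT elimination and the partition
evaluation.  Failures are recorded per item and the run continues.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .abraham import (
    PartitionObservation,
    SoluteDescriptors,
    SolventLFERCoefficients,
    evaluate_predictions,
    experimental_log_partition,
    predict_log_partition,
)
from .core import (
    BUILTIN_SOLVENTS,
    BinarySolubilityProfile,
    SolubilityMeasurement,
    SolventSpec,
    WATER,
)
from .cosolvency import excess_profile, fit_cnibs, locate_maximum, select_order
from .errors import CollinearityError, DomainError, TableValidationError
from .kat import KATParameters, REDUCED_QUADRATIC_SPEC, eliminate_terms

logger = logging.getLogger("cosolv")

SOLUBILITY_COLUMNS = ["solute", "alcohol", "ester", "x2_ethyl_acetate", "x", "T_K", "P_kPa"]


def _solvent_from_name(name: str) -> SolventSpec:
    try:
        return BUILTIN_SOLVENTS[name]
    except KeyError:
        # Unknown solvents get placeholder constants; only the name matters
        # for grouping, but molarity conversion then needs user densities.
        return SolventSpec(name, molar_mass=100.0, density_298K=1.0)


def read_solubility_table(path) -> list[BinarySolubilityProfile]:
    """Read and validate a solubility CSV into profiles.

    Rows are grouped by (solute, alcohol, ester) and sorted by composition.
    Malformed rows (non-numeric cells, out-of-range values, duplicate
    compositions) are reported together with their 1-based line numbers.
    Each profile must include both pure-solvent endpoints (x2 = 0 and 1).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SOLUBILITY_COLUMNS if c not in df.columns]
    if missing:
        raise TableValidationError(f"{path.name}: missing columns {missing}")

    bad_rows: list[tuple[int, str]] = []
    records = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            rec = {
                "solute": row["solute"].strip(),
                "alcohol": row["alcohol"].strip(),
                "ester": row["ester"].strip(),
                "x2": float(row["x2_ethyl_acetate"]),
                "x": float(row["x"]),
                "T_K": float(row["T_K"]),
                "P_kPa": float(row["P_kPa"]),
                "line": line,
            }
        except ValueError:
            bad_rows.append((line, "non-numeric cell"))
            continue
        if not (0.0 <= rec["x2"] <= 1.0):
            bad_rows.append((line, f"x2 = {rec['x2']} outside [0, 1]"))
            continue
        if not (0.0 < rec["x"] < 1.0):
            bad_rows.append((line, f"x = {rec['x']} outside (0, 1)"))
            continue
        records.append(rec)
    if bad_rows:
        raise TableValidationError(f"{path.name}: invalid rows", bad_rows)

    if not records:
        return []
    profiles = []
    table = pd.DataFrame(records)
    for (solute, alcohol, ester), grp in table.groupby(
        ["solute", "alcohol", "ester"], sort=False
    ):
        grp = grp.sort_values("x2", kind="stable")
        dup = grp[grp.duplicated("x2", keep=False)]
        if not dup.empty:
            raise TableValidationError(
                f"{path.name}: duplicate compositions for {solute}/{alcohol}",
                [(int(l), f"duplicate x2 = {v}") for l, v in zip(dup["line"], dup["x2"])],
            )
        x2 = grp["x2"].to_numpy()
        if x2[0] != 0.0 or x2[-1] != 1.0:
            raise TableValidationError(
                f"{path.name}: profile {solute}/{alcohol} lacks pure-solvent "
                "endpoints (x2 = 0 and x2 = 1 rows required)"
            )
        pts = tuple(
            SolubilityMeasurement(
                solute, float(r.x2), float(r.x), float(r.T_K), float(r.P_kPa)
            )
            for r in grp.itertuples()
        )
        profiles.append(
            BinarySolubilityProfile(
                solute,
                _solvent_from_name(alcohol),
                _solvent_from_name(ester),
                pts,
                x1_pure=float(grp["x"].iloc[0]),
                x2_pure=float(grp["x"].iloc[-1]),
            )
        )
    return profiles


def write_solubility_table(profiles: list[BinarySolubilityProfile], path) -> None:
    """Write profiles back to the solubility CSV schema (6 significant digits)."""
    rows = []
    for p in profiles:
        for m in p.points:
            rows.append(
                {
                    "solute": p.solute,
                    "alcohol": p.alcohol.name,
                    "ester": p.ester.name,
                    "x2_ethyl_acetate": f"{m.x2_ethyl_acetate:.6g}",
                    "x": f"{m.x:.6g}",
                    "T_K": f"{m.temperature:.6g}",
                    "P_kPa": f"{m.pressure:.6g}",
                }
            )
    pd.DataFrame(rows, columns=SOLUBILITY_COLUMNS).to_csv(path, index=False)


def read_kat_params(path) -> list[KATParameters]:
    df = pd.read_csv(path)
    needed = {"x2_ethyl_acetate", "alpha", "beta", "pi_star", "deltaH2"}
    missing = needed - set(df.columns)
    if missing:
        raise TableValidationError(f"kat params: missing columns {sorted(missing)}")
    return [
        KATParameters(
            float(r.x2_ethyl_acetate),
            float(r.alpha),
            float(r.beta),
            float(r.pi_star),
            float(r.deltaH2),
        )
        for r in df.itertuples()
    ]


def write_kat_params(params: list[KATParameters], path) -> None:
    pd.DataFrame(
        [
            {
                "x2_ethyl_acetate": p.x2_ethyl_acetate,
                "alpha": p.alpha,
                "beta": p.beta,
                "pi_star": p.pi_star,
                "deltaH2": p.deltaH2,
            }
            for p in params
        ]
    ).to_csv(path, index=False, float_format="%.6g")


def read_descriptors(path) -> dict[str, SoluteDescriptors]:
    df = pd.read_csv(path)
    return {
        r.solute: SoluteDescriptors(
            E=float(r.E), S=float(r.S), A=float(r.A), B=float(r.B), V=float(r.V),
            solute=str(r.solute),
        )
        for r in df.itertuples()
    }


def read_lfer_coefficients(path) -> dict[str, SolventLFERCoefficients]:
    df = pd.read_csv(path)
    return {
        r.solvent: SolventLFERCoefficients(
            c=float(r.c), e=float(r.e), s=float(r.s), a=float(r.a),
            b=float(r.b), v=float(r.v), solvent=str(r.solvent),
        )
        for r in df.itertuples()
    }


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    solubility_path: str
    out_dir: str
    kat_params_path: str | None = None
    descriptors_path: str | None = None
    lfer_coefficients_path: str | None = None
    water_solubility_path: str | None = None
    cnibs_order: int | None = 1  # None -> AICc selection
    kat_threshold: float = 0.05
    kat_response: str = "x"
    seed: int = 0
    verbosity: int = 0

    def validate(self) -> None:
        for attr in (
            "solubility_path",
            "kat_params_path",
            "descriptors_path",
            "lfer_coefficients_path",
            "water_solubility_path",
        ):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise TableValidationError(f"{attr} does not exist: {p}")
        if not isinstance(self.seed, int):
            raise TableValidationError("seed must be an integer")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_full_analysis(config: RunConfig) -> dict:
    """Run every applicable stage for every profile in the input.

    Returns the report bundle (also written to ``<out_dir>/report.json``
    with per-profile CSVs alongside).  Per-item failures are collected in
    ``report["errors"]``; the run continues with the remaining items.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": _jsonable(asdict(config)),
        "profiles": [],
        "abraham": None,
        "errors": [],
    }

    profiles = read_solubility_table(config.solubility_path)
    if not profiles:
        logger.warning("input contains no profiles; writing empty report")

    kat_params = (
        read_kat_params(config.kat_params_path) if config.kat_params_path else None
    )

    for prof in profiles:
        tag = f"{prof.solute}/{prof.alcohol.name}+{prof.ester.name}"
        entry: dict = {"system": tag, "n_points": len(prof.points)}
        try:
            exc = excess_profile(prof)
            exc_path = out_dir / f"excess_{tag.replace('/', '_').replace(' ', '-')}.csv"
            exc.to_csv(exc_path, index=False, float_format="%.6g")
            entry["excess_csv"] = exc_path.name
            entry["excess_all_positive_interior"] = bool(
                (exc.ln_xE[(exc.x2_ethyl_acetate > 0) & (exc.x2_ethyl_acetate < 1)] > 0).all()
            )

            if config.cnibs_order is None:
                sel = select_order(prof)
                fit = sel.best
                entry["order_table"] = _jsonable(sel.table.reset_index().to_dict("records"))
            else:
                fit = fit_cnibs(prof, config.cnibs_order)
            entry["cnibs"] = {
                "order": fit.order,
                "S_coeffs": _jsonable(fit.s_coeffs),
                "ci_halfwidths": _jsonable(fit.ci_halfwidths),
                "r2": fit.r2,
                "rmsd": fit.rmsd,
            }
            loc = locate_maximum(prof)
            fit_loc = locate_maximum(fit)
            entry["maximum"] = {
                "grid_x2": loc.x2_at_max,
                "grid_enhancement_vs_alcohol_pct": loc.enhancement_vs_alcohol,
                "grid_enhancement_vs_ester_pct": loc.enhancement_vs_ester,
                "fit_x2": fit_loc.x2_at_max,
                "fit_enhancement_vs_alcohol_pct": fit_loc.enhancement_vs_alcohol,
            }

            if kat_params is not None:
                try:
                    elim = eliminate_terms(
                        prof,
                        kat_params,
                        REDUCED_QUADRATIC_SPEC,
                        threshold=config.kat_threshold,
                        response=config.kat_response,
                    )
                    entry["kat"] = {
                        "final_terms": list(elim.final.spec.included_terms),
                        "coefficients": _jsonable(elim.final.coefficients),
                        "rmsd": elim.final.rmsd,
                        "trace": [
                            {"dropped": s.dropped, "reason": s.reason,
                             "terms": list(s.spec.included_terms)}
                            for s in elim.trace
                        ],
                    }
                except (CollinearityError, DomainError) as err:
                    report["errors"].append({"system": tag, "stage": "kat", "error": str(err)})
        except (DomainError, TableValidationError) as err:
            report["errors"].append({"system": tag, "stage": "cosolvency", "error": str(err)})
        report["profiles"].append(entry)

    if config.descriptors_path and config.lfer_coefficients_path and config.water_solubility_path:
        try:
            report["abraham"] = _run_abraham(config, profiles, report)
        except (DomainError, TableValidationError) as err:
            report["errors"].append({"system": "*", "stage": "abraham", "error": str(err)})

    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))
    return report


def _run_abraham(config: RunConfig, profiles, report) -> dict | None:
    descriptors = read_descriptors(config.descriptors_path)
    coefficients = read_lfer_coefficients(config.lfer_coefficients_path)
    water = pd.read_csv(config.water_solubility_path).set_index("solute")["x"]

    observations, predictions = [], []
    for prof in profiles:
        for solvent_spec, x in (
            (prof.alcohol, prof.x1_pure),
            (prof.ester, prof.x2_pure),
        ):
            if prof.solute not in descriptors:
                report["errors"].append(
                    {"system": prof.solute, "stage": "abraham",
                     "error": "no descriptors for solute"}
                )
                continue
            if prof.solute not in water.index or solvent_spec.name not in coefficients:
                continue
            obs = PartitionObservation(
                prof.solute,
                solvent_spec.name,
                experimental_log_partition(x, solvent_spec, float(water[prof.solute])),
            )
            pred = predict_log_partition(
                descriptors[prof.solute], coefficients[solvent_spec.name]
            )
            observations.append(obs)
            predictions.append(pred)
    if not observations:
        return None
    seen = set()
    uniq_obs, uniq_pred = [], []
    for o, p in zip(observations, predictions):
        key = (o.solute, o.solvent)
        if key not in seen:
            seen.add(key)
            uniq_obs.append(o)
            uniq_pred.append(p)
    ev = evaluate_predictions(uniq_obs, uniq_pred)
    return {
        "pairs": _jsonable(ev.pairs.to_dict("records")),
        "by_solute": _jsonable(ev.by_solute),
        "by_solvent": _jsonable(ev.by_solvent),
        "grand_mean_ard": ev.grand_mean,
        "scale": ev.scale,
    }
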