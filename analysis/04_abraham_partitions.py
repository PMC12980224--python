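#!/usr/bin/env python
"""Abraham LFER evaluation of the pure-solvent solubilities.

Converts the measured mole-fraction solubilities (three polyphenols x
three organic solvents, plus water) to molarity-scale partitions,
predicts them from Abraham descriptors, and reports per-pair ARDs,
group means, and per-descriptor contributions.  Also attempts the
inverse regression for trans-polydatin, whose descriptors are not
published.

Caveat: the bundled solute descriptors are synthetic stand-in estimates
(only the McGowan volume V is exact), so the deviation table measures
those estimates as much as the model; the structural findings — V is the
dominant contributor in ethyl acetate, and the polydatin inversion is
under-determined (3 partitions cannot fix 5 descriptors) — do not depend
on the estimates.
"""

from pathlib import Path

import pandas as pd

from cosolv import (
    PartitionObservation,
    SoluteDescriptors,
    SolventLFERCoefficients,
    evaluate_predictions,
    experimental_log_partition,
    fit_solute_descriptors,
    predict_log_partition,
    term_contributions,
)
from cosolv.core import BUILTIN_SOLVENTS
from cosolv.synthetic import load_reference_table

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    pure = load_reference_table("pure_solubility")
    water = load_reference_table("water_solubility").set_index("solute")["x"]
    descriptors = {
        r.solute: SoluteDescriptors(r.E, r.S, r.A, r.B, r.V, solute=r.solute)
        for r in load_reference_table("solute_descriptors_synthetic").itertuples()
    }
    coefficients = {
        r.solvent: SolventLFERCoefficients(r.c, r.e, r.s, r.a, r.b, r.v,
                                           solvent=r.solvent)
        for r in load_reference_table("lfer_coefficients").itertuples()
    }

    obs, preds = [], []
    for r in pure.itertuples():
        if r.solute not in descriptors:
            continue
        obs.append(
            PartitionObservation(
                r.solute, r.solvent,
                experimental_log_partition(
                    r.x, BUILTIN_SOLVENTS[r.solvent], float(water[r.solute])
                ),
            )
        )
        preds.append(predict_log_partition(descriptors[r.solute],
                                           coefficients[r.solvent]))
    ev = evaluate_predictions(obs, preds)

    OUT.mkdir(exist_ok=True)
    ev.pairs.to_csv(OUT / "abraham_partition_ards.csv", index=False,
                    float_format="%.6g")
    contrib_rows = []
    for solute, d in descriptors.items():
        for solvent, k in coefficients.items():
            row = {"solute": solute, "solvent": solvent}
            row.update(term_contributions(d, k))
            contrib_rows.append(row)
    contrib = pd.DataFrame(contrib_rows)
    contrib.to_csv(OUT / "abraham_contributions.csv", index=False,
                   float_format="%.4g")

    print(ev.pairs.sort_values("ard").to_string(index=False))
    print(f"\ngrand mean ARD (log scale, stand-in descriptors): "
          f"{ev.grand_mean:.1f}%")
    ester = contrib[contrib.solvent == "ethyl acetate"]
    print("dominant term in ethyl acetate per solute:",
          ester.set_index("solute")[["E", "S", "A", "B", "V"]].idxmax(axis=1).to_dict())

    # inverse problem for the glucoside with no published descriptors
    polydatin_obs = [
        PartitionObservation(
            "trans-polydatin", solvent,
            experimental_log_partition(
                float(pure.query(
                    "solute == 'trans-polydatin' and solvent == @solvent")["x"].iloc[0]),
                BUILTIN_SOLVENTS[solvent],
                1e-4,  # nominal aqueous solubility supplied for the attempt
            ),
        )
        for solvent in ("methanol", "ethanol", "ethyl acetate")
    ]
    res = fit_solute_descriptors(
        polydatin_obs, [coefficients[o.solvent] for o in polydatin_obs],
        ("E", "S", "A", "B", "V"),
    )
    print(f"\ntrans-polydatin descriptor regression: status={res.status} "
          f"({res.message})")


if __name__ == "__main__":
    main()
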