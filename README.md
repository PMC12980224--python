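# cosolv

Solubility modelling of bioactive polyphenols (*trans*-polydatin,
*p*-coumaric acid, quercetin, *trans*-resveratrol) in methanol, ethanol,
ethyl acetate and the binary mixtures methanol + ethyl acetate and
ethanol + ethyl acetate at 298.2 K and 0.1 MPa. Polyphenol extraction is
routinely limited by low solubility in any single green solvent; mixing an
ester cosolvent into an alcohol can raise solubility well above either pure
solvent (the "maximum solubility effect"), and quantifying that synergy is
what this package is for. It is aimed at solution thermodynamics and
pharmaceutical pre-formulation work: anyone asking *which solvent mixture,
at which composition, dissolves this solute best, and why*.

## Models

Three complementary descriptions are implemented, plus seeded synthetic
generators so that every stage is testable without external data.

**Abraham solvation model (LFER).** The molarity-scale partition of a
solute between an organic solvent and water follows

    log10(Cs/Cw) = c + eE + sS + aA + bB + vV

with solute descriptors E (excess molar refraction), S (dipolarity/
polarizability), A, B (hydrogen-bond acidity/basicity) and V (McGowan
volume), and solvent coefficients c..v. The package predicts partitions,
converts measured mole-fraction solubilities to experimental partitions
(dilute approximation C = 1000·x·ρ/M), reports per-pair ARDs and
per-descriptor contributions, and attempts the inverse regression of
unknown descriptors with an explicit structured failure when the problem
is under-determined.

**Excess solubility and CNIBS/Redlich–Kister.** In a binary solvent with
alcohol fraction x₁ = 1 − x₂,

    ln xE = ln x − [x₁ ln x₁⁰ + x₂ ln x₂⁰]
    ln x  =        x₁ ln x₁⁰ + x₂ ln x₂⁰ + x₁x₂ Σᵢ Sᵢ (x₂ − x₁)ⁱ ,  i = 0..n ≤ 3

where x₁⁰, x₂⁰ are the pure-solvent solubilities (data, not parameters —
the model is exact at both endpoints for any Sᵢ). Fitting is OLS on ln x
over the interior compositions, with k = 2 confidence half-widths, R² and
log-scale RMSD, AICc order comparison, and location of the solubility
maximum with percent enhancement over each pure solvent.

**KAT-LSER solvatochromic correlation.** The classical linear model
ln x = C₀ + C₁α + C₂β + C₃π* + C₄(δ_H²/1000) cannot produce an interior
maximum from monotone mixture parameter curves, so a quadratic family in
α, β, π*, δ_H² (response x) is fitted and pruned by iterative term
elimination — greedy backward (per-term t-tests) or exhaustive AICc
enumeration — returning the full elimination trace for audit.

## Worked example

Reconstruct the *trans*-resveratrol / methanol + ethyl acetate system from
its fitted constants and endpoints, refit, and locate the maximum:

```python
from cosolv import fit_cnibs, locate_maximum
from cosolv.synthetic import reference_profile

prof = reference_profile("trans-resveratrol", "methanol")
fit = fit_cnibs(prof, order=1)
print("S coefficients:", fit.s_coeffs.round(4))
loc = locate_maximum(fit)
print("max at x2 =", round(loc.x2_at_max, 4),
      "enhancement vs methanol =", f"{loc.enhancement_vs_alcohol:.1f}%")
```

prints

```
S coefficients: [ 4.6619 -0.0721]
max at x2 = 0.4163 enhancement vs methanol = 128.1%
```

i.e. the two Redlich–Kister constants are recovered exactly from the
reconstructed curve, and the fitted curve peaks near 0.4 mole fraction of
ethyl acetate where the solute is ~128 % more soluble than in pure
methanol — the cosolvency maximum that makes the mixed solvent worth
using. Likewise `ard(2583e-5, 1660e-5)` → `55.6` % reproduces the
largest literature deviation for ethanolic *trans*-resveratrol.

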