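# Methods

Conventions, estimation choices, and the scope of what the synthetic data
can and cannot show. All solubilities are isothermal (298.2 K, 100 kPa)
mole fractions; compositions are solute-free solvent mole fractions with
x₂ the ethyl acetate fraction and x₁ = 1 − x₂ the alcohol fraction.

## Unit conversion and error metrics

* **Mole fraction → molarity** uses the dilute-solution approximation
  C = 1000·x·ρ/M (mol/L), neglecting the solute's contribution to the
  solution volume: one mole of solution is assigned the molar volume of
  the pure solvent. Bundled 298.15 K densities (g/cm³): water 0.99705,
  methanol 0.7866, ethanol 0.7849, ethyl acetate 0.894. The conversion
  accepts a user-supplied density so the sensitivity of partition-based
  results to this convention can be checked directly; at the solubilities
  involved (x ≤ 0.07) the neglected (1 − x) factor shifts log₁₀ partitions
  by < 0.02.
* **ARD** = |x − x_ref|/|x_ref|·100. For partitions the default is
  computed on the log₁₀ partition values themselves: LFER errors are
  additive in log units, and percent deviations of a few of these
  log-unit quantities correspond to realistic model errors, whereas the
  same percentages on the linear partition scale would imply implausibly
  accurate predictions. A linear-scale mode is exposed.
* **RMSD** is evaluated on ln x by default. The fitted-curve RMSDs of the
  cosolvency model (0.02–0.11 for solubilities of 10⁻³–10⁻²) are only
  dimensionally consistent with log-scale residuals; a raw-scale flag is
  provided. R² is computed on the same ln x scale the model is fitted on.

## Cosolvency model (CNIBS/Redlich–Kister)

ln x = x₁ ln x₁⁰ + x₂ ln x₂⁰ + x₁x₂ ΣᵢSᵢ(x₂−x₁)ⁱ, i = 0..n ≤ 3.

* Endpoints x₁⁰, x₂⁰ are **data**: the x₁x₂ prefactor makes the model
  exact at both pure solvents for any coefficients, so the endpoints are
  never free parameters and the regression uses interior points only
  (endpoint residuals are identically zero and carry no information
  about Sᵢ). Fitting is unweighted OLS of ln x − ideal on the
  Redlich–Kister basis.
* Confidence half-widths are k = 2 times the coefficient standard error.
  With 9 interior points and 2 constants this corresponds to ~91–92 %
  actual coverage (the exact t₇ multiplier would be 2.36); the simulation
  in `analysis/03_cnibs_refits.py` measures ~90–93 %.
* Order comparison uses AICc on the interior log-scale residuals, counting
  the residual variance as an estimated parameter. Under a 2-constant
  truth with 3 % log noise the 2-constant model is selected in ≥ 90 % of
  replicates; noise-free nested refits agree to < 10⁻¹⁰ in RSS.
* The solubility maximum of a measured profile is the grid arg-max (ties
  break toward lower ester fraction); for a fitted curve the model is
  maximised on a 10⁻⁴ grid followed by bounded scalar refinement.
  Enhancements are (x_max − x_pure)/x_pure·100.

## Abraham model

log₁₀(Cs/Cw) = c + eE + sS + aA + bB + vV (base-10 by convention; the
cosolvency and KAT models use natural logs). Per-descriptor contributions
are |term|/Σ|terms|·100 over the five product terms with the intercept
excluded — the intercept is a solvent property, not a solute–solvent
interaction — with an include-intercept variant for comparison. The
inverse problem (descriptor regression from measured partitions) returns
a structured result: `under_determined` when observations or design rank
cannot fix the free descriptors, `invariant_violation` when the algebraic
solution is unphysical (A < 0, B < 0, V ≤ 0); solutions are never clamped
into the feasible region, because a clamped fit would misrepresent a
genuinely non-convergent regression. With only three pure-solvent
partitions, the full five-descriptor problem is structurally
under-determined; this is the package's account of why descriptors for
*trans*-polydatin cannot be regressed from this dataset.

## KAT-LSER and term elimination

The quadratic family x = C₀ + Σ over {α, α², β, β², π*, (π*)², h, h²}
with h = δ_H²/1000 (the 1/1000 scaling is applied uniformly so all
regressors are of order one; some reported coefficient tables omit the
scaling from their headers, which is treated as a typographical
inconsistency). The response defaults to x itself — a model linear in
monotone parameter curves cannot produce the observed interior maxima on
the ln x scale, which is why the classical linear KAT form (available via
`response="lnx"`) is insufficient for these systems.

Elimination modes:

* **backward** (default): refit, drop the term with the largest p-value
  above the threshold (default 0.05), repeat; stop when all terms are
  significant or only the intercept plus one term remain. Terms whose
  design column is constant across compositions (π* in these mixtures)
  are removed before iteration and recorded in the trace — a parameter
  that does not vary cannot influence a composition-dependent response —
  as are exactly collinear columns.
* **exhaustive**: every subset of the (pre-screened) terms is fitted and
  ranked by AICc; feasible at ≤ 9 terms.

Sign conventions are never constrained during fitting; the interpretive
expectations (α and β promote dissolution, δ_H² opposes it via the
cavity-formation cost) are post-fit annotations, not constraints.

**Known limitation — greedy instability.** The mixture parameter curves
are strongly collinear (all nearly monotone in x₂), so the saturated
7-term fit has a highly degenerate design. Under these conditions greedy
backward elimination is path-unstable: an informative term dropped early
cannot return, and the procedure frequently terminates in a statistically
adequate surrogate model rather than the generating one (planted-model
recovery < 5 % in the selection-consistency experiment). Exhaustive AICc
enumeration over the same data recovers the planted 3-term model in
~93–96 % of 200 replicates, which is why the selection-consistency checks
use the exhaustive mode; the backward trace remains available for
audit and mirrors the iterative refinement usually described for this
kind of correlation. Model-form conclusions from a single backward run on
collinear solvatochromic data should be treated with caution.

## Synthetic data

* **Binary profiles** invert the cosolvency model: x(x₂) from given
  endpoints and Sᵢ on the 0.0, 0.1, …, 1.0 grid, with multiplicative
  log-normal noise exp(ε), ε ~ N(0, σ²) on interior points only (endpoint
  values are data and stay noise-free; solubility errors scale with
  magnitude, matching the log-scale fit). Default σ = 0.03, a realistic
  repeatability for UV-quantified equilibrium solubility.
* **Mixture solvatochromic curves** interpolate α, β, δ_H² linearly from
  the alcohol endpoint (methanol: α 0.98, β 0.66, π* 0.60, δ_H 29.6 MPa^0.5;
  ethanol: α 0.86, β 0.75, π* 0.54, δ_H 26.5) to the ester endpoint
  (α 0, β 0.45, π* 0.55, δ_H 18.2 — pure ethyl acetate has no hydrogen-bond
  donor acidity), plus a small smooth bump 4·a·x₂(1−x₂)(1+s(2x₂−1)) that
  vanishes at both ends. Default amplitudes/skews (α 0.06/0.3, β 0.04/−0.3,
  δ_H² −18/0.2) keep every curve strictly monotone while giving each
  parameter a distinct preferential-solvation shape; π* is held constant.
* **Partition datasets** invert the LFER with additive Gaussian noise on
  log₁₀ partitions.
* All generators are bit-reproducible from an integer seed.

**What the reconstructions are not.** The bundled binary-mixture profiles
are the fitted cosolvency curves sampled on the measurement grid, not the
raw measurements: they reproduce the maximum-solubility compositions of
all reported systems (within one grid step) and the enhancement of the
best-fitted system (~128 % vs a reported 129 % for *trans*-resveratrol in
methanol + ethyl acetate), but enhancements that depend on measurement
scatter around the curve are smoothed (e.g. the reconstruction gives
158 % where 121 % was measured for quercetin in ethanol + ethyl acetate).
Similarly, the bundled solute descriptor table is a synthetic stand-in
(exact McGowan volumes; estimated E, S, A, B), so Abraham deviation
magnitudes measure those estimates as much as the model; structural
results (V dominating in ethyl acetate, the under-determined polydatin
inversion) are insensitive to them. Noise-free reconstructions also make
every regression term formally significant, so KAT elimination on them
retains more terms than it would on scattered measurements. Passing tests
on synthetic data therefore validate the estimators and the selection
procedures — recovery of planted truths, coverage, exactness identities —
not the measured values themselves.

## Problem sizes

Simulation-based checks use 100 replicates (order selection), 200
replicates (model-form selection consistency), and 500 replicates
(confidence-interval coverage, noise calibration) on 11-point
profiles — large enough that the pass thresholds (≥ 90 % rates) sit
several Monte-Carlo standard errors from the observed rates.
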