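# Methods

## The model

`petpop` implements a population (nonlinear mixed-effects) analysis of
(R)-[¹¹C]verapamil kinetics in plasma and brain, designed around the paired
PET study in which P-glycoprotein (P-gp) at the blood–brain barrier is
inhibited by tariquidar part-way through the baseline scan.

**Plasma.** Tracer disposition follows a three-compartment mammillary
model on drug amounts (kBq): a central volume `Vc` with elimination
clearance `CL`, exchanging with two peripheral volumes `Vp1`, `Vp2`
through inter-compartmental clearances `Q1`, `Q2`. The tracer injection is
a zero-order infusion over the recorded injection duration, not an
instantaneous bolus.

**Brain.** The brain is a two-compartment system driven by the plasma
concentration `C_c(t)`: a central brain volume `Vbr1` exchanging with
plasma through an influx clearance `Qin` and an efflux clearance `Qout`,
and a peripheral brain volume `Vbr2` connected by a bidirectional
clearance `Qbr`. For rats `Vbr2` is fixed at 2 ml, the total volume of a
rat brain. The equations are written on amounts with concentrations
`C_x = A_x / V_x`, which keeps clearance × concentration dimensionally an
amount rate and preserves the equilibrium ratio below.

**Inhibition covariate.** Tariquidar enters as a dimensionless factor
`D = Eff_tariquidar(dose)^cov × Eff_scan^cov`, a product of two categorical
covariates: the dose-group effect (cov = 1 from the start of the
administration onward) and a scan effect (cov = 1 only in the second,
post-inhibition scan, absorbing the partial washout of inhibition between
scans). `D` multiplies either `Qout` (efflux enhancement hypothesis) or
`Qin` (influx hindrance); the two placements are non-nested alternatives
compared by OFV. `D` switches as a step at the *start* of the tariquidar
administration: the covariate is categorical and the onset timing within
the 60-s (rat) or 30-min (human) administration is not identified by the
data. Status epilepticus enters as a multiplicative factor `Eff_SE` on
`Vbr1`.

**Observation model.** PET measures total regional activity, so the
observed brain concentration is `(A_br1 + A_br2) / (Vbr1 + Vbr2)`. This
convention makes the equilibrium brain-to-plasma ratio equal
`Qin / (D·Qout)` exactly, matching the definition of the reported
partition coefficient `V_T = Qin/Qout`; dividing by a separately chosen
physical volume is available through the `obs_volume` argument.
Inter-individual variability is lognormal, `θ_i = θ_pop·exp(η_i)` with
`η ~ N(0, ω²)` and shared-eta blocks (the plasma model shares one eta
across {Vc, CL, Q2} and one across {Vp1, Q1}, as in the published
estimates). Residual error is proportional, `y = f·(1+ε)`, with separate
σ for the plasma and brain streams. Published variability values are
interpreted as standard deviations (ω of the exponential model, σ of the
proportional model); both are configurable.

Each scan starts from zero tracer amounts: the inter-scan gap is ≥ 6
carbon-11 half-lives and curves are decay-corrected per scan. Radioactive
decay itself is not modeled. Internal units are min, ml, kBq, g.

## Exact simulation

All structural systems are linear and time-invariant within segments, so
no ODE stepping is used. The plasma system is solved by eigendecomposition
with φ-function quadrature over the piecewise-constant infusion schedule
(exact; the matrix-exponential augmented-system fallback covers
ill-conditioned eigenvector matrices, and `CL = 0` is supported for
mass-balance checks). The plasma concentration is then represented as
piecewise *sums of exponentials* in closed form, and the brain response to
each exponential mode is itself closed form — so the brain curves are
exact too, with no interpolation of the forcing function. A general
piecewise-linear forcing path exists for sampled input curves (it is exact
for that input class) and is also the basis of the classic 2T4K model fit.
Near-resonant modes (a forcing exponent coinciding with a brain
eigenvalue) are nudged by 1e-8 min⁻¹, far below any other error source.
The hot evaluation path of the fitting loop is a numba-compiled kernel
over a packed per-scan cache; a pure-numpy implementation of the same
algebra is kept as the reference and fallback, and the two agree to ~1e-11.

## Estimation

The marginal likelihood per subject is approximated Laplace-style: an
inner damped Newton (Gauss–Newton curvature, Armijo backtracking,
gradient tolerance 1e-8, finite-difference sensitivities with step 1e-4 on
eta) finds the mode of the joint density; the objective is

OFV = Σ_i [ 2·g_i(η̂_i) + log det Ω + log det H_i ],

where `g` is the negative log joint density and `H` the curvature at the
mode. `objective="focei"` (default) uses the Gauss–Newton/expected
curvature with the residual variance evaluated at the conditional
estimates (first-order conditional with interaction); `objective="laplace"`
uses the exact finite-difference Hessian, and is the automatic fallback
when the FOCE curvature is not positive definite. With no (or zero-ω)
random effects the OFV reduces to the closed-form proportional-error
expression. Against 64-node adaptive Gauss–Hermite quadrature on one-eta
problems the approximation is within a few hundredths of an OFV unit.

The outer problem optimizes log-transformed free thetas, omegas and sigmas
(positivity by construction) with L-BFGS-B (relative function tolerance
1e-9, numerical gradient step 1e-4 on the log scale); per-subject eta
modes are warm-started across objective evaluations. Reaching the
iteration budget returns the best point found, flagged in the convergence
message; only abnormal terminations count as failures. Relative standard
errors come from the inverse observed Hessian of the OFV on the log scale
(central differences, step 0.02); a singular Hessian yields missing
entries, which mirrors how uncertainties are reported as "−" for the
five-subject human study.

**Sequential fitting.** The plasma model is fitted first on the plasma
stream; the brain model is then fitted with each subject's plasma fixed.
By default the brain forcing is the *individual* (empirical-Bayes) plasma
curve; the population curve is a configuration switch
(`forcing="population"`). Individual forcing is the default because the
brain data are conditionally independent of the plasma data given the
subject's own input function, and using the population curve visibly
biases `Qin`/`Qout` in simulation.

**Covariate selection.** Forward addition accepts, per round, the
candidate with the largest OFV drop exceeding the χ²(df) quantile
(3.84/6.63/10.83 at p = 0.05/0.01/0.001 for 1 df — the exact quantiles,
one printed source rounds the first to 3.83); backward deletion then
removes covariates whose deletion costs less than the (by default equal)
threshold. Ties break lexicographically by candidate name. A
tariquidar-plus-scan effect is a single structured candidate (the scan
effect is meaningless alone). The efflux-vs-influx placement question is a
non-nested comparison of equal-dimension models: both are fitted to the
identical data and the lower OFV is preferred.

## Synthetic studies

The generator reproduces the two published designs: rats (n = 21 as
7/4/5/5 across naïve/post-SE × 3/15 mg kg⁻¹; 140-min baseline scan with
tariquidar as a 60-s bolus at 60 min; 60-min post-inhibition scan 2 h
later; body weights, injected activities and injection durations drawn
from the reported group means ± SD, truncated positive) and humans (n = 5;
120/40-min scans; 2 mg kg⁻¹ infused over 30 min from 40 min; second scan
2 h 50 min after the infusion end). True parameters default to the
published population estimates; brain transport clearances get a
conventional 20% lognormal between-subject CV (the original reports list
no brain IIV), and residual errors default to the reported proportional
SDs (plasma 0.482, whole-brain 0.382). Observations are predictions at
frame midpoints times `(1+ε)`, clipped at zero. PET frame schedules are
not part of the published designs; the default is a conventional dynamic
schedule (12×10 s, 6×30 s, 5×60 s, then 5-min frames), with `coarse` and
`sparse` variants for simulation studies.

The generator emulates the statistical structure the analysis assumes —
it does not simulate scanner resolution, partial-volume effects, count
statistics, or radiometabolite kinetics. Passing recovery tests therefore
demonstrates the correctness of the estimation machinery under the assumed
model, not robustness to those real-data features.

## Classic PET analyses

The 2T4K model (K1, k2, k3, k4; `V_T = K1/k2·(1+k3/k4)`) is fitted by
uniform-weight least squares on log rate constants from three starting
points, with the tissue response computed exactly for the piecewise-linear
input. Logan analysis regresses `∫C_T/C_T` on `∫C_p/C_T` over late frames;
integrals are trapezoidal, computed on each curve's own grid anchored at
t = 0 (the plasma grid is denser around the bolus peak, which dominates
its integral). The default `t*` is the earliest start whose regression
reaches R² ≥ 0.99 with ≥ 3 points. Frames from the start of the
tariquidar administration to the end of the baseline scan are excluded by
default, since these methods assume time-constant parameters. A constant
plasma-to-blood ratio of 1.29 converts whole-blood curves. No
blood-volume term is included by default (none is part of the published
analyses).

## Problem sizes used in the test suite

The simulation studies in the acceptance tests use sizes chosen by this
package: parameter recovery runs one 50-rat study with the default frame
schedule and the full sequential pipeline (median relative error of the
transport parameters ~3%, criterion < 15%); the placement comparison runs
20 seeded replicates of 7-rat cohorts and the stepwise-selection operating
characteristics 20 (power) and 10 (type-I) replicates of 12-rat cohorts
with the sparse frame schedule, with the brain stage driven by the
simulated subjects' true individual plasma curves so each replicate
isolates the brain-stage machinery being scored.

## Known limitations

* No SAEM or importance-sampling estimators; no off-diagonal omega
  structure beyond shared-eta blocks.
* The plasma→brain sequential approach conditions on the plasma point
  estimates; plasma uncertainty is not propagated into the brain stage.
* Proportional error with the large published σ values implies a small
  likelihood-induced bias of fits toward lower predictions; this is a
  property of the model family, visible in the noise-free self-consistency
  tests only when σ is not taken to zero.
* The human design (n = 5) generally leaves the IIV and RSE of the brain
  stage unidentifiable; the reporting conventions expect missing entries.
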