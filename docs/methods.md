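# Methods

## Structural model and assumptions

The simulator is a one-compartment model with zero-order infusion input and
first-order elimination. Concentrations under arbitrary dosing histories are
computed by superposing the closed-form single-infusion solution; AUC over a
window [t1, t2] is obtained by mass balance,
AUC = (A(t1) + dose infused in (t1, t2] − A(t2)) / CL, with infusions that
straddle a window boundary prorated by their overlap. Both are exact for the
model (no quadrature error); the test suite checks them against an
independent stiff ODE integration and adaptive quadrature.

One compartment is the right fidelity here because the prior has a fixed
volume of distribution (60.7 L, the mean of the 53.9–67.5 L development
range) and because the dosing nomogram's day-2 AUCs are weight-independent
for identical absolute doses — both facts are only consistent with a
CLcr-driven clearance and a weight-free structural model. Two-compartment
support, paediatric/obese/renal-replacement priors and unbound-fraction
modelling are out of scope.

## Covariate relations and calibration

- CL_pop = θ_intercept + θ_slope · min(CLcr, 130 mL/min), with
  θ_intercept = 0 by default. CLcr is used as given when measured;
  otherwise Cockcroft–Gault on actual body weight (×0.85 for women), with
  no body-surface-area adjustment.
- The 130 mL/min cap: augmented clearance (eGFR ≥ 130) is handled by the
  regimen rules (q8h dosing), not by extrapolating the linear clearance
  relation beyond the range the prior was built on.
- θ_slope is not a published number; it is identified by least squares so
  that forward simulation of every nomogram cell (loading dose at t = 0,
  maintenance q12h from 12 h or q24h from 24 h, infusion durations 30 min
  per 0.5 g with a 1 h floor) reproduces the printed day-2 AUC. The fit
  gives θ_slope = 0.04961 L/h per mL/min with a maximum relative residual
  of 1.26 % over all 36 cells. Adding a free intercept does not reduce the
  maximum residual (1.55 %), so the intercept stays at zero — the residual
  pattern shows no evidence of a non-renal clearance term. The fitted value
  is stored as configuration data (`data/default_model.yaml`), not code.
- Once-daily nomogram rows start maintenance at t = 24 h (the first
  calendar day carries the loading dose only); q12h rows at t = 12 h.
  Loading doses are taken as printed and verified forward only; the
  selection rule behind them is not re-derived. The printed CLcr-40 /
  80-kg cell (528) exceeds the nomogram's titular 400–500 band; it is
  treated as printed truth.

## Between-subject and residual variability

η_CL and η_V are log-normal with default standard deviations 0.35 and 0.25
(typical vancomycin magnitudes; package defaults, configurable, not
published estimates). Residual error is proportional + additive with
defaults σ_prop = 0.10 and σ_add = 0.5 mg/L, shared between the simulator's
noise model and the MAP objective's weights.

## MAP estimation

The posterior mode minimizes
Σ_i (C_obs,i − C_pred,i)²/var_i + η'Ω⁻¹η with
var_i = (σ_prop·C_pred,i)² + σ_add². Observed sampling times are used
verbatim — no snapping to the nominal trough. Numerical choices:

- Gradients by complex-step differentiation of the closed-form solution
  (step 1e−20): machine-precision derivatives with no finite-difference
  tuning, valid because the solution is analytic in (CL, V) inside each
  time segment.
- L-BFGS-B from η = 0 plus four fixed perturbations (±0.5 on each axis);
  the best objective wins, ties broken toward the smallest ‖η‖. Fully
  deterministic, no random seed involved.
- No observations → the prior mode (η = 0) is returned exactly, skipping
  the optimizer.
- An observation before the first infusion or more than 48 h after the
  last infusion ends is rejected; optimizer non-convergence is flagged on
  the result, never silent.
- Estimation is posterior-mode only; full posterior sampling (MCMC) is out
  of scope, matching how the field's dose-forecasting tools operate.

With two samples (trough + peak) clearance is well identified (noise-free
recovery within 1 %); volume is weakly identified and shrinks toward the
prior — the tests assert this asymmetry rather than hiding it.

## Dose optimization

The optimizer enumerates maintenance doses 250–2000 mg (250 mg grid) ×
intervals {8, 12, 24} h and minimizes |daily dose/CL − 500 μg·h/mL|, the
point target with its ±100 margin. Ties break toward fewer daily
administrations, then the lower daily dose; a current regimen already at
least as close to target is kept unchanged. If no grid point lands inside
400–600 the nearest regimen is returned flagged infeasible. Initial
regimens: 30 mg/kg loading + 20 mg/kg q12h (actual body weight) for normal
renal function, 20 mg/kg q8h for augmented clearance (eGFR ≥ 130),
nomogram lookup for CLcr < 60 mL/min. Recommendations return nominal
weight-based doses; snapping to the 0.25 g vial grid is opt-in and only
applied when the rounded dose stays within 2.5 mg/kg of nominal. Warnings
attach for loading doses > 3 g and daily doses > 4 g.

## Rules engine

Pure functions of their inputs, each returning the clinical-question
citations that fired. Efficacy uses AUC ≥ 400 μg·h/mL irrespective of the
measured MIC (a two-fold MIC dilution error would otherwise dominate the
ratio); AUC/MIC by method (broth microdilution threshold 400, Etest 200) is
reported as information, and the minimum AUC needed at a given MIC is
exposed (800 μg·h/mL at MIC 2 — beyond the 600 safety cap, hence flagged
unattainable). AKI risk factors: eGFR < 30, piperacillin/tazobactam,
diuretics, trough > 20 μg/mL, ICU stay; the factor-specific safe-trough
cut-offs are 12.4 / 13.5 / 11.7 μg/mL against 19.3 overall, and with
multiple factors the lowest applies (conservative choice; the source rules
give no combination rule). "Serious/complicated infection" is an input
flag, not inferred. The stricter literature day-2 upper bound (515) is
available as an optional policy, default off. TDM timing: day 2 for
serious infection, high AKI risk or q24h dosing; day 3+ otherwise; ICU adds
an earlier-and-frequent flag; non-ICU day-2 plans carry the advice that the
third dose may be held if only a trough was drawn.

## Synthetic patients

Covariates are truncated normals on the printed ranges with the location
solved so the truncated mean equals the printed mean and SD = range/4
(keeps ~95 % of the untruncated mass in range for a centred mean). The
printed CLcr summary (range 6.85–85.0, mean 77.1 mL/min) puts the mean near
the upper bound; it is encoded as printed, which makes the CLcr
distribution strongly left-skewed. CLcr is sampled directly as a measured
clearance rather than through an invented creatinine distribution. Flag
prevalences (ICU 20 %, piperacillin/tazobactam 15 %, diuretics 20 %, other
nephrotoxins 10 %, serious infection 30 %) and the 50 % female fraction are
package defaults, not published values.

Trough sampling times are jittered per the recorded real-world scatter
(q12h: <10 h 5.9 %, 10–11 h 22.8 %, 11–12 h 55.0 %, ≥12 h 16.3 %; q24h:
<22 h 24.1 %, 22–23 h 27.6 %, 23–24 h 41.4 %, >24 h 6.9 %), uniform within
a bin; the open outer bins are given 2 h and 1 h widths. Peaks are drawn
uniformly 1–2 h after the end of infusion. Simulated concentrations add
proportional + additive noise with a 0.05 mg/L assay floor, and the
generator retains a noise-free truth record for recovery tests.

What the generator does *not* emulate: covariate correlations (age–CLcr,
weight–CLcr), time-varying renal function, assay censoring below a
quantification limit, and clinical outcomes (AKI events, treatment
response). Passing tests therefore demonstrate internal consistency of the
estimate-then-optimize loop under the model's own assumptions, not
predictive performance on real patients — the published external-evaluation
accuracy ratios require patient data and are not reproduced here.

## Problem sizes and tolerances

Test and verification sizes are chosen to keep the full suite under a
minute: 20 random regimens for the ODE/quadrature oracles (relative error
bounds 1e−6 and 0.1 %), a 41×41 grid oracle for the MAP objective on 20
cases, 200 virtual patients for parameter recovery (median |CL̂/CL − 1| ≤
10 % at 10 % proportional noise), 10⁴ draws for distributional checks, and
50–60 patients for the end-to-end target-attainment loop (≥ 90 % in band,
noise-free). Nomogram reproduction is held to ±3 %, absorbing unprinted
details of the original software (exact ramp handling, internal rounding).
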