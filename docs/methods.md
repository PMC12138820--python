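# Methods

## Model structure and assumptions

Ergothioneine (EGT) enters cells only through OCTN1, so every tissue flux
is either a Michaelis–Menten uptake term sharing one transporter affinity
(K_m = 21 μM, human OCTN1) or a linear efflux/flow term.  The body is a
fixed 70-kg adult; no body-weight scaling, no metabolism (metabolite
plasma levels are negligible), no brain compartment (human brain
disposition is unknown), no protein-binding correction, and no fecal loss
(oral absorption is treated as complete).  Urine is the only elimination
route: filtered EGT (GFR·C_p) enters a small proximal-duct compartment,
is reabsorbed by a saturable carrier (V_maxD), and the residue leaves at
the urinary flow Q_u.  Circulating red cells act as a large slow
reservoir: a marrow precursor pool takes up EGT from plasma (V_maxP),
matures into RBCs with rate k_1, and RBC turnover (k_b) returns EGT to
plasma.

Two structural choices deserve emphasis because the mass balances were
assembled from the model description rather than a printed equation set:

1. **RBC degradation returns EGT to plasma.**  With a degradation sink
   instead, the system equilibrates near ~5 μM under 8 mg/day and cannot
   reproduce the published trajectory (5.78 → 7.69 → 9.08 → 10.0 μM);
   with return, urinary excretion is the sole elimination route and the
   full dose-projection grid is reproduced within ~1% per cell.
2. **Absorbed gut flux enters the first liver sub-unit** (portal route),
   consistent with the flow-limited tandem-liver design.  A config switch
   (`absorption_route="systemic"`) routes absorption to plasma instead;
   the difference is far below reporting precision because the liver
   eliminates nothing.

The liver is five tandem sub-units in series, each carrying one fifth of
V_he, V_h, V_maxH and PS_eff_H — the standard equal-split dispersion
approximation.  Peripheral V_max values scale from the hepatic anchor by
OCTN1 mRNA expression per gram, with organ mass approximated by
intracellular volume at 1 kg/L (no organ masses are published for this
parameterization).  Efflux clearances are fixed by
PS_eff = (V_max/K_m)/K_p so that the linear-regime steady state
reproduces the measured tissue-to-plasma ratios.

## Parameters

All defaults live in `ModelParameters` (and `data/default_params.yaml`):
volumes and plasma flows of the standard 70-kg human, k_a = 6 /h (gastric
emptying; absorption is fast), k_1 = 0.0104 /h (precursor half-life
2.75 d), k_b = 0.000963 /h (RBC half-life 30 d), V_maxH = 10·Q_h·K_m
= 10,227 μmol/h (flow-limited anchor), and the three calibrated values
R = 1.36 μmol/h (≈7.48 mg/day dietary intake), V_maxD = 121 μmol/h,
V_maxP = 11.1 μmol/h.  Hematocrit defaults to V_RBC/V_blood =
2.29/5.20 ≈ 0.440 and is configurable; the printed per-arm baseline RBC
values are used as given rather than re-derived, since they reflect
group-specific hematocrits.  Oral doses convert at 229.30 g/mol
(L-ergothioneine, C9H15N3O2S).

Baseline initial conditions pin plasma and RBC to observed blank values
and solve every other compartment from its local balance (gut R/k_a,
liver extracellular C_p + R/Q_h, saturable-uptake/linear-efflux tissue
levels, the positive root of the duct quadratic, precursor
v_upP(C_p)/k_1).  A global steady state is deliberately **not** imposed:
under the calibrated R the model's whole-system equilibrium plasma level
(~8.7 μM) exceeds observed baselines, so baselines drift slowly upward
even without supplementation — a property of the published
parameterization, not an integration artifact.

Reported "week-w" concentrations are pre-dose troughs at t = 168·w h
(trial sampling was fasted, before dosing); intra-day fluctuation is far
below reporting precision at these kinetics.

## Numerics

The stiff time scale is the liver extracellular relaxation,
(V_maxH/5/K_m)/(V_he/5) ≈ 1.4e3 /h.  Integration uses LSODA with
rtol 1e-8 / atol 1e-10, restarted at every dose event (doses are
impulsive additions to the gut amount).  `odeint` is used on hot paths
with `mxstep` raised to 1e6 — its default step cap silently truncates
this system.  The RHS is numba-compiled; a fixed-step classical RK4
integrator (dt = 2e-4 h, chosen an order of magnitude inside the
explicit-stability bound dt ≲ 2e-3 h) serves as an independent
brute-force oracle and agrees with the stiff solution to ~1e-8 relative
over 24 h (the suite asserts ≤1e-4 over 72 h).

Calibration minimizes weighted least squares jointly over all arms and
both matrices with `scipy.optimize.least_squares` (TRF) on
log-parameters (positivity by construction).  Relative weighting
(residual/prediction) is the default so that plasma (~5 μM) and RBC
(~600 μM) residuals contribute comparably; 1/√ŷ and uniform schemes are
options.  The finite-difference Jacobian step is 1e-3 on the log scale —
deliberately large, because steps near √eps fall below the adaptive
integrator's noise floor and corrupt the gradient.  CVs are the
Gauss–Newton approximation: square roots of the diagonal of
s²(JᵀJ)⁻¹ at the optimum on the log scale, which are first-order
relative standard errors of the natural-scale estimates.  A multistart
option (geometric perturbations spanning ×0.25–×4) guards against local
minima.  Ties and degenerate inputs: a singular information matrix
reports CVs as NaN rather than fabricating them; an unattainable
dose-finding target returns an explicit "not attained" result.

## Synthetic cohorts

The generator emulates the two trials' designs: arms of n subjects
sampled at days 0/8/14/21/28/56 (8-week study) or weeks 0/16, lognormal
between-subject variability on the baseline plasma level (CV 51%), the
baseline RBC level (CV 44%) and the dietary rate R (CV 43% — the
published cross-sectional dispersions), and multiplicative lognormal
assay noise (CV 10%).  Each subject's trajectory is the deterministic
model solution from their individualized baseline and R; an optional
missing-at-random flag drops post-baseline visits.  What the generator
does **not** emulate: within-subject day-to-day intake variation,
dose-timing irregularity, assay heteroscedasticity beyond a constant CV,
and any covariate structure (age, renal function).  Passing recovery
tests therefore demonstrate identifiability under the stated variability
model, not robustness to structural misspecification in real data.

Recovery studies fit arm-mean profiles with each arm's initial values
pinned to the realized arm-mean baselines, mirroring the use of measured
blanks in the original calibration.

## Problem sizes used in the automated checks

Dose projections integrate the full 16-week regimens (112 daily doses)
at rtol 1e-8.  The Monte-Carlo recovery study uses 50 replicate virtual
trials of three arms (5/10/20 mg/day) × 14 subjects at the 8-week
sampling schedule, generated at rtol 1e-6 and fitted at rtol 1e-5 —
integration error at these tolerances is orders of magnitude below the
10% bias criterion, and the sizes keep the whole study in the
minutes range on one CPU.

## Known limitations

- The mass-balance equations are a reconstruction validated against the
  published simulation surface (projection grid, dose-finding
  conclusion, sensitivity signs), not against an authoritative equation
  listing; residual ~1% cell-level deviations remain, and at the
  knife-edge 7 mg/day × low-baseline cell (9.46 vs printed 9.56 μM,
  target 9.51) that margin flips the per-block attainment call.
- Fixed 70-kg physiology; no inter-occasion variability; means-only
  calibration (no mixed-effects estimation).
- The dietary rate R is a single constant; real dietary EGT intake
  varies within and between days.
- Sensitivity analysis is local (one parameter at a time, 0.5–2-fold);
  no global variance decomposition.
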