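# Methods

## Binding equilibrium

Free hydrocortisone *F* equilibrates with three independent single-site
binders — albumin, intact CBG (CBGi) and elastase-cleaved CBG (CBGe) — so

TotF = F · (1 + TotA/(K_A+F) + TotCi/(K_Ci+F) + TotCe/(K_Ce+F)),

with all concentrations in nmol/L.  The dissociation constants default to
K_A = 330 000 nM, K_Ci = 33 nM, K_Ce = 330 nM.  The assignment of 33 vs
330 nM to the intact and cleaved pools follows the physiology (cleaved CBG
binds ~10-fold more weakly, hence the larger Kd); the opposite, literal
ordering found in some published parameter listings is available through
`BindingConstants.printed_assignment()` / the `binding.printed_assignment`
config switch for sensitivity analyses, and is logged as inconsistent when
selected.  The CBG pool is split by the cleaved fraction RC ∈ [0,1]:
CBGe = RC·CBG, CBGi = (1−RC)·CBG.

The forward map is strictly increasing with TotF ≥ F, so the inverse
(`free_from_total`) is found by Brent's method on the bracket [0, TotF]
(xtol 1e-12; round-trip accuracy is held to ≤1e-8 relative and tested over
randomised milieus).  At F = 0 the unbound fraction uses its analytic
dilute limit 1/(1 + Σ TotP/K_P) rather than 0/0.

## Kinetics ("free mode")

One compartment, linear in the free drug: dA/dt = input(t) − (CL/V)·A with
C_free = A/V.  Elimination is driven by the free concentration; protein
binding is an instantaneous, non-mass-tracked observation transform.  This
reading is the only one consistent with free-mode operation at V ≈ 405 L
and CL ≈ 226 L/h for a drug whose total plasma levels sit in the hundreds
of nM: the large apparent volume belongs to the free scale, and tracking
bound mass in the compartment would double-count the buffer.

Dose inputs are first-order (Bateman; optional dissolution lag; analytic
ka→k limit F·D·k·τ·e^(−kτ)/V engaged when |ka−k|/k < 1e-9) or zero-order
(constant-rate release over amount/rate hours, standard infusion
solution).  Multi-dose profiles are exact closed-form superpositions, and
a test pins them against piecewise adaptive ODE integration to ≤1e-6
relative.  Doses in mg convert to nmol with M = 362.46 g/mol.

Steady state under a 24-h-periodic regimen is obtained by replicating the
regimen over 7 preceding days and reading the final day; the free-scale
half-life is ~1.25 h, so the residual periodicity error is ~e^(−7·24·k),
far below 1e-6 (asserted by comparing 7- vs 8-day run-in).  Profiles are
evaluated on a 0.05 h grid by default; AUC is trapezoidal with endpoint
interpolation.  The fixed structural constants are ka = 0.7 h⁻¹, tlag = 0
(neither is reported for the fitted immediate-release model; both
overridable in config) and F_bio = 0.96.

## Population estimation (ITSB)

Inter-individual variability: log-normal for V and CL, logit-normal for RC
so individual values respect [0,1].  "Typical" value = median
(back-transformed mean of the transformed scale).  CV% is
√(exp(ω²)−1)·100 for log-normal components; the logit-normal CV has no
closed form and is computed by 201-node Gauss-Hermite quadrature (the
inverse problem — which logit-SD produces a requested CV — is solved by
bracketing, e.g. ≈1.132 for CV 85% at median 0.13).

Each iteration runs two stages:

1. **Individual stage.**  Per subject, minimise
   Σ ½[(y−f)²/v + ln v] + Σ ½(t_k−t_k(μ))²/ω_k² over the transformed
   parameters, with v = σ_add² + (σ_prop·f)².  Free-analyte observations
   are predicted directly; total-analyte observations through the forward
   isotherm (no inversion in the likelihood).  The optimiser is
   Nelder-Mead on the transformed scale, warm-started from the previous
   iteration, and never returns a point worse than its start.  The MAP
   point is then refined to the **posterior mean and variance by adaptive
   Gauss-Hermite quadrature** (5 nodes/dimension, grid centred on the MAP
   and scaled by the Cholesky factor of the inverse Hessian).  This
   refinement matters: with two blood draws per visit the likelihood is
   approximately Gaussian in RC itself, so in logit space the posterior of
   a low-RC subject is strongly right-skewed and the raw MAP point is
   biased upward; the posterior mean is not.  Setting
   `FitSettings(individual_estimator="map")` restores the plain MAP
   two-stage for comparison.

2. **Population stage.**  μ = back-transformed mean of the individual
   estimates.  ω² = mean over subjects of (deviation² + posterior
   variance) — the EM-type update.  The posterior-variance term is what
   keeps ω from collapsing: a subject whose data say nothing about a
   parameter contributes its prior variance, not a shrunken-to-zero
   deviation.  `omega_method="sd"` gives the plain sample-SD update
   (exposed as `update_population`).

Convergence: largest relative change of any (μ, ω) component < 1e-4, cap
50 iterations.  The loop is deterministic — identical dataset and settings
give a bitwise-identical trace.  Residual parameters stay fixed by default
(the combined 1.1 nM + 9.5 % model); with `reestimate_residual=True` they
are re-estimated each iteration by pooled maximum likelihood over all
residuals, which is only well identified under rich sampling.  The
additive SD is interpreted as 1.1 on the nM observation scale: the
published "mg/mL" unit is dimensionally implausible for plasma cortisol
(five orders of magnitude above the measurements) and is treated as a
misprint, with the value exposed purely as a config entry.

Shrinkage is reported as 100·(1 − SD(η)/ω) per parameter, clipped to
[0, 100], and undefined (missing) when ω = 0.  Weighted residuals are
(y−f)/√(σ_add²+(σ_prop f)²) at both population and individual parameters.

Starting values for the fit are the earlier model's V = 474 L and
CL = 236 L/h with their CVs (54 %, 46 %); that model has no RC, so the fit
starts RC at 0.20 with a logit-SD of 1.0 (implementer defaults — wide
enough not to pin the estimate, and re-estimated from the first iteration
on).

## Synthetic cohorts

The generator emulates the crossover design that motivated the model:
46 subjects by default, randomised to low (0.2–0.3 mg/kg/day) then high
(0.4–0.6) dosing or the reverse, three divided doses at 7:00/13:00/19:00
split 4:2:1 and rounded to 0.5 mg, three run-in days before each visit
(≈58 free-scale half-lives, so kinetic steady state to machine precision),
one blood draw 1 h after the 7:00 visit-day dose and a second 5–6 h later
(uniform jitter), each assayed for free and total drug with combined
additive+proportional noise truncated at zero.  A rich variant
(`rich_design()`, 12 draws per period spanning 0.5–11.5 h post-dose)
exists for residual-error work.  Periods are separated by a 7-day gap;
carry-over is nil at this half-life.

Individual (V, CL, RC) are drawn from the population model above.
Covariates are implementer defaults, physiologically typical and not taken
from any study table: weight ~ N(80, 15²) kg truncated to [50, 120];
albumin ~ log-normal, median 600 000 nM, CV 10 %; total CBG ~ log-normal,
median 700 nM, CV 20 %.  The ground truth of every generated cohort is
returned alongside the dataset for recovery scoring, and generation is
byte-reproducible per seed.

What the generator does **not** emulate — and hence what passing recovery
tests cannot show — includes endogenous residual cortisol secretion, CBG
circadian rhythm, steroid competition for CBG, assay-specific error
structure, dropout and dose-doubling during illness, and any covariate
correlation between weight, albumin and CBG.  Recovery results certify the
estimator under the assumed model, not the model against real patients;
the published real-data correlations are in that sense not reproducible
here.

## Calibration experiments

The acceptance experiments regenerate cohorts from the published
population values as ground truth (V 405 L CV 55 %, CL 226 L/h CV 51 %,
RC 0.13 CV 85 %, residual 1.1 nM + 9.5 %) and refit with ITSB initialised
at the earlier model's values, averaging five seeds: typical V, CL, RC at
the study size n = 46; CV% of V at n = 200 (variability needs more
subjects than typical values); and the proportional residual SD on the
rich design with re-estimation enabled.  Problem sizes were chosen as the
smallest that make the Monte-Carlo error of a 5-seed mean comfortably
smaller than the corresponding acceptance band.

## Known limitations

- ITSB is an approximate ML scheme; a full-likelihood mixed-effects fit
  (FOCE/SAEM) is out of scope.  The quadrature-EM refinement removes the
  dominant small-sample biases but inherits the Laplace centring.
- One shared residual model for both analytes (an analyte-specific term
  would be a config extension; the data the design yields cannot separate
  them under sparse sampling).
- The AUC24 window is integrated over the steady-state day [0, 24); for a
  periodic profile this equals any 24-h anchor up to grid resolution.
- The modified-release reference regimen places its peak near 4:40
  (23:00 dose + 4 h lag + ln(ka/k)/(ka−k) ≈ 1.6 h), i.e. slightly before
  the physiological 7:00 peak; matching the endogenous acrophase exactly
  would need a ~6.5 h lag.
- V and CL are treated as absolute per-subject values (no allometric
  weight scaling), matching how the reference values are reported.
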