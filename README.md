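# hcpk — hydrocortisone population PK with explicit plasma protein binding

Patients with secondary adrenal insufficiency replace their missing
cortisol with oral hydrocortisone (HC).  Most of the drug in plasma is not
free: it rides on corticosteroid-binding globulin (CBG, high affinity, low
capacity — and partly present in an elastase-**cleaved** state with ~10-fold
weaker binding) and on albumin (low affinity, high capacity).  Only the free
fraction is pharmacologically active, and because CBG saturates at
therapeutic concentrations the unbound fraction *f*u changes over the
dosing day.  `hcpk` is a library for pharmacometricians who want to model
free and total HC jointly instead of fitting them as two separate drugs.

## The model

**Binding.**  Each protein P ∈ {albumin, CBGi, CBGe} is an independent
single-site binder with dissociation constant *K*ₚ, so total drug at free
concentration *F* is

    TotF = F · (1 + TotA/(K_A+F) + TotCi/(K_Ci+F) + TotCe/(K_Ce+F))

with *K*_A = 330 000 nM, *K*_Ci = 33 nM, *K*_Ce = 330 nM and the CBG pool
split by the cleaved fraction RC: CBGe = RC·CBG, CBGi = (1−RC)·CBG.

**Kinetics ("free mode").**  One compartment, linear in the free drug:
dA/dt = input(t) − (CL/V)·A, C_free = A/V, with first-order (Bateman,
optional dissolution lag) or zero-order (extended-release) absorption and
bioavailability 0.96.  Elimination is driven by the free concentration; the
total concentration is an instantaneous transform of the free one through
the isotherm above.  Multi-dose profiles are exact closed-form
superpositions.

**Estimation.**  Individual parameters (V, CL, RC) carry log-normal /
log-normal / logit-normal inter-individual variability.  The population fit
is iterative two-stage Bayesian (ITSB): per-subject MAP estimates under the
current population prior (refined to adaptive Gauss-Hermite posterior
means), then a population moment update with an EM-type variance
correction, alternated to convergence.  The residual model is combined
additive (1.1 nM) + proportional (9.5 %).

Because the underlying clinical dataset is not public, the package ships a
synthetic-cohort generator that emulates the study design (46 subjects,
low-dose 0.2–0.3 then high-dose 0.4–0.6 mg/kg/day crossover, three divided
doses, two blood draws per visit assayed for both free and total HC), so
the whole pipeline is testable by simulation-based calibration.

## Worked example

`examples/04_cohort_fit.py` simulates a 20-subject cohort from the
published population values (V 405 L, CL 226 L/h, RC 0.13) and refits it:

```
simulated 20 subjects, 160 observations
converged in 35 iterations
               recovered     truth
typical V         460.3     405.0 L
typical CL        215.6     226.0 L/h
typical RC        0.127     0.130
CV% V              39.3      55.0
shrinkage %  V=1.6, CL=0.0, RC=25.1
GOF Spearman r: individual 0.9955, population 0.9626 (n=160)
free-vs-total AUC24 Spearman r = 0.926 [0.842, 0.968], n=40 subject-periods
```

The recovered typical values sit close to the generating truth (a single
20-subject replicate still carries visible sampling noise — the acceptance
experiments below average 5 replicates at n = 46); individual predictions
track the observations almost perfectly while population predictions are
looser, and the free-vs-total exposure correlation is below 1 because
subjects differ in albumin, CBG and RC.  The other examples print the
binding curve (`01`), a typical patient's steady-state day under 10-5-2.5 mg
dosing including the *f*u swing (`02`), and the two-dose modified-release
design that restores the early-morning cortisol rise (`03`).

A thin CLI wraps the same workflows:

```bash
hcpk generate --out run1        # dataset.csv + truth.csv
hcpk fit run1/dataset.csv --out run1
hcpk simulate modified --out run1
hcpk recover --seed 7 --out run1
hcpk config                     # resolved defaults
```

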