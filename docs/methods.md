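# Methods

## Model structure and assumptions

The model is a linear, time-invariant compartment network over drug amounts
(mg), with internal units h / L / mg / mg·L⁻¹. Every transfer is a directed
clearance edge `flux = CL × C_driving(source)`, where the driving
concentration is the source's total, plasma-equivalent or unbound
concentration depending on mechanism:

- blood flow carries total blood concentration;
- glomerular filtration, tubular secretion and non-renal clearance are
  plasma clearances (flux = CL × C_plasma), so the tabulated clearances are
  used without re-scaling;
- all passive exchange between blood and extravascular water is driven by
  unbound concentrations. Interstitial and tubular fluid are treated as
  fully unbound (microdialysis samples unbound drug; both drugs are polar
  with negligible tissue binding). Unbound plasma is
  `fu × C_blood / (blood:plasma ratio)`.

Perfusion-limited organs (lungs, adipose, liver, rest of body) emit
out-flowing blood in equilibrium with tissue, `C_out = BP × C_t / Kp`.
Muscle is permeability-limited with three spaces and symmetric passive
clearances; with no muscle elimination this forces the muscle-interstitium
to unbound-plasma AUC(0–∞) ratio to exactly 1 — the control-tissue
property the whole design relies on, asserted in tests rather than fitted.

The kidney has four regions (cortex, outer medulla, inner medulla 1 and 2).
Regional blood follows a serial medullary chain: 8% of renal blood flow
continues from cortex into the outer medulla, 1.5% into inner medulla 1 and
0.5% into inner medulla 2, the remainder returning directly (standard renal
physiology; configurable). Each tubule segment exchanges only with its host
region's interstitium: cortex hosts PT1–3, DT and CD1–3; outer medulla
DLH, ALH and CD4–6; inner medulla 1 CD7–8; inner medulla 2 CD9. The
ascending limb is water-impermeable; the water-remaining profile (fraction
of GFR still flowing at segment exit) falls from 0.70/0.50/0.34 across the
proximal segments to 0.17 at the descending limb, 0.10 after the distal
tubule, then geometrically down to urine flow / GFR at CD9. Reabsorbed
water leaves without drug, concentrating the filtrate; drug leaves the
lumen only by flow and by transcellular permeation.

## Parameters

| Parameter | Default | Unit | Origin |
|---|---|---|---|
| Tubular Papp apical→basal (CAZ / AVI) | 1.44e-6 / 2.53e-6 | cm/s | LLC-PK1 monolayer transport |
| Tubular Papp basal→apical (CAZ / AVI) | 3.10e-6 / 5.21e-6 | cm/s | LLC-PK1 monolayer transport |
| Vascular P blood→interstitium | 100e-6 | cm/s | fixed fast reference |
| Vascular P interstitium→blood (CAZ rat/pig) | 33.8e-6 / 31.5e-6 | cm/s | in vivo estimate |
| Vascular P interstitium→blood (AVI rat/pig) | 18.5e-6 / 16.4e-6 | cm/s | in vivo estimate |
| fu (CAZ / AVI) | 0.90 / 0.92 | – | literature protein binding ~10% / 8% |
| Blood:plasma ratio (CAZ / AVI) | 0.82 / 0.57 | – | fixed constants |
| Kp lungs/adipose/liver/rest | 0.5 / 0.05 / 0.4 / 0.2 | – | extracellular-restricted distribution of polar drugs |
| Muscle cell:water partition | 0.1 | – | cell exclusion of polar drugs |
| Muscle PS clearance | 10 × Q_muscle | L/h | near-flow-limited; muscle and blood profiles superimpose |
| GFR rat / pig / human | 0.171 / 6.6 / 7.2 | L/h | species physiology; human = 120 mL/min CrCL |
| Urine flow | 1.2–1.5% of GFR | L/h | species physiology |

Per-species clearance estimates (glomerular, secretion, non-renal) are
stored in the drug configs under `fitted:` and selected with
`load_drug_parameters(name, species=...)`.

**Permeability scale.** The fixed "100" reference and the fitted
interstitium→blood permeabilities are interpreted on the same 1e-6 cm/s
scale as the measured tubular Papp values. Only the ratio of the vascular
pair and the products permeability × surface matter to the model; on this
common scale the vascular reference (1e-4 cm/s) is fast relative to every
tissue process — its equilibration time against the cortex interstitial
volume is seconds — while remaining physically meaningful for a continuous
endothelium, and the tubular and vascular exchange terms compete as they
must for the interstitium to deviate from pure vascular equilibrium.

**Kidney geometry.** The supplement-level anatomy is rebuilt from nephron
morphometry (`scripts/generate_default_configs.py`): segment surface
`π·d·L·N` and lumen volume per species nephron number (64 000 rat,
2.4 million pig, 2.0 million human, both kidneys), with the collecting duct
as nine successive fusion events (duct count halving, diameter growing
25% per level). Regional vascular exchange surface defaults to half the
summed tubular surface of the region — peritubular capillaries are apposed
to the tubules and morphometric apposition fractions are about one half —
rather than to a free specific-surface constant; it is configurable per
region. Regional volumes split the kidney 70/20/7/3% from cortex inward
with literature blood and interstitial volume fractions.

## Numerics

Between dose events the system matrix is constant, so the default
integrator is exact piecewise matrix-exponential propagation: boluses are
state jumps, infusions enter through an augmented constant-input matrix,
and repeated identical steps reuse one cached `expm`. This is
machine-precision accurate for an LTI system, unconditionally stable
despite the stiffness from the fast vascular exchange, and fast enough for
multi-start fitting (one rat simulation ≈ 2 ms). A stiff adaptive LSODA
backend (rtol 1e-8, atol 1e-10) integrates the same equations as an
independent numerical route; the two agree to ~1e-5 in tests. AUCs are
co-integrated as augmented states (grid-independent, exact at output
times), and the algebraic AUC(0–∞) of the integrated mass balance
(`a = -A⁻¹·dose`, one linear solve, no time stepping) serves as a third,
fully independent oracle for AUC ratios. Mass balance (dose = compartments
+ sinks) holds to ≤1e-6 at all times on all shipped configurations.

%fT>threshold locates crossing times by Brent root-finding on a monotone
cubic (PCHIP) interpolant of the final-interval profile, not by grid
counting. Steady state is declared when the last two dosing intervals
differ by <1% at the peak scale (4 days q8h is >40 half-lives for both
drugs; observed periodicity <0.1%).

## Estimation and uncertainty

Fitting is per animal: proportional-error weighted least squares between
recovery-corrected concentrations and model interval averages, on
log-transformed parameters (positivity by construction) with bound
constraints and deterministic multi-start (default 5 starts, log-normal
perturbations of the initial values). Default free parameters mirror the
estimated rows of the parameter tables: {CL_glomerular, P_i2b} for
ceftazidime in rats, plus CL_nonrenal in pigs; {CL_glomerular,
CL_secretion, P_i2b} for avibactam in both species. Residual coefficients
are estimated per probe site. Cohorts are summarized as across-animal
medians; per-animal uncertainty propagates through 1000 multivariate
log-normal parameter draws (nearest-PSD repair by eigenvalue clipping if
needed) simulated 0–100 h each, with percentile 2.5/97.5 CIs.

The parameter covariance is the inverse Gauss–Newton Fisher information
(central finite-difference sensitivities at the optimum), with two
corrections found necessary for honest interval coverage:

1. an `n/(n−p)` small-sample inflation of the plug-in residual variances;
2. delta-method propagation of the recovery-calibration error: corrected
   concentrations share one multiplicative error per probe (the mean RL is
   estimated from only three retrodialysis intervals), which is invisible
   to residual-based information. Its variance — the squared relative
   standard error of the mean recovery — is mapped through the sensitivity
   of the estimates to a per-site scale factor and added to the
   covariance.

Without correction 2, synthetic-cohort coverage of the 95% CIs is ~60%;
with it, ~85% at 10 repetitions.

## What the synthetic data do and do not emulate

The generator reproduces the study design: 5 animals per species, three
probes (jugular/cephalic blood, hind-leg/longissimus muscle, renal cortex),
retrodialysis at the study perfusate concentrations (rat 100/10, pig
50/12.5 µg/mL CAZ/AVI) with 3 × 20-min fractions, washout with no
carryover, species dosing (rat 20/5 mg/kg bolus; pig 40/10 mg/kg 2-h
infusion) and sampling (rat 10-min × 6 then 30-min × 3; pig 30-min × 12).
True recoveries are drawn from the observed per-tissue means ± SD
(truncated to 20–95%), between-animal parameter variability is log-normal
with 25% CV (consistent with the reported CI widths; the true magnitude is
unreported), and residual error is proportional with 15% CV (the assay's
stated precision bound).

Not emulated: quantification limits and censoring, probe failure or drift,
flow-rate dependence of recovery, within-animal recovery drift between the
retrodialysis and PK phases, and model misspecification (the generating
model is the fitted model). Passing recovery tests therefore demonstrates
estimator correctness under the stated observation model, not robustness
to structural error in real data.

## Human extrapolation

Human physiology replaces animal physiology; kidney vascular
permeabilities keep the pig estimates (the species closer to human renal
anatomy). Clearances are reconstructed rather than copied: glomerular
clearance = fu × GFR (7.2 L/h), avibactam secretion scales from the pig
estimate by the GFR ratio, ceftazidime non-renal clearance scales
allometrically (BW^0.75). The resulting totals (≈6.7 L/h CAZ, ≈11 L/h
AVI) sit in the range of adult clinical values. Attainment is evaluated on
the final 8-h interval of a 4-day q8h schedule of 2-h infusions, for the
standard (2 g/0.5 g) and reduced (1 g/0.25 g) CZA regimens, against 50%
fT>MIC on the doubling grid 1–128 mg/L for ceftazidime and 50% fT>1 mg/L
for avibactam.

## Design choices where the design was open

- **Integrator:** exact matrix exponentials instead of a stiff ODE solver
  as the primary engine (the model is LTI; the stiff solver remains as a
  cross-check backend).
- **Secretion entry:** distributed equally over PT1–3, driven by cortex
  blood plasma concentration (transporter-mediated secretion is proximal;
  finer localization is not identifiable).
- **Non-renal clearance** attaches to the liver and acts on the liver
  plasma-equivalent concentration.
- **Population machinery:** per-animal fits summarized by across-animal
  medians replace nonlinear mixed-effects estimation; the reported
  quantities are per-animal medians, so this reproduces the summaries
  without a population likelihood.
- **fu handling:** unbound fractions act in filtration and all
  blood-to-tissue driving concentrations; dialysate corrections yield
  unbound tissue concentrations directly.
- **Observation time stamps:** fitting always uses interval integrals;
  midpoint plotting is a display convention only.

## Known limitations

- Kidney geometry is a literature-based reconstruction; the cortex AUC
  ratio depends on the balance of tubular to vascular exchange surfaces,
  which is why forward simulations reproduce reported penetration ratios
  to within ~15% rather than exactly.
- Linear kinetics throughout: no transporter saturation, pH-dependent
  reabsorption, or separate short/long nephron populations.
- A single representative subject per species; no virtual-population
  covariate distributions, so attainment results are point predictions,
  not population target-attainment probabilities.
- Kidney-specific PK/PD targets may differ from plasma-derived ones; the
  attainment analysis assumes the plasma targets apply in the
  interstitium.
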