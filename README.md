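# renalpbpk

Physiologically based pharmacokinetic (PBPK) modelling of
ceftazidime–avibactam (CZA) distribution into the renal cortex
interstitium — the target site in pyelonephritis — with a whole-body model
nested around a mechanistic multi-nephron kidney, a microdialysis
observation model, per-animal parameter estimation, and extrapolation to
human dosing with renal PK/PD target attainment.

It is written for pharmacometricians and PK/PD researchers who want to ask:
*given plasma-calibrated dosing targets, what does the kidney interstitium
actually see?*

## The model

The whole body is a linear compartment network over drug amounts,
`dx/dt = A x + u(t)`: venous blood → lungs → arterial blood in series, with
perfusion-limited adipose, liver and rest-of-body, a permeability-limited
three-space muscle (vascular ⇌ interstitial ⇌ cellular, symmetric passive
clearances driven by unbound concentrations), and a nested kidney.

The kidney splits into four anatomical regions (cortex, outer medulla, two
inner medulla zones), each with blood and interstitium compartments, plus a
15-segment tubule chain (PT1–3, DLH, ALH, DT, CD1–9, one collecting-duct
compartment per nephron fusion event). Mechanisms:

- glomerular filtration `CL_glom = fu × GFR` (or a fitted plasma clearance)
  from cortex blood into PT1;
- water reabsorption along the chain (segment exit flow = GFR × water
  remaining fraction, down to urine flow at CD9) concentrating the luminal
  drug;
- transcellular tubular exchange at the directional apparent permeabilities
  measured on LLC-PK1 monolayers, `CL = Papp × S_segment`;
- asymmetric vascular exchange per region: blood → interstitium fixed fast
  (the "100" reference permeability), interstitium → blood slower
  (`P_i2b`, estimated in vivo) — the mechanism behind interstitial
  accumulation;
- optional tubular secretion (avibactam) from cortex blood into the
  proximal lumen, and non-renal clearance from the liver.

Because the system is linear and time-invariant between dose events, the
default integrator propagates the exact solution with matrix exponentials
(boluses as state jumps, infusions as piecewise-constant inputs); AUCs are
co-integrated as extra states. An LSODA backend and an algebraic
AUC(0–∞) oracle (`-A⁻¹·dose`) provide independent cross-checks.

Microdialysis enters through the retrodialysis recovery by loss,
`RL = (C_in − C_out)/C_in × 100`; dialysate concentrations divided by the
mean RL give unbound tissue concentrations, compared against model
*interval averages* (AUC over the collection interval / width). Per-animal
proportional-error least squares on log parameters, with a Gauss–Newton
Fisher information matrix for uncertainty, feeds 1000-draw multivariate
log-normal sampling of derived metrics (AUC ratios, clearance
decomposition) reported as medians with percentile 95% CIs.

## Worked example

Forward-simulate a 20 mg/kg ceftazidime bolus in a 0.33 kg rat at the
estimated median parameters and compute kidney penetration:

```python
import renalpbpk as rp

phys = rp.load_species_physiology("rat")
geom = rp.load_kidney_geometry("rat")
drug = rp.load_drug_parameters("CAZ", species="rat")

net = rp.build_whole_body_model(phys, geom, drug)
res = rp.simulate(net, rp.DoseRegimen.bolus(20 * 0.33), 100.0)

auc_u = rp.compute_auc(res, "auc_unbound_plasma", 0, 100)
auc_m = rp.compute_auc(res, "auc_muscle_interstitium", 0, 100)
auc_k = rp.compute_auc(res, "auc_cortex_interstitium", 0, 100)
print(f"unbound plasma AUC(0-100h):      {auc_u:.1f} mg*h/L")
print(f"muscle interstitium AUC(0-100h): {auc_m:.1f} mg*h/L  (ratio {auc_m/auc_u:.3f})")
print(f"cortex interstitium AUC(0-100h): {auc_k:.1f} mg*h/L  (ratio {auc_k/auc_u:.2f})")
print(f"urine recovery: {res.amount('urine')[-1] / 6.6:.1%} of dose")
```

prints

```
unbound plasma AUC(0-100h):      48.2 mg*h/L
muscle interstitium AUC(0-100h): 48.2 mg*h/L  (ratio 1.000)
cortex interstitium AUC(0-100h): 108.8 mg*h/L  (ratio 2.26)
urine recovery: 100.0% of dose
```

Muscle interstitium is equivalent to unbound plasma (the control tissue),
while the renal cortex interstitium sees ~2.3× the unbound plasma exposure;
the fully renally cleared dose ends in urine.

The same pipeline runs from the shell:

```bash
renalpbpk synth --species rat --drug CAZ --seed 1 --out synth_out   # virtual cohort
renalpbpk fit --data synth_out/dialysate.csv --species rat --seed 1 # recovery->fit->CIs
renalpbpk pta --drug CAZ --dose-mg 1000 --out pta_out               # human %fT>MIC table
```

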