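# Default AVI drug parameter configuration shipped with renalpbpk.
# Literature-based stand-in values; see docs/methods.md for provenance and
# scripts/generate_default_configs.py for the derivation.  Units: h, L, mg,
# cm/s (permeabilities), cm^2 (surfaces).  All values are overridable by
# loading a user file with the same schema.
drug:
  drug_name: AVI
  molecular_weight: 265.2
  fu_plasma: 0.92
  blood_plasma_ratio: 0.57
  papp_lumen_to_interstitium: 2.53e-06
  papp_interstitium_to_lumen: 5.21e-06
  p_blood_to_interstitium: 0.0001
  p_interstitium_to_blood: 1.85e-05
  kp:
    lungs: 0.5
    adipose: 0.05
    liver: 0.4
    rest: 0.2
  cl_nonrenal: 0.0
  cl_tubular_secretion: 0.0612
  cl_glomerular: null
  kp_muscle_cell: 0.1
  muscle_ps_multiplier: 10.0
  source: LLC-PK1 transport assay; extracellular-restricted Kp for a polar diazabicyclooctane
fitted:
  rat:
    cl_glomerular: 0.158
    cl_tubular_secretion: 0.0612
    p_interstitium_to_blood: 1.85e-05
  pig:
    cl_glomerular: 5.71
    cl_tubular_secretion: 3.96
    p_interstitium_to_blood: 1.64e-05
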