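# Default CAZ drug parameter configuration shipped with renalpbpk.
# Literature-based stand-in values; see docs/methods.md for provenance and
# scripts/generate_default_configs.py for the derivation.  Units: h, L, mg,
# cm/s (permeabilities), cm^2 (surfaces).  All values are overridable by
# loading a user file with the same schema.
drug:
  drug_name: CAZ
  molecular_weight: 546.6
  fu_plasma: 0.9
  blood_plasma_ratio: 0.82
  papp_lumen_to_interstitium: 1.44e-06
  papp_interstitium_to_lumen: 3.1e-06
  p_blood_to_interstitium: 0.0001
  p_interstitium_to_blood: 3.38e-05
  kp:
    lungs: 0.5
    adipose: 0.05
    liver: 0.4
    rest: 0.2
  cl_nonrenal: 0.0
  cl_tubular_secretion: 0.0
  cl_glomerular: null
  kp_muscle_cell: 0.1
  muscle_ps_multiplier: 10.0
  source: LLC-PK1 transport assay; extracellular-restricted Kp for a polar cephalosporin
fitted:
  rat:
    cl_glomerular: 0.154
    cl_nonrenal: 0.0
    p_interstitium_to_blood: 3.38e-05
  pig:
    cl_glomerular: 6.41
    cl_nonrenal: 0.14
    p_interstitium_to_blood: 3.15e-05
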