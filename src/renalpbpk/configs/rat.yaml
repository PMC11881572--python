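# Default rat physiology + kidney geometry configuration shipped with renalpbpk.
# Literature-based stand-in values; see docs/methods.md for provenance and
# scripts/generate_default_configs.py for the derivation.  Units: h, L, mg,
# cm/s (permeabilities), cm^2 (surfaces).  All values are overridable by
# loading a user file with the same schema.
species:
  species_name: rat
  body_weight: 0.33
  cardiac_output: 5.0
  blood_flows:
    adipose: 0.35
    muscle: 0.85
    liver: 0.9
    kidney: 0.7
    rest: 2.2
  organ_volumes:
    venous_blood: 0.0135
    arterial_blood: 0.0065
    lungs: 0.0015
    adipose: 0.023
    muscle_vascular: 0.004
    muscle_interstitial: 0.016
    muscle_cellular: 0.112
    liver: 0.0135
    rest: 0.13
  hematocrit: 0.45
  gfr: 0.171
  urine_flow: 0.0026
  medullary_blood_flow_fractions:
    outer_medulla: 0.08
    inner_medulla_1: 0.015
    inner_medulla_2: 0.005
  source: laboratory-rat physiology compendia (Brown et al. 1997 scale)
kidney_geometry:
  regions:
    cortex:
      blood_volume: 0.000462
      interstitial_volume: 0.00024024
      vascular_exchange_surface: 388.389209
    outer_medulla:
      blood_volume: 0.0001056
      interstitial_volume: 0.0001056
      vascular_exchange_surface: 148.552636
    inner_medulla_1:
      blood_volume: 2.772e-05
      interstitial_volume: 5.544e-05
      vascular_exchange_surface: 0.547716
    inner_medulla_2:
      blood_volume: 1.188e-05
      interstitial_volume: 3.168e-05
      vascular_exchange_surface: 0.131662
  segments:
    PT1:
      surface_area: 167.551608
      lumen_volume: 0.00010472
      region: cortex
      water_fraction_exit: 0.7
    PT2:
      surface_area: 167.551608
      lumen_volume: 0.00010472
      region: cortex
      water_fraction_exit: 0.5
    PT3:
      surface_area: 167.551608
      lumen_volume: 0.00010472
      region: cortex
      water_fraction_exit: 0.34
    DLH:
      surface_area: 90.477868
      lumen_volume: 3.39292e-05
      region: outer_medulla
      water_fraction_exit: 0.17
    ALH:
      surface_area: 201.06193
      lumen_volume: 0.000100531
      region: outer_medulla
      water_fraction_exit: 0.17
    DT:
      surface_area: 251.327412
      lumen_volume: 0.00015708
      region: cortex
      water_fraction_exit: 0.1
    CD1:
      surface_area: 11.309734
      lumen_volume: 8.4823e-06
      region: cortex
      water_fraction_exit: 0.0811163839
    CD2:
      surface_area: 7.068583
      lumen_volume: 6.6268e-06
      region: cortex
      water_fraction_exit: 0.0657986774
    CD3:
      surface_area: 4.417865
      lumen_volume: 5.17719e-06
      region: cortex
      water_fraction_exit: 0.0533735077
    CD4:
      surface_area: 2.761165
      lumen_volume: 4.04468e-06
      region: outer_medulla
      water_fraction_exit: 0.0432946594
    CD5:
      surface_area: 1.725728
      lumen_volume: 3.1599e-06
      region: outer_medulla
      water_fraction_exit: 0.0351190622
    CD6:
      surface_area: 1.07858
      lumen_volume: 2.46867e-06
      region: outer_medulla
      water_fraction_exit: 0.0284873133
    CD7:
      surface_area: 0.674113
      lumen_volume: 1.92865e-06
      region: inner_medulla_1
      water_fraction_exit: 0.0231078784
    CD8:
      surface_area: 0.42132
      lumen_volume: 1.50676e-06
      region: inner_medulla_1
      water_fraction_exit: 0.0187442754
    CD9:
      surface_area: 0.263325
      lumen_volume: 1.17716e-06
      region: inner_medulla_2
      water_fraction_exit: 0.0152046784
  source: nephron morphometry (segment surface pi*d*L*N, nine CD fusion events) after
    Li 2017 / Huang & Isoherranen 2018 / Scotcher 2017; vascular exchange surface
    = 0.5 x regional tubular surface
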