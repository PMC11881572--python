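# Default pig physiology + kidney geometry configuration shipped with renalpbpk.
# Literature-based stand-in values; see docs/methods.md for provenance and
# scripts/generate_default_configs.py for the derivation.  Units: h, L, mg,
# cm/s (permeabilities), cm^2 (surfaces).  All values are overridable by
# loading a user file with the same schema.
species:
  species_name: pig
  body_weight: 40.0
  cardiac_output: 240.0
  blood_flows:
    adipose: 12.0
    muscle: 60.0
    liver: 60.0
    kidney: 48.0
    rest: 60.0
  organ_volumes:
    venous_blood: 1.7
    arterial_blood: 0.9
    lungs: 0.4
    adipose: 6.0
    muscle_vascular: 0.5
    muscle_interstitial: 2.0
    muscle_cellular: 13.5
    liver: 0.9
    rest: 13.0
  hematocrit: 0.4
  gfr: 6.6
  urine_flow: 0.08
  medullary_blood_flow_fractions:
    outer_medulla: 0.08
    inner_medulla_1: 0.015
    inner_medulla_2: 0.005
  source: growing-pig physiology (Upton 2008 scale)
kidney_geometry:
  regions:
    cortex:
      blood_volume: 0.04375
      interstitial_volume: 0.02275
      vascular_exchange_surface: 18948.957876
    outer_medulla:
      blood_volume: 0.01
      interstitial_volume: 0.01
      vascular_exchange_surface: 7513.653136
    inner_medulla_1:
      blood_volume: 0.002625
      interstitial_volume: 0.00525
      vascular_exchange_surface: 31.950131
    inner_medulla_2:
      blood_volume: 0.001125
      interstitial_volume: 0.003
      vascular_exchange_surface: 7.68032
  segments:
    PT1:
      surface_area: 9047.786842
      lumen_volume: 0.00678584
      region: cortex
      water_fraction_exit: 0.7
    PT2:
      surface_area: 9047.786842
      lumen_volume: 0.00678584
      region: cortex
      water_fraction_exit: 0.5
    PT3:
      surface_area: 9047.786842
      lumen_volume: 0.00678584
      region: cortex
      water_fraction_exit: 0.34
    DLH:
      surface_area: 5654.866776
      lumen_volume: 0.00212058
      region: outer_medulla
      water_fraction_exit: 0.17
    ALH:
      surface_area: 9047.786842
      lumen_volume: 0.00452389
      region: outer_medulla
      water_fraction_exit: 0.17
    DT:
      surface_area: 9424.777961
      lumen_volume: 0.00589049
      region: cortex
      water_fraction_exit: 0.1
    CD1:
      surface_area: 659.734457
      lumen_volume: 0.000577268
      region: cortex
      water_fraction_exit: 0.079099144
    CD2:
      surface_area: 412.334036
      lumen_volume: 0.00045099
      region: cortex
      water_fraction_exit: 0.0625667458
    CD3:
      surface_area: 257.708772
      lumen_volume: 0.000352336
      region: cortex
      water_fraction_exit: 0.0494897603
    CD4:
      surface_area: 161.067983
      lumen_volume: 0.000275263
      region: outer_medulla
      water_fraction_exit: 0.0391459768
    CD5:
      surface_area: 100.667489
      lumen_volume: 0.000215049
      region: outer_medulla
      water_fraction_exit: 0.0309641325
    CD6:
      surface_area: 62.917181
      lumen_volume: 0.000168007
      region: outer_medulla
      water_fraction_exit: 0.0244923638
    CD7:
      surface_area: 39.323238
      lumen_volume: 0.000131255
      region: inner_medulla_1
      water_fraction_exit: 0.0193732501
    CD8:
      surface_area: 24.577024
      lumen_volume: 0.000102543
      region: inner_medulla_1
      water_fraction_exit: 0.015324075
    CD9:
      surface_area: 15.36064
      lumen_volume: 8.0112e-05
      region: inner_medulla_2
      water_fraction_exit: 0.0121212121
  source: nephron morphometry (segment surface pi*d*L*N, nine CD fusion events) after
    Li 2017 / Huang & Isoherranen 2018 / Scotcher 2017; vascular exchange surface
    = 0.5 x regional tubular surface
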