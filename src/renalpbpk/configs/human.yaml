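# Default human physiology + kidney geometry configuration shipped with renalpbpk.
# Literature-based stand-in values; see docs/methods.md for provenance and
# scripts/generate_default_configs.py for the derivation.  Units: h, L, mg,
# cm/s (permeabilities), cm^2 (surfaces).  All values are overridable by
# loading a user file with the same schema.
species:
  species_name: human
  body_weight: 70.0
  cardiac_output: 312.0
  blood_flows:
    adipose: 16.0
    muscle: 53.0
    liver: 78.0
    kidney: 60.0
    rest: 105.0
  organ_volumes:
    venous_blood: 3.5
    arterial_blood: 1.7
    lungs: 0.5
    adipose: 13.0
    muscle_vascular: 0.9
    muscle_interstitial: 3.5
    muscle_cellular: 24.6
    liver: 1.8
    rest: 20.0
  hematocrit: 0.45
  gfr: 7.2
  urine_flow: 0.09
  medullary_blood_flow_fractions:
    outer_medulla: 0.08
    inner_medulla_1: 0.015
    inner_medulla_2: 0.005
  source: reference-adult physiology (ICRP 2002 scale)
kidney_geometry:
  regions:
    cortex:
      blood_volume: 0.05425
      interstitial_volume: 0.02821
      vascular_exchange_surface: 22311.443763
    outer_medulla:
      blood_volume: 0.0124
      interstitial_volume: 0.0124
      vascular_exchange_surface: 8675.545791
    inner_medulla_1:
      blood_volume: 0.003255
      interstitial_volume: 0.00651
      vascular_exchange_surface: 38.035871
    inner_medulla_2:
      blood_volume: 0.001395
      interstitial_volume: 0.00372
      vascular_exchange_surface: 9.143238
  segments:
    PT1:
      surface_area: 11728.612573
      lumen_volume: 0.0117286
      region: cortex
      water_fraction_exit: 0.7
    PT2:
      surface_area: 11728.612573
      lumen_volume: 0.0117286
      region: cortex
      water_fraction_exit: 0.5
    PT3:
      surface_area: 11728.612573
      lumen_volume: 0.0117286
      region: cortex
      water_fraction_exit: 0.34
    DLH:
      surface_area: 5654.866776
      lumen_volume: 0.00212058
      region: outer_medulla
      water_fraction_exit: 0.17
    ALH:
      surface_area: 11309.733553
      lumen_volume: 0.00565487
      region: outer_medulla
      water_fraction_exit: 0.17
    DT:
      surface_area: 7853.981634
      lumen_volume: 0.00490874
      region: cortex
      water_fraction_exit: 0.1
    CD1:
      surface_area: 785.398163
      lumen_volume: 0.000785398
      region: cortex
      water_fraction_exit: 0.0793700526
    CD2:
      surface_area: 490.873852
      lumen_volume: 0.000613592
      region: cortex
      water_fraction_exit: 0.0629960525
    CD3:
      surface_area: 306.796158
      lumen_volume: 0.000479369
      region: cortex
      water_fraction_exit: 0.05
    CD4:
      surface_area: 191.747598
      lumen_volume: 0.000374507
      region: outer_medulla
      water_fraction_exit: 0.0396850263
    CD5:
      surface_area: 119.842249
      lumen_volume: 0.000292584
      region: outer_medulla
      water_fraction_exit: 0.0314980262
    CD6:
      surface_area: 74.901406
      lumen_volume: 0.000228581
      region: outer_medulla
      water_fraction_exit: 0.025
    CD7:
      surface_area: 46.813379
      lumen_volume: 0.000178579
      region: inner_medulla_1
      water_fraction_exit: 0.0198425131
    CD8:
      surface_area: 29.258362
      lumen_volume: 0.000139515
      region: inner_medulla_1
      water_fraction_exit: 0.0157490131
    CD9:
      surface_area: 18.286476
      lumen_volume: 0.000108996
      region: inner_medulla_2
      water_fraction_exit: 0.0125
  source: nephron morphometry (segment surface pi*d*L*N, nine CD fusion events) after
    Li 2017 / Huang & Isoherranen 2018 / Scotcher 2017; vascular exchange surface
    = 0.5 x regional tubular surface
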