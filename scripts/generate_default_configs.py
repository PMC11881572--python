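"""Regenerate the shipped default configuration files under src/renalpbpk/configs.

Default values are literature-based renal-physiology and whole-body PBPK
stand-ins (mechanistic kidney models of Li et al. 2017, Huang & Isoherranen
2018, Scotcher et al. 2017; standard species physiology compendia).  The
kidney geometry is derived from nephron morphometry: per-segment luminal
surface S = pi * d * L * N and volume V = pi * (d/2)^2 * L * N, with the
collecting-duct chain modelled as nine successive fusion events (duct count
halving, diameter growing).  Regional vascular exchange surface defaults to
half the summed tubular surface of the region (peritubular capillary
apposition fraction ~0.5).

Run from the repository root:  python scripts/generate_default_configs.py
"""

from __future__ import annotations

import math
from pathlib import Path

import yaml

OUT = Path(__file__).resolve().parents[1] / "src" / "renalpbpk" / "configs"

SEGMENT_ORDER = (
    "PT1", "PT2", "PT3", "DLH", "ALH", "DT",
    "CD1", "CD2", "CD3", "CD4", "CD5", "CD6", "CD7", "CD8", "CD9",
)

REGION_OF = {
    "PT1": "cortex", "PT2": "cortex", "PT3": "cortex", "DT": "cortex",
    "CD1": "cortex", "CD2": "cortex", "CD3": "cortex",
    "DLH": "outer_medulla", "ALH": "outer_medulla",
    "CD4": "outer_medulla", "CD5": "outer_medulla", "CD6": "outer_medulla",
    "CD7": "inner_medulla_1", "CD8": "inner_medulla_1",
    "CD9": "inner_medulla_2",
}

# Fraction of GFR still flowing at segment exit (classic water-reabsorption
# profile: ~2/3 reabsorbed in the proximal tubule, descending limb to ~17%,
# ascending limb water-impermeable, distal tubule to ~10%, collecting duct
# geometric down to urine flow).
WATER_EXIT = {"PT1": 0.70, "PT2": 0.50, "PT3": 0.34, "DLH": 0.17, "ALH": 0.17, "DT": 0.10}

# Morphometry: nephron number (both kidneys) and tubule dimensions (cm).
MORPHOMETRY = {
    "rat": dict(
        nephrons=64_000,
        pt_length=1.0, pt_diameter=0.0025,
        dlh_length=0.30, dlh_diameter=0.0015,
        alh_length=0.50, alh_diameter=0.0020,
        dt_length=0.50, dt_diameter=0.0025,
        cd_length=0.15, cd_diameter0=0.0030,
        kidney_volume=0.00264,
    ),
    "pig": dict(
        nephrons=2_400_000,
        pt_length=1.2, pt_diameter=0.0030,
        dlh_length=0.50, dlh_diameter=0.0015,
        alh_length=0.60, alh_diameter=0.0020,
        dt_length=0.50, dt_diameter=0.0025,
        cd_length=0.20, cd_diameter0=0.0035,
        kidney_volume=0.25,
    ),
    "human": dict(
        nephrons=2_000_000,
        pt_length=1.4, pt_diameter=0.0040,
        dlh_length=0.60, dlh_diameter=0.0015,
        alh_length=0.90, alh_diameter=0.0020,
        dt_length=0.50, dt_diameter=0.0025,
        cd_length=0.25, cd_diameter0=0.0040,
        kidney_volume=0.31,
    ),
}

REGION_VOLUME_FRACTION = {
    "cortex": 0.70, "outer_medulla": 0.20,
    "inner_medulla_1": 0.07, "inner_medulla_2": 0.03,
}
REGION_BLOOD_FRACTION = {
    "cortex": 0.25, "outer_medulla": 0.20,
    "inner_medulla_1": 0.15, "inner_medulla_2": 0.15,
}
REGION_INTERSTITIAL_FRACTION = {
    "cortex": 0.13, "outer_medulla": 0.20,
    "inner_medulla_1": 0.30, "inner_medulla_2": 0.40,
}
CAPILLARY_APPOSITION = 0.5  # vascular exchange surface / tubular surface

PHYSIOLOGY = {
    "rat": dict(
        species_name="rat",
        body_weight=0.33,           # kg, mid-range of a 300-350 g cohort
        cardiac_output=5.0,         # L/h (~83 mL/min)
        blood_flows={"adipose": 0.35, "muscle": 0.85, "liver": 0.90,
                     "kidney": 0.70, "rest": 2.20},
        organ_volumes={"venous_blood": 0.0135, "arterial_blood": 0.0065,
                       "lungs": 0.0015, "adipose": 0.023,
                       "muscle_vascular": 0.004, "muscle_interstitial": 0.016,
                       "muscle_cellular": 0.112, "liver": 0.0135, "rest": 0.130},
        hematocrit=0.45,
        gfr=0.171,                  # L/h (~2.85 mL/min)
        urine_flow=0.0026,          # L/h (~1.5% of GFR)
        medullary_blood_flow_fractions={"outer_medulla": 0.08,
                                        "inner_medulla_1": 0.015,
                                        "inner_medulla_2": 0.005},
        source="laboratory-rat physiology compendia (Brown et al. 1997 scale)",
    ),
    "pig": dict(
        species_name="pig",
        body_weight=40.0,
        cardiac_output=240.0,       # L/h (~4 L/min, ~100 mL/min/kg juvenile pig)
        blood_flows={"adipose": 12.0, "muscle": 60.0, "liver": 60.0,
                     "kidney": 48.0, "rest": 60.0},
        organ_volumes={"venous_blood": 1.70, "arterial_blood": 0.90,
                       "lungs": 0.40, "adipose": 6.0,
                       "muscle_vascular": 0.50, "muscle_interstitial": 2.00,
                       "muscle_cellular": 13.5, "liver": 0.90, "rest": 13.0},
        hematocrit=0.40,
        gfr=6.6,                    # L/h (~2.75 mL/min/kg)
        urine_flow=0.08,
        medullary_blood_flow_fractions={"outer_medulla": 0.08,
                                        "inner_medulla_1": 0.015,
                                        "inner_medulla_2": 0.005},
        source="growing-pig physiology (Upton 2008 scale)",
    ),
    "human": dict(
        species_name="human",
        body_weight=70.0,
        cardiac_output=312.0,       # L/h (5.2 L/min)
        blood_flows={"adipose": 16.0, "muscle": 53.0, "liver": 78.0,
                     "kidney": 60.0, "rest": 105.0},
        organ_volumes={"venous_blood": 3.50, "arterial_blood": 1.70,
                       "lungs": 0.50, "adipose": 13.0,
                       "muscle_vascular": 0.90, "muscle_interstitial": 3.50,
                       "muscle_cellular": 24.6, "liver": 1.80, "rest": 20.0},
        hematocrit=0.45,
        gfr=7.2,                    # L/h = 120 mL/min creatinine clearance
        urine_flow=0.09,
        medullary_blood_flow_fractions={"outer_medulla": 0.08,
                                        "inner_medulla_1": 0.015,
                                        "inner_medulla_2": 0.005},
        source="reference-adult physiology (ICRP 2002 scale)",
    ),
}

DRUGS = {
    "caz": dict(
        drug=dict(
            drug_name="CAZ",
            molecular_weight=546.6,
            fu_plasma=0.90,                # ~10% plasma protein binding
            blood_plasma_ratio=0.82,
            papp_lumen_to_interstitium=1.44e-6,   # cm/s, LLC-PK1 apical->basal
            papp_interstitium_to_lumen=3.10e-6,   # cm/s, basal->apical
            p_blood_to_interstitium=100e-6,       # cm/s, fixed fast reference
            p_interstitium_to_blood=33.8e-6,      # cm/s, in vivo estimate (rat)
            kp={"lungs": 0.5, "adipose": 0.05, "liver": 0.4, "rest": 0.2},
            cl_nonrenal=0.0,
            cl_tubular_secretion=0.0,
            cl_glomerular=None,
            kp_muscle_cell=0.1,
            muscle_ps_multiplier=10.0,
            source="LLC-PK1 transport assay; extracellular-restricted Kp for a polar cephalosporin",
        ),
        fitted=dict(
            rat=dict(cl_glomerular=0.154, cl_nonrenal=0.0,
                     p_interstitium_to_blood=33.8e-6),
            pig=dict(cl_glomerular=6.41, cl_nonrenal=0.140,
                     p_interstitium_to_blood=31.5e-6),
        ),
    ),
    "avi": dict(
        drug=dict(
            drug_name="AVI",
            molecular_weight=265.2,
            fu_plasma=0.92,                # ~8% plasma protein binding
            blood_plasma_ratio=0.57,
            papp_lumen_to_interstitium=2.53e-6,
            papp_interstitium_to_lumen=5.21e-6,
            p_blood_to_interstitium=100e-6,
            p_interstitium_to_blood=18.5e-6,
            kp={"lungs": 0.5, "adipose": 0.05, "liver": 0.4, "rest": 0.2},
            cl_nonrenal=0.0,
            cl_tubular_secretion=0.0612,
            cl_glomerular=None,
            kp_muscle_cell=0.1,
            muscle_ps_multiplier=10.0,
            source="LLC-PK1 transport assay; extracellular-restricted Kp for a polar diazabicyclooctane",
        ),
        fitted=dict(
            rat=dict(cl_glomerular=0.158, cl_tubular_secretion=0.0612,
                     p_interstitium_to_blood=18.5e-6),
            pig=dict(cl_glomerular=5.71, cl_tubular_secretion=3.96,
                     p_interstitium_to_blood=16.4e-6),
        ),
    ),
}


def tube(n: float, length: float, diameter: float) -> tuple[float, float]:
    """(surface cm^2, volume L) of n parallel tubes."""
    surface = math.pi * diameter * length * n
    volume = math.pi * (diameter / 2.0) ** 2 * length * n / 1000.0  # cm^3 -> L
    return surface, volume


def build_geometry(species: str, gfr: float, urine_flow: float) -> dict:
    m = MORPHOMETRY[species]
    n = m["nephrons"]
    segments: dict[str, dict] = {}

    for k, name in enumerate(("PT1", "PT2", "PT3")):
        s, v = tube(n, m["pt_length"] / 3.0, m["pt_diameter"])
        segments[name] = dict(surface_area=s, lumen_volume=v)
    s, v = tube(n, m["dlh_length"], m["dlh_diameter"])
    segments["DLH"] = dict(surface_area=s, lumen_volume=v)
    s, v = tube(n, m["alh_length"], m["alh_diameter"])
    segments["ALH"] = dict(surface_area=s, lumen_volume=v)
    s, v = tube(n, m["dt_length"], m["dt_diameter"])
    segments["DT"] = dict(surface_area=s, lumen_volume=v)
    # Collecting duct fusion chain: duct count halves and diameter grows at
    # each of the nine fusion levels.
    count = n / 8.0
    for k in range(1, 10):
        d = m["cd_diameter0"] * 1.25 ** (k - 1)
        s, v = tube(count, m["cd_length"], d)
        segments[f"CD{k}"] = dict(surface_area=s, lumen_volume=v)
        count /= 2.0

    # Water-remaining profile; collecting duct declines geometrically from
    # the distal-tubule exit down to urine_flow/GFR at CD9.
    f_urine = urine_flow / gfr
    r = (f_urine / WATER_EXIT["DT"]) ** (1.0 / 9.0)
    water = dict(WATER_EXIT)
    for k in range(1, 10):
        water[f"CD{k}"] = WATER_EXIT["DT"] * r ** k
    water["CD9"] = f_urine  # exact closure

    for name in SEGMENT_ORDER:
        segments[name]["region"] = REGION_OF[name]
        segments[name]["water_fraction_exit"] = round(float(water[name]), 10)
        segments[name]["surface_area"] = round(float(segments[name]["surface_area"]), 6)
        segments[name]["lumen_volume"] = float(f"{segments[name]['lumen_volume']:.6g}")

    regions = {}
    for region in ("cortex", "outer_medulla", "inner_medulla_1", "inner_medulla_2"):
        v_region = m["kidney_volume"] * REGION_VOLUME_FRACTION[region]
        tubular_surface = sum(
            segments[s]["surface_area"] for s in SEGMENT_ORDER
            if REGION_OF[s] == region
        )
        regions[region] = dict(
            blood_volume=float(f"{v_region * REGION_BLOOD_FRACTION[region]:.6g}"),
            interstitial_volume=float(f"{v_region * REGION_INTERSTITIAL_FRACTION[region]:.6g}"),
            vascular_exchange_surface=round(CAPILLARY_APPOSITION * tubular_surface, 6),
        )

    return dict(
        regions=regions,
        segments={s: segments[s] for s in SEGMENT_ORDER},
        source=(
            "nephron morphometry (segment surface pi*d*L*N, nine CD fusion "
            "events) after Li 2017 / Huang & Isoherranen 2018 / Scotcher 2017; "
            "vascular exchange surface = 0.5 x regional tubular surface"
        ),
    )


HEADER = """\
# Default {what} configuration shipped with renalpbpk.
# Literature-based stand-in values; see docs/methods.md for provenance and
# scripts/generate_default_configs.py for the derivation.  Units: h, L, mg,
# cm/s (permeabilities), cm^2 (surfaces).  All values are overridable by
# loading a user file with the same schema.
"""


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for species, phys in PHYSIOLOGY.items():
        doc = {
            "species": phys,
            "kidney_geometry": build_geometry(species, phys["gfr"], phys["urine_flow"]),
        }
        text = HEADER.format(what=f"{species} physiology + kidney geometry")
        text += yaml.safe_dump(doc, sort_keys=False)
        (OUT / f"{species}.yaml").write_text(text)
        print(f"wrote {species}.yaml")
    for key, doc in DRUGS.items():
        text = HEADER.format(what=f"{doc['drug']['drug_name']} drug parameter")
        text += yaml.safe_dump(doc, sort_keys=False)
        (OUT / f"{key}.yaml").write_text(text)
        print(f"wrote {key}.yaml")


if __name__ == "__main__":
    main()
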