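"""Nested mechanistic kidney submodel.

The kidney is split into four anatomical regions (cortex, outer medulla and
two inner-medulla zones), each with a blood and an interstitium compartment,
plus a 15-segment tubular chain (PT1-3, DLH, ALH, DT, CD1-9) carrying the
glomerular filtrate to a urine sink.  Water reabsorption concentrates the
luminal drug (reabsorbed water leaves without drug); drug crosses the
tubular epithelium with the directional in vitro permeabilities, and
exchanges between regional blood and interstitium with an asymmetric
vascular permeability pair (fast blood->interstitium reference, slower
fitted interstitium->blood).  Optional tubular secretion transfers drug
from cortex blood into the proximal-tubule lumen.
"""

from __future__ import annotations

import numpy as np

from .config import (
    CM3_PER_S_TO_L_PER_H,
    REGIONS,
    SEGMENT_ORDER,
    DoseRegimen,
    DrugParameters,
    KidneyGeometry,
    SpeciesPhysiology,
)
from .network import (
    BuildError,
    CompartmentNetwork,
    aqueous_compartment,
    blood_compartment,
    sink_compartment,
)

__all__ = [
    "REGION_BLOOD",
    "REGION_INTERSTITIUM",
    "add_kidney_submodel",
    "tubular_flow_profile",
    "filtration_flux",
    "steady_auc_ratio_oracle",
]

REGION_BLOOD = {r: f"kidney_{r}_blood" for r in REGIONS}
REGION_INTERSTITIUM = {r: f"kidney_{r}_interstitium" for r in REGIONS}
LUMEN = {s: f"lumen_{s}" for s in SEGMENT_ORDER}
PROXIMAL_SEGMENTS = ("PT1", "PT2", "PT3")


def permeability_clearance(p_cm_s: float, surface_cm2: float) -> float:
    """Permeability-surface product as a clearance in L/h."""
    return p_cm_s * surface_cm2 * CM3_PER_S_TO_L_PER_H


def tubular_flow_profile(phys: SpeciesPhysiology, geom: KidneyGeometry) -> dict:
    """Filtrate flow (L/h) entering and leaving each tubule segment.

    Inflow of segment k is GFR times the water-remaining fraction at the
    exit of segment k-1 (GFR itself for PT1); outflow is GFR times the
    fraction at the segment's own exit.  CD9 outflow equals the urine flow.
    """
    fractions = geom.water_remaining_fraction
    profile = {}
    upstream = 1.0
    for seg in SEGMENT_ORDER:
        f = fractions[seg]
        profile[seg] = (phys.gfr * upstream, phys.gfr * f)
        upstream = f
    return profile


def filtration_flux(gfr: float, fu: float, c_plasma: float) -> float:
    """Glomerular filtration rate of drug (mg/h): GFR x fu x C_plasma."""
    if min(gfr, fu, c_plasma) < 0:
        raise ValueError("filtration inputs must be non-negative")
    return gfr * fu * c_plasma


def add_kidney_submodel(
    net: CompartmentNetwork,
    phys: SpeciesPhysiology,
    geom: KidneyGeometry,
    drug: DrugParameters,
    arterial: str = "arterial_blood",
    venous: str = "venous_blood",
    urine_sink: str = "urine",
) -> None:
    """Wire the kidney into an existing network between arterial and venous blood."""
    fu, bp = drug.fu_plasma, drug.blood_plasma_ratio

    for region in REGIONS:
        spec = geom.regions[region]
        net.add_compartment(
            blood_compartment(REGION_BLOOD[region], spec["blood_volume"], fu, bp)
        )
        net.add_compartment(
            aqueous_compartment(
                REGION_INTERSTITIUM[region], spec["interstitial_volume"], "interstitial"
            )
        )
    for seg in SEGMENT_ORDER:
        net.add_compartment(
            aqueous_compartment(LUMEN[seg], geom.segments[seg]["lumen_volume"], "lumen")
        )
    if urine_sink not in net:
        net.add_compartment(sink_compartment(urine_sink))

    # --- regional blood chain: renal artery perfuses the cortex; a small
    # fraction continues serially into the medulla, the rest returns directly.
    q_kid = phys.blood_flows["kidney"]
    f_om = phys.medullary_blood_flow_fractions["outer_medulla"]
    f_im1 = phys.medullary_blood_flow_fractions["inner_medulla_1"]
    f_im2 = phys.medullary_blood_flow_fractions["inner_medulla_2"]
    cortex_b = REGION_BLOOD["cortex"]
    om_b = REGION_BLOOD["outer_medulla"]
    im1_b = REGION_BLOOD["inner_medulla_1"]
    im2_b = REGION_BLOOD["inner_medulla_2"]
    net.add_transfer(arterial, cortex_b, q_kid, "total", "renal artery")
    net.add_transfer(cortex_b, venous, q_kid * (1 - f_om), "total", "cortical venous return")
    net.add_transfer(cortex_b, om_b, q_kid * f_om, "total", "descending vasa recta")
    net.add_transfer(om_b, venous, q_kid * (f_om - f_im1), "total", "OM venous return")
    net.add_transfer(om_b, im1_b, q_kid * f_im1, "total", "descending vasa recta")
    net.add_transfer(im1_b, venous, q_kid * (f_im1 - f_im2), "total", "IM1 venous return")
    net.add_transfer(im1_b, im2_b, q_kid * f_im2, "total", "descending vasa recta")
    net.add_transfer(im2_b, venous, q_kid * f_im2, "total", "IM2 venous return")

    # --- glomerular filtration into PT1 (plasma clearance fu*GFR by default)
    cl_glom = drug.glomerular_clearance(phys.gfr)
    net.add_transfer(cortex_b, LUMEN["PT1"], cl_glom, "plasma", "glomerular filtration")

    # --- optional tubular secretion, spread over the proximal segments
    if drug.cl_tubular_secretion > 0:
        share = drug.cl_tubular_secretion / len(PROXIMAL_SEGMENTS)
        for seg in PROXIMAL_SEGMENTS:
            net.add_transfer(cortex_b, LUMEN[seg], share, "plasma", "tubular secretion")

    # --- luminal flow chain with water reabsorption (drug stays behind)
    profile = tubular_flow_profile(phys, geom)
    for k, seg in enumerate(SEGMENT_ORDER):
        outflow = profile[seg][1]
        target = LUMEN[SEGMENT_ORDER[k + 1]] if k + 1 < len(SEGMENT_ORDER) else urine_sink
        net.add_transfer(LUMEN[seg], target, outflow, "total", "filtrate flow")

    # --- transcellular tubular exchange at the in vitro permeabilities
    for seg in SEGMENT_ORDER:
        spec = geom.segments[seg]
        interstitium = REGION_INTERSTITIUM[spec["region"]]
        surface = spec["surface_area"]
        net.add_transfer(
            LUMEN[seg], interstitium,
            permeability_clearance(drug.papp_lumen_to_interstitium, surface),
            "total", "tubular reabsorption (apical->basal)",
        )
        net.add_transfer(
            interstitium, LUMEN[seg],
            permeability_clearance(drug.papp_interstitium_to_lumen, surface),
            "total", "tubular passive secretion (basal->apical)",
        )

    # --- asymmetric vascular exchange per region
    for region in REGIONS:
        surface = geom.regions[region]["vascular_exchange_surface"]
        net.add_transfer(
            REGION_BLOOD[region], REGION_INTERSTITIUM[region],
            permeability_clearance(drug.p_blood_to_interstitium, surface),
            "unbound", "vascular blood->interstitium",
        )
        net.add_transfer(
            REGION_INTERSTITIUM[region], REGION_BLOOD[region],
            permeability_clearance(drug.p_interstitium_to_blood, surface),
            "total", "vascular interstitium->blood",
        )


def steady_auc_ratio_oracle(
    phys: SpeciesPhysiology,
    geom: KidneyGeometry,
    drug: DrugParameters,
    region: str = "cortex",
    regimen: DoseRegimen | None = None,
) -> float:
    """Interstitium:unbound-plasma AUC(0, inf) ratio from the integrated balance.

    Algebraic cross-check of the ODE engine: for the linear, fully
    eliminating system the vector of amount-time integrals solves
    ``A a = -dose``, so the AUC ratio follows from one linear solve with no
    time stepping.  The dose placement (not its time course) is all that
    matters, so any regimen with the same compartment totals gives the same
    ratio.
    """
    from .model import build_whole_body_model

    net = build_whole_body_model(phys, geom, drug)
    if regimen is None:
        regimen = DoseRegimen.bolus(1.0)
    dose_amounts: dict[str, float] = {}
    for event in regimen.events:
        dose_amounts[event.target] = dose_amounts.get(event.target, 0.0) + event.amount
    auc_interstitium = net.auc_infinity_concentration(
        dose_amounts, REGION_INTERSTITIUM[region], "total"
    )
    auc_unbound_plasma = net.auc_infinity_concentration(
        dose_amounts, "venous_blood", "unbound"
    )
    return auc_interstitium / auc_unbound_plasma
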