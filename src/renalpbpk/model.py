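"""Whole-body model assembly.

Body plan: venous blood -> lungs -> arterial blood in series; arterial blood
feeds adipose, liver, rest-of-body (perfusion limited), the three-space
muscle and the mechanistic kidney in parallel, all returning to venous
blood.  Muscle is permeability limited with symmetric passive transfer
along vascular <-> interstitial <-> cellular, driven by unbound
concentrations.  Non-renal clearance leaves from the liver; urine collects
from the collecting duct.  Doses target venous blood.
"""

from __future__ import annotations

from .config import DrugParameters, KidneyGeometry, SpeciesPhysiology
from .kidney import add_kidney_submodel
from .network import (
    BuildError,
    CompartmentNetwork,
    aqueous_compartment,
    blood_compartment,
    cellular_compartment,
    sink_compartment,
    tissue_compartment,
)

__all__ = ["build_whole_body_model", "OBSERVABLES"]

#: Microdialysis probe site -> (compartment, driving concentration).
OBSERVABLES = {
    "blood": ("venous_blood", "unbound"),
    "muscle": ("muscle_interstitium", "total"),
    "kidney": ("kidney_cortex_interstitium", "total"),
}


def build_whole_body_model(
    phys: SpeciesPhysiology,
    geom: KidneyGeometry,
    drug: DrugParameters,
    track_observables: bool = True,
) -> CompartmentNetwork:
    """Assemble the full whole-body + kidney network for one species and drug.

    When ``track_observables`` is set (default), AUC trackers for unbound
    plasma, muscle interstitium and kidney cortex interstitium are
    registered so interval-averaged microdialysis predictions and AUC
    ratios come from co-integrated states.
    """
    fu, bp = drug.fu_plasma, drug.blood_plasma_ratio
    vol = phys.organ_volumes

    net = CompartmentNetwork()
    net.add_compartment(blood_compartment("venous_blood", vol["venous_blood"], fu, bp))
    net.add_compartment(blood_compartment("arterial_blood", vol["arterial_blood"], fu, bp))
    for organ in ("lungs", "adipose", "liver", "rest"):
        try:
            kp = drug.kp[organ]
        except KeyError as exc:
            raise BuildError(f"drug {drug.drug_name} lacks kp[{organ!r}]") from exc
        net.add_compartment(tissue_compartment(organ, vol[organ], kp, fu, bp))
    net.add_compartment(
        blood_compartment("muscle_vascular", vol["muscle_vascular"], fu, bp)
    )
    net.add_compartment(
        aqueous_compartment("muscle_interstitium", vol["muscle_interstitial"], "interstitial")
    )
    net.add_compartment(
        cellular_compartment("muscle_cell", vol["muscle_cellular"], drug.kp_muscle_cell)
    )
    net.add_compartment(sink_compartment("urine"))
    net.add_compartment(sink_compartment("nonrenal"))

    co = phys.cardiac_output
    q = phys.blood_flows

    # series: venous -> lungs -> arterial
    net.add_transfer("venous_blood", "lungs", co, "total", "pulmonary flow")
    net.add_transfer("lungs", "arterial_blood", co, "total", "pulmonary flow")

    # parallel perfusion-limited organs
    for organ in ("adipose", "liver", "rest"):
        net.add_transfer("arterial_blood", organ, q[organ], "total", "arterial flow")
        net.add_transfer(organ, "venous_blood", q[organ], "total", "venous flow")

    # three-space muscle
    net.add_transfer("arterial_blood", "muscle_vascular", q["muscle"], "total", "arterial flow")
    net.add_transfer("muscle_vascular", "venous_blood", q["muscle"], "total", "venous flow")
    cl_ps = drug.muscle_ps_multiplier * q["muscle"]
    net.add_transfer("muscle_vascular", "muscle_interstitium", cl_ps, "unbound",
                     "muscle passive transfer")
    net.add_transfer("muscle_interstitium", "muscle_vascular", cl_ps, "unbound",
                     "muscle passive transfer")
    net.add_transfer("muscle_interstitium", "muscle_cell", cl_ps, "unbound",
                     "muscle passive transfer")
    net.add_transfer("muscle_cell", "muscle_interstitium", cl_ps, "unbound",
                     "muscle passive transfer")

    # hepatic (non-renal) elimination against the liver plasma-equivalent
    if drug.cl_nonrenal > 0:
        net.add_transfer("liver", "nonrenal", drug.cl_nonrenal, "plasma",
                         "non-renal clearance")

    add_kidney_submodel(net, phys, geom, drug)

    net.add_dose_target("venous_blood")
    if track_observables:
        net.track("venous_blood", "unbound", "auc_unbound_plasma")
        net.track("muscle_interstitium", "total", "auc_muscle_interstitium")
        net.track("kidney_cortex_interstitium", "total", "auc_cortex_interstitium")
    return net
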