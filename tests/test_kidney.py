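"""Kidney submodel structure, flows and the algebraic AUC-ratio oracle."""

import dataclasses

import numpy as np
import pytest

from renalpbpk.config import DoseRegimen, SEGMENT_ORDER
from renalpbpk.kidney import (
    filtration_flux,
    steady_auc_ratio_oracle,
    tubular_flow_profile,
)
from renalpbpk.model import build_whole_body_model
from renalpbpk.simulate import compute_auc, simulate


def phases(net):
    out = {}
    for comp in net.compartments:
        out.setdefault(comp.phase, []).append(comp.name)
    return out


class TestStructure:
    def test_fifteen_lumen_and_four_regions(self, physiologies, geometries, drugs):
        net = build_whole_body_model(physiologies["rat"], geometries["rat"],
                                     drugs[("CAZ", "rat")])
        by_phase = phases(net)
        assert len(by_phase["lumen"]) == 15
        kidney_interstitia = [n for n in by_phase["interstitial"] if "kidney" in n]
        kidney_blood = [n for n in by_phase["blood"] if "kidney" in n]
        assert len(kidney_interstitia) == 4
        assert len(kidney_blood) == 4

    def test_caz_has_no_secretion_edges(self, physiologies, geometries, drugs):
        net = build_whole_body_model(physiologies["rat"], geometries["rat"],
                                     drugs[("CAZ", "rat")])
        table = net.edge_table()
        assert (table["mechanism"] == "tubular secretion").sum() == 0
        assert (table["mechanism"] == "non-renal clearance").sum() == 0

    def test_avi_pig_secretion_total(self, physiologies, geometries, drugs):
        net = build_whole_body_model(physiologies["pig"], geometries["pig"],
                                     drugs[("AVI", "pig")])
        table = net.edge_table()
        secretion = table[table["mechanism"] == "tubular secretion"]
        assert secretion["clearance_L_h"].sum() == pytest.approx(3.96)
        assert len(secretion) == 3  # spread over PT1-3

    def test_pig_caz_liver_elimination(self, physiologies, geometries, drugs):
        net = build_whole_body_model(physiologies["pig"], geometries["pig"],
                                     drugs[("CAZ", "pig")])
        table = net.edge_table()
        nonrenal = table[table["mechanism"] == "non-renal clearance"]
        assert nonrenal["clearance_L_h"].sum() == pytest.approx(0.140)

    def test_vascular_asymmetry_ratio(self, physiologies, geometries, drugs):
        """Blood->interstitium over interstitium->blood clearance is the fixed
        100 over the fitted permeability (~6.1 for pig avibactam)."""
        net = build_whole_body_model(physiologies["pig"], geometries["pig"],
                                     drugs[("AVI", "pig")])
        table = net.edge_table()
        b2i = table[table["mechanism"] == "vascular blood->interstitium"]
        i2b = table[table["mechanism"] == "vascular interstitium->blood"]
        ratio = b2i["clearance_L_h"].sum() / i2b["clearance_L_h"].sum()
        assert ratio == pytest.approx(100.0 / 16.4, rel=1e-9)


class TestTubularFlow:
    def test_profile_arithmetic(self, physiologies, geometries):
        """Human GFR 7.2 L/h with PT3-exit fraction 0.34 flows 2.448 L/h."""
        profile = tubular_flow_profile(physiologies["human"], geometries["human"])
        assert profile["PT3"][1] == pytest.approx(7.2 * 0.34)
        assert profile["PT1"][0] == pytest.approx(7.2)

    @pytest.mark.parametrize("species", ["rat", "pig", "human"])
    def test_cd9_outflow_is_urine_flow(self, physiologies, geometries, species):
        profile = tubular_flow_profile(physiologies[species], geometries[species])
        assert profile["CD9"][1] == pytest.approx(physiologies[species].urine_flow)

    def test_unit_fractions_mean_no_concentration(self, physiologies, geometries):
        geom = geometries["rat"]
        segments = {s: dict(v, water_fraction_exit=1.0) for s, v in geom.segments.items()}
        flat = dataclasses.replace(geom, segments=segments)
        profile = tubular_flow_profile(physiologies["rat"], flat)
        for seg in SEGMENT_ORDER:
            assert profile[seg] == (pytest.approx(physiologies["rat"].gfr),) * 2


class TestFiltrationFlux:
    def test_arithmetic(self):
        assert filtration_flux(7.2, 0.9, 10.0) == pytest.approx(64.8)
        assert filtration_flux(7.2, 0.9, 0.0) == 0.0

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            filtration_flux(7.2, 0.9, -1.0)


def isolated_vascular_drug(drug, p_i2b):
    """Drug variant whose kidney couples only through the vascular pair:
    vanishing tubular permeability and filtration, hepatic elimination."""
    return drug.with_updates(
        papp_lumen_to_interstitium=1e-30,
        papp_interstitium_to_lumen=1e-30,
        cl_tubular_secretion=0.0,
        cl_glomerular=1e-12,
        cl_nonrenal=1.0,
        p_interstitium_to_blood=p_i2b,
    )


class TestAucRatioOracle:
    def test_pure_vascular_case_is_permeability_ratio(self, physiologies, geometries,
                                                      drugs):
        """With the tubule decoupled the cortex ratio is exactly P_b2i/P_i2b
        (100/33.8 = 2.96)."""
        drug = isolated_vascular_drug(drugs["CAZ"], 33.8e-6)
        ratio = steady_auc_ratio_oracle(physiologies["rat"], geometries["rat"], drug)
        assert ratio == pytest.approx(100.0 / 33.8, rel=1e-6)

    def test_symmetric_permeabilities_give_unity(self, physiologies, geometries, drugs):
        drug = isolated_vascular_drug(drugs["CAZ"], 100e-6)
        ratio = steady_auc_ratio_oracle(physiologies["rat"], geometries["rat"], drug)
        assert ratio == pytest.approx(1.0, rel=1e-9)

    def test_oracle_matches_ode_simulation(self, physiologies, geometries, drugs):
        phys, geom = physiologies["rat"], geometries["rat"]
        drug = drugs[("CAZ", "rat")]
        oracle = steady_auc_ratio_oracle(phys, geom, drug)
        net = build_whole_body_model(phys, geom, drug)
        res = simulate(net, DoseRegimen.bolus(6.6), 200.0,
                       grid=np.array([0.0, 200.0]))
        simulated = (compute_auc(res, "auc_cortex_interstitium", 0, 200.0)
                     / compute_auc(res, "auc_unbound_plasma", 0, 200.0))
        assert simulated == pytest.approx(oracle, rel=1e-4)

    def test_ratio_strictly_decreases_with_outflux_permeability(
        self, physiologies, geometries, drugs
    ):
        values = [10e-6, 20e-6, 40e-6, 80e-6]
        ratios = [
            steady_auc_ratio_oracle(
                physiologies["rat"], geometries["rat"],
                drugs[("CAZ", "rat")].with_updates(p_interstitium_to_blood=p),
            )
            for p in values
        ]
        assert all(a > b for a, b in zip(ratios, ratios[1:]))

    def test_directional_tubular_loss_pulls_ratio_below_one(
        self, physiologies, geometries, drugs
    ):
        """With symmetric vascular exchange, the basal->apical excess of the
        measured tubular permeabilities drains the interstitium: ratio < 1."""
        drug = drugs[("CAZ", "rat")].with_updates(p_interstitium_to_blood=100e-6)
        ratio = steady_auc_ratio_oracle(physiologies["rat"], geometries["rat"], drug)
        assert ratio < 1.0

    def test_urine_collects_everything_not_cleared_hepatically(
        self, physiologies, geometries, drugs
    ):
        """Drug entering the tubule and not reabsorbed ends in urine: for a
        purely renally cleared drug the urine integral equals the dose."""
        net = build_whole_body_model(physiologies["rat"], geometries["rat"],
                                     drugs[("AVI", "rat")])
        res = simulate(net, DoseRegimen.bolus(1.65), 300.0,
                       grid=np.array([0.0, 300.0]))
        assert res.amount("urine")[-1] == pytest.approx(1.65, rel=1e-6)
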