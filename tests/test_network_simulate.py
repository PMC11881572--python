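"""ODE engine: closed forms, conservation, linearity and AUC bookkeeping."""

import numpy as np
import pytest

from renalpbpk.config import DoseRegimen
from renalpbpk.model import build_whole_body_model
from renalpbpk.simulate import (
    SimulationResult,
    blood_to_unbound_plasma,
    compute_auc,
    mass_balance,
    simulate,
)


class TestClosedForms:
    @pytest.mark.parametrize("method", ["expm", "lsoda"])
    def test_one_compartment_exponential_decay(self, one_compartment, method):
        """V=10 L, CL=1 L/h, 100 mg bolus: C(t) = 10 exp(-0.1 t)."""
        net = one_compartment(volume=10.0, clearance=1.0)
        res = simulate(net, DoseRegimen.bolus(100.0), 24.0, method=method)
        expected = 10.0 * np.exp(-0.1 * res.times)
        np.testing.assert_allclose(res.concentration("venous_blood"), expected,
                                   rtol=1e-6)

    def test_auc_to_infinity_is_dose_over_clearance(self, one_compartment):
        net = one_compartment(volume=10.0, clearance=1.0)
        res = simulate(net, DoseRegimen.bolus(100.0), 400.0)
        assert compute_auc(res, "auc_blood", 0.0, 400.0) == pytest.approx(100.0, rel=1e-8)

    def test_constant_concentration_auc(self, one_compartment):
        """No elimination: 20 mg in 10 L is 2 mg/L; AUC over 5 h is 10."""
        net = one_compartment(volume=10.0, clearance=0.0)
        res = simulate(net, DoseRegimen.bolus(20.0), 10.0)
        assert compute_auc(res, "auc_blood", 2.0, 7.0) == pytest.approx(10.0, rel=1e-10)

    def test_auc_additivity(self, one_compartment):
        net = one_compartment()
        res = simulate(net, DoseRegimen.bolus(50.0), 30.0)
        total = compute_auc(res, "auc_blood", 0.0, 30.0)
        split = (compute_auc(res, "auc_blood", 0.0, 11.0)
                 + compute_auc(res, "auc_blood", 11.0, 30.0))
        assert split == pytest.approx(total, rel=1e-10)

    def test_untracked_compartment_is_a_helpful_error(self, one_compartment):
        net = one_compartment()
        res = simulate(net, DoseRegimen.bolus(1.0), 1.0)
        with pytest.raises(KeyError, match="track"):
            compute_auc(res, "auc_liver", 0.0, 1.0)


class TestConservationAndLinearity:
    def test_zero_elimination_conserves_dose(self, one_compartment):
        net = one_compartment(clearance=0.0)
        res = simulate(net, DoseRegimen.bolus(42.0), 50.0)
        np.testing.assert_allclose(res.total_in_system(), 42.0, rtol=1e-12)

    @pytest.mark.parametrize("species,drug_key", [
        ("rat", ("CAZ", "rat")), ("rat", ("AVI", "rat")),
        ("pig", ("CAZ", "pig")), ("pig", ("AVI", "pig")),
        ("human", "CAZ"),
    ])
    def test_mass_balance_on_shipped_configs(self, physiologies, geometries, drugs,
                                             species, drug_key):
        net = build_whole_body_model(physiologies[species], geometries[species],
                                     drugs[drug_key])
        regimen = (DoseRegimen.bolus(10.0) if species == "rat"
                   else DoseRegimen.infusion(400.0, 2.0))
        res = simulate(net, regimen, 48.0)
        assert mass_balance(res) <= 1e-6

    def test_mass_balance_zero_dose(self, one_compartment):
        res = simulate(one_compartment(), DoseRegimen(()), 5.0)
        assert mass_balance(res) == 0.0

    def test_mass_balance_detects_leaks(self, one_compartment):
        """Negative control: deleting the sink amounts breaks the balance."""
        net = one_compartment(volume=10.0, clearance=1.0)
        res = simulate(net, DoseRegimen.bolus(100.0), 24.0)
        broken = res._states.copy()
        broken[:, net.index("eliminated")] = 0.0
        leaky = SimulationResult(net, res.times, broken, res.regimen)
        assert mass_balance(leaky) > 1e-2

    def test_doubling_dose_doubles_concentrations(self, physiologies, geometries, drugs):
        net = build_whole_body_model(physiologies["rat"], geometries["rat"],
                                     drugs[("CAZ", "rat")])
        lo = simulate(net, DoseRegimen.bolus(6.6), 24.0)
        hi = simulate(net, DoseRegimen.bolus(13.2), 24.0)
        c_lo = lo.concentration("kidney_cortex_interstitium")
        c_hi = hi.concentration("kidney_cortex_interstitium")
        mask = c_lo > c_lo.max() * 1e-12
        np.testing.assert_allclose(c_hi[mask], 2.0 * c_lo[mask], rtol=1e-8)

    def test_rat_caz_dose_fully_recovered_in_urine(self, physiologies, geometries, drugs):
        """All rat ceftazidime elimination is renal, so the urine sink holds
        the full dose once the drug is eliminated."""
        net = build_whole_body_model(physiologies["rat"], geometries["rat"],
                                     drugs[("CAZ", "rat")])
        res = simulate(net, DoseRegimen.bolus(6.6), 100.0, grid=np.array([0.0, 100.0]))
        assert res.amount("urine")[-1] == pytest.approx(6.6, rel=1e-3)


class TestBackendsAgree:
    def test_expm_matches_lsoda_on_whole_body_model(self, physiologies, geometries, drugs):
        net = build_whole_body_model(physiologies["pig"], geometries["pig"],
                                     drugs[("AVI", "pig")])
        regimen = DoseRegimen.infusion(400.0, 2.0)
        grid = np.linspace(0.0, 12.0, 49)
        exact = simulate(net, regimen, 12.0, grid=grid, method="expm")
        lsoda = simulate(net, regimen, 12.0, grid=grid, method="lsoda")
        for comp in ("venous_blood", "kidney_cortex_interstitium", "muscle_interstitium"):
            a, b = exact.concentration(comp), lsoda.concentration(comp)
            np.testing.assert_allclose(b, a, rtol=2e-5, atol=1e-10 * a.max())


class TestBloodToUnboundPlasma:
    def test_caz_constants(self, drugs):
        assert blood_to_unbound_plasma(0.82, drugs["CAZ"]) == pytest.approx(0.90)

    def test_avi_constants(self, drugs):
        assert blood_to_unbound_plasma(0.57, drugs["AVI"]) == pytest.approx(0.92)

    def test_zero_and_negative(self, drugs):
        assert blood_to_unbound_plasma(0.0, drugs["CAZ"]) == 0.0
        with pytest.raises(ValueError):
            blood_to_unbound_plasma(-1.0, drugs["CAZ"])
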