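import numpy as np
import pytest

from renalpbpk.config import (
    load_drug_parameters,
    load_kidney_geometry,
    load_species_physiology,
)
from renalpbpk.network import (
    CompartmentNetwork,
    aqueous_compartment,
    blood_compartment,
    sink_compartment,
)


@pytest.fixture(scope="session")
def physiologies():
    return {s: load_species_physiology(s) for s in ("rat", "pig", "human")}


@pytest.fixture(scope="session")
def geometries():
    return {s: load_kidney_geometry(s) for s in ("rat", "pig", "human")}


@pytest.fixture(scope="session")
def drugs():
    out = {}
    for name in ("CAZ", "AVI"):
        out[name] = load_drug_parameters(name)
        for species in ("rat", "pig"):
            out[(name, species)] = load_drug_parameters(name, species=species)
    return out


def one_compartment_network(volume=10.0, clearance=1.0, fu=1.0, bp=1.0):
    """Single blood compartment named venous_blood with linear elimination."""
    net = CompartmentNetwork()
    net.add_compartment(blood_compartment("venous_blood", volume, fu, bp))
    net.add_compartment(sink_compartment("eliminated"))
    if clearance > 0:
        net.add_transfer("venous_blood", "eliminated", clearance, "total", "elimination")
    net.add_dose_target("venous_blood")
    net.track("venous_blood", "total", "auc_blood")
    return net


@pytest.fixture
def one_compartment():
    return one_compartment_network
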