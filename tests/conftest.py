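import pytest

from stoichcal import AttenuationParams, CTMeasurement, theoretical_hu
from stoichcal.datasets import AUDIT_PHANTOM_MATERIALS, FORMULA_MATERIALS
from stoichcal.tissues import representative_tissues


@pytest.fixture(scope="session")
def tissues():
    return representative_tissues()


@pytest.fixture(scope="session")
def truth_params():
    """Ground-truth parameters at the standard initialization scale, with a
    scanner whose air CT number sits 3% above nominal magnitude."""
    return AttenuationParams(1.24e-3, 3.06e-5, 0.97)


@pytest.fixture(scope="session")
def audit_pair():
    return AUDIT_PHANTOM_MATERIALS["tough_lung"], AUDIT_PHANTOM_MATERIALS["tough_bone"]


@pytest.fixture(scope="session")
def formula_materials():
    return FORMULA_MATERIALS


def synthetic_measurements(materials, params, rng=None, noise_sd=0.0):
    """Forward-generate CT measurements exactly from the HU model."""
    out = []
    for m in materials:
        hu = theoretical_hu(m, params)
        if rng is not None and noise_sd > 0:
            hu += rng.normal(0.0, noise_sd)
        out.append(CTMeasurement(m, float(hu)))
    return out
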