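import numpy as np
import pytest

from traitforest.dynamics import GapModelParams, Patch
from traitforest.herbivory import HerbivorySettings
from traitforest.traits import TraitBounds, default_curves


@pytest.fixture(scope="session")
def bounds():
    return TraitBounds()


@pytest.fixture(scope="session")
def local_curves():
    return default_curves("local")


@pytest.fixture(scope="session")
def global_curves():
    return default_curves("global")


@pytest.fixture
def params():
    return GapModelParams()


@pytest.fixture
def patch(params):
    return Patch(params=params)


@pytest.fixture
def herb_settings():
    return HerbivorySettings()


def climate_year(tair=16.0, precip=2500.0, rad=15.0, n_in=20.0, p_in=1.6):
    return {
        "tair_c": tair,
        "precip_mm": precip,
        "rad_mj_m2_d": rad,
        "n_in_kg_ha_yr": n_in,
        "p_in_kg_ha_yr": p_in,
    }
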