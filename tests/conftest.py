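import math

import pytest

from molehb import AllostericParams, Conditions, NoiseModel, generate_oec


@pytest.fixture
def eastern_blood_params():
    """Whole-blood-like parameter set: low DPG/chloride response, shallow Bohr-era
    temperature sensitivity (dh_corr -8.3 kJ/mol), P50 28.8 mmHg at 36 degC/pH 7.36."""
    return AllostericParams(
        logp50_ref=math.log10(28.8),
        hill_n=2.76,
        bohr_phi=-0.78,
        k_cl=0.0,
        dpg_shift=0.0,
        dh_corr=-8.3,
        ref_conditions=Conditions(temperature_c=36.0, ph=7.36),
    )


@pytest.fixture
def effector_params():
    """Purified-Hb-like parameter set exercising every linkage term."""
    return AllostericParams(
        logp50_ref=math.log10(10.0),
        hill_n=2.5,
        bohr_phi=-0.55,
        k_cl=0.30,
        dpg_shift=0.25,
        dh_corr=-9.0,
        ref_conditions=Conditions(temperature_c=37.0, ph=7.2, chloride_m=0.1, dpg_ratio=0.0),
    )


# tonometry-style grid: ~10 steps inside the 30-70% window of a P50 ~28.8,
# n ~2.76 curve, plus anchoring extremes
BLOOD_GRID = [5.0, 22.0, 24.0, 26.0, 28.0, 30.0, 32.0, 34.0, 36.0, 38.0, 40.0, 60.0]


def noise_free(params, conditions=None, grid=None, label=""):
    c = conditions or params.ref_conditions
    g = grid or BLOOD_GRID
    return generate_oec(params, c, g, NoiseModel(saturation_sd=0.0, seed=0), label=label)


@pytest.fixture
def blood_grid():
    return list(BLOOD_GRID)
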