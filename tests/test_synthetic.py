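"""Forward allosteric model and generators: closed-form checks and contracts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from molehb import (
    AllostericParams,
    Conditions,
    NoiseModel,
    ValidationError,
    generate_blood_panel,
    generate_oec,
    p50_at_conditions,
    saturation_at,
)

from conftest import noise_free


class TestConditionsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"temperature_c": 0.0, "ph": 7.4},
            {"temperature_c": 50.0, "ph": 7.4},
            {"temperature_c": 37.0, "ph": 5.0},
            {"temperature_c": 37.0, "ph": 7.4, "chloride_m": -0.1},
            {"temperature_c": 37.0, "ph": 7.4, "dpg_ratio": -1.0},
        ],
    )
    def test_invalid_conditions_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            Conditions(**kwargs)

    def test_hill_n_bounds(self):
        with pytest.raises(ValidationError):
            AllostericParams(
                logp50_ref=1.0, hill_n=5.0, bohr_phi=0, k_cl=0, dpg_shift=0,
                dh_corr=0, ref_conditions=Conditions(37.0, 7.4),
            )


class TestP50AtConditions:
    def test_identity_at_reference(self, eastern_blood_params):
        p = p50_at_conditions(eastern_blood_params, eastern_blood_params.ref_conditions)
        assert p == pytest.approx(28.8, rel=1e-12)

    def test_temperature_ratio_closed_form(self, eastern_blood_params):
        # exp((-20800/8.314)*(1/313.15 - 1/305.15)) evaluated independently
        p40 = p50_at_conditions(eastern_blood_params, Conditions(40.0, 7.36))
        p32 = p50_at_conditions(eastern_blood_params, Conditions(32.0, 7.36))
        assert p40 / p32 == pytest.approx(1.2329980269186969, rel=1e-9)

    def test_bohr_shift_closed_form(self, eastern_blood_params):
        # dpH +0.40 with phi -0.78: factor 10**(-0.312)
        p_hi = p50_at_conditions(eastern_blood_params, Conditions(36.0, 7.76))
        assert p_hi / 28.8 == pytest.approx(10 ** (-0.312), rel=1e-9)
        assert p_hi / 28.8 == pytest.approx(0.4875, abs=5e-4)

    def test_chloride_reference_mismatch_raises(self, effector_params):
        with pytest.raises(ValidationError, match="chloride reference mismatch"):
            p50_at_conditions(effector_params, Conditions(37.0, 7.2, chloride_m=None))

    def test_dpg_saturates_above_ratio_50(self, effector_params):
        p_50x = p50_at_conditions(
            effector_params, Conditions(37.0, 7.2, chloride_m=0.1, dpg_ratio=50)
        )
        p_90x = p50_at_conditions(
            effector_params, Conditions(37.0, 7.2, chloride_m=0.1, dpg_ratio=90)
        )
        assert p_90x == pytest.approx(p_50x, rel=1e-12)
        assert math.log10(p_50x / effector_params.p50_ref) == pytest.approx(0.25, rel=1e-9)

    @given(dph=st.floats(-0.5, 0.5), dt=st.floats(-4, 4))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_sign_properties(self, dph, dt):
        # bohr_phi < 0: lower pH -> higher P50; dH_app < 0: warmer -> higher P50
        params = AllostericParams(
            logp50_ref=math.log10(28.8), hill_n=2.76, bohr_phi=-0.78, k_cl=0.0,
            dpg_shift=0.0, dh_corr=-8.3, ref_conditions=Conditions(36.0, 7.36),
        )
        base = p50_at_conditions(params, Conditions(36.0, 7.36))
        moved = p50_at_conditions(params, Conditions(36.0 + dt, 7.36 + dph))
        if dph < 0 and dt == 0:
            assert moved > base
        if dt > 0 and dph == 0:
            assert moved > base


class TestSaturationAt:
    def test_half_saturation_at_p50(self):
        assert saturation_at(10.0, 10.0, 2.8) == pytest.approx(0.5, abs=1e-15)

    def test_zero_po2(self):
        assert saturation_at(0.0, 25.0, 2.5) == 0.0

    def test_derived_value(self):
        assert saturation_at(20.0, 10.0, 2.0) == pytest.approx(0.8, rel=1e-12)

    @given(
        po2=st.floats(0.1, 200), p50=st.floats(1, 100), n=st.floats(0.6, 4),
        dpo2=st.floats(0.01, 50), dp50=st.floats(0.01, 50),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_monotonicity(self, po2, p50, n, dpo2, dp50):
        y = saturation_at(po2, p50, n)
        assert saturation_at(po2 + dpo2, p50, n) > y
        assert saturation_at(po2, p50 + dp50, n) < y


class TestGenerateOEC:
    def test_noise_free_half_saturation_at_p50(self, eastern_blood_params):
        ds = generate_oec(
            eastern_blood_params, eastern_blood_params.ref_conditions,
            [10.0, 28.8, 50.0], NoiseModel(0.0, 7),
        )
        assert ds.saturation[1] == pytest.approx(0.5, abs=1e-12)

    def test_seed_determinism(self, eastern_blood_params, blood_grid):
        kw = dict(params=eastern_blood_params, c=eastern_blood_params.ref_conditions,
                  po2_grid=blood_grid, noise=NoiseModel(0.01, 42))
        a, b = generate_oec(**kw), generate_oec(**kw)
        assert a.saturation == b.saturation
        c = generate_oec(**{**kw, "noise": NoiseModel(0.01, 43)})
        assert a.saturation != c.saturation

    def test_empty_grid_rejected(self, eastern_blood_params):
        with pytest.raises(ValidationError):
            generate_oec(eastern_blood_params, eastern_blood_params.ref_conditions,
                         [], NoiseModel(0.0, 1))

    def test_saturations_clipped(self, eastern_blood_params, blood_grid):
        ds = generate_oec(eastern_blood_params, eastern_blood_params.ref_conditions,
                          blood_grid, NoiseModel(0.05, 3))
        assert all(0.0 <= s <= 1.0 for s in ds.saturation)

    def test_dataset_invariants(self, eastern_blood_params):
        with pytest.raises(ValidationError):
            generate_oec(eastern_blood_params, eastern_blood_params.ref_conditions,
                         [10.0, 5.0], NoiseModel(0.0, 1))


class TestGenerateBloodPanel:
    def test_zero_sd_draws_equal_mean(self):
        (g,) = generate_blood_panel([("hct", 46.8, 0.0, 5)], seed=1)
        assert np.allclose(g.values, 46.8)
        assert g.mean == pytest.approx(46.8)
        assert g.se == 0.0

    def test_seed_reproducibility(self):
        a = generate_blood_panel([("x", 10, 2, 6), ("y", 5, 1, 4)], seed=9)
        b = generate_blood_panel([("x", 10, 2, 6), ("y", 5, 1, 4)], seed=9)
        for ga, gb in zip(a, b):
            assert np.array_equal(ga.values, gb.values)

    def test_summary_from_draws(self):
        (g,) = generate_blood_panel([("dpg", 7.09, 0.35, 3)], seed=11)
        assert g.n == 3
        assert g.se == pytest.approx(np.std(g.values, ddof=1) / np.sqrt(3))


def test_noise_free_round_trip_preserves_hill_shape(effector_params):
    # generator output at any conditions is an exact Hill curve in its own P50
    c = Conditions(37.0, 7.0, chloride_m=0.05, dpg_ratio=60)
    from molehb import fit_hill
    ds = noise_free(effector_params, c, grid=[float(x) for x in np.geomspace(8, 45, 12)])
    fit = fit_hill(ds)
    from molehb import p50_at_conditions as p50_at
    assert fit.p50 == pytest.approx(p50_at(effector_params, c), rel=1e-9)
    assert fit.n50 == pytest.approx(effector_params.hill_n, rel=1e-9)
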