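"""Excitation photon-budget model: attenuation, energies, repetition rate."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from deep3p.tissue_optics import (
    ConstraintViolation,
    LaserConfig,
    TissueOpticsModel,
    attenuation_factor,
    calibrate_depth,
    check_constraints,
    focus_pulse_energy,
    optimal_rep_rate,
    relative_signal,
    required_surface_energy,
    signal_ratio,
)

depths = st.floats(min_value=0.0, max_value=3000.0)
eals = st.floats(min_value=50.0, max_value=500.0)


class TestAttenuation:
    @pytest.mark.parametrize(
        "layers, z, expected",
        [
            (((1e7, 300.0),), 0.0, 1.0),
            (((1e7, 300.0),), 300.0, math.exp(-1)),
            # hand-summed segment ratios: 1000/300 + 200/150 + 300/300
            (((1000, 300), (200, 150), (1e7, 300)), 1500.0, math.exp(-17 / 3)),
        ],
    )
    def test_layered_path_integral(self, layers, z, expected):
        tissue = TissueOpticsModel(layers=layers)
        assert attenuation_factor(tissue, z) == pytest.approx(expected, rel=1e-12)

    def test_negative_depth_rejected(self, uniform_tissue):
        with pytest.raises(ValueError):
            attenuation_factor(uniform_tissue, -1.0)

    def test_deepest_layer_extends_indefinitely(self):
        tissue = TissueOpticsModel(layers=((100.0, 200.0),))
        assert attenuation_factor(tissue, 400.0) == pytest.approx(math.exp(-2))

    @given(z1=depths, z2=depths, eal=eals)
    def test_multiplicative_over_segments(self, z1, z2, eal):
        tissue = TissueOpticsModel.uniform(eal)
        a = attenuation_factor(tissue, z1 + z2)
        b = attenuation_factor(tissue, z1) * attenuation_factor(tissue, z2)
        assert a == pytest.approx(b, rel=1e-9)

    @given(z=st.floats(min_value=1.0, max_value=3000.0), eal=eals)
    def test_strictly_decreasing(self, z, eal):
        tissue = TissueOpticsModel.uniform(eal)
        assert attenuation_factor(tissue, z) < attenuation_factor(tissue, z - 0.5)


class TestPulseEnergies:
    def test_surface_energy_identity_at_zero_depth(self, uniform_tissue):
        assert focus_pulse_energy(2.0, uniform_tissue, 0.0) == pytest.approx(2.0)
        assert required_surface_energy(2.0, uniform_tissue, 0.0) == pytest.approx(2.0)

    def test_one_attenuation_length(self, uniform_tissue):
        assert focus_pulse_energy(5.0, uniform_tissue, 300.0) == pytest.approx(5 / math.e)
        assert required_surface_energy(2.0, uniform_tissue, 300.0) == pytest.approx(2 * math.e)

    def test_microjoule_surface_reaches_2nj_at_2mm(self):
        # EAL chosen so that e^{z/EAL} = 500 at z = 2000 um
        eal = 2000.0 / math.log(500.0)
        tissue = TissueOpticsModel.uniform(eal)
        assert focus_pulse_energy(1000.0, tissue, 2000.0) == pytest.approx(2.0, rel=1e-9)

    @given(e=st.floats(min_value=1e-3, max_value=1e4), z=depths, eal=eals)
    def test_exact_inverse_pair(self, e, z, eal):
        tissue = TissueOpticsModel.uniform(eal)
        roundtrip = focus_pulse_energy(required_surface_energy(e, tissue, z), tissue, z)
        assert roundtrip == pytest.approx(e, rel=1e-12)


class TestRepRate:
    def test_surface_endpoint_is_50mhz(self, uniform_tissue):
        assert optimal_rep_rate(uniform_tissue, 0.0) == pytest.approx(50e6)

    def test_one_eal_down(self, uniform_tissue):
        assert optimal_rep_rate(uniform_tissue, 300.0) == pytest.approx(50e6 / math.e)

    def test_100khz_operating_point(self):
        # same EAL as the 1 uJ -> 2 nJ pairing: f drops to ~0.1 MHz at 2 mm
        tissue = TissueOpticsModel.uniform(2000.0 / math.log(500.0))
        assert optimal_rep_rate(tissue, 2000.0) == pytest.approx(0.1e6, rel=1e-9)

    @given(z=depths, eal=eals)
    def test_power_budget_conservation(self, z, eal):
        """f(z) x Esurface(z) equals the surface power limit at every depth."""
        tissue = TissueOpticsModel.uniform(eal)
        f = optimal_rep_rate(tissue, z, psurface_max_mw=100.0, efocus_max_nj=2.0)
        esurf = required_surface_energy(2.0, tissue, z)
        assert f * esurf * 1e-6 == pytest.approx(100.0, rel=1e-9)


class TestSignalScaling:
    def test_high_energy_low_rate_hundredfold(self, uniform_tissue):
        a = LaserConfig.from_rep_rate(1e5, 1000.0)  # 1 uJ @ 100 kHz
        b = LaserConfig.from_rep_rate(1e6, 100.0)  # 0.1 uJ @ 1 MHz
        assert a.surface_power_mw == pytest.approx(b.surface_power_mw)
        assert signal_ratio(a, b, uniform_tissue, 2000.0) == pytest.approx(100.0)

    def test_cube_law_when_surface_energy_doubles(self, uniform_tissue):
        a = LaserConfig.from_rep_rate(1e6, 200.0)
        b = LaserConfig.from_rep_rate(1e6, 100.0)
        assert signal_ratio(a, b, uniform_tissue, 500.0) == pytest.approx(8.0)

    def test_halving_rate_at_fixed_power_quadruples(self, uniform_tissue):
        a = LaserConfig.from_power(100.0, 0.5e6)
        b = LaserConfig.from_power(100.0, 1e6)
        assert signal_ratio(a, b, uniform_tissue, 500.0) == pytest.approx(4.0)

    @given(
        ea=st.floats(min_value=1.0, max_value=1e3),
        eb=st.floats(min_value=1.0, max_value=1e3),
        z=depths,
    )
    def test_equal_power_ratio_is_squared_energy_ratio(self, ea, eb, z):
        tissue = TissueOpticsModel.uniform(300.0)
        power = 100.0
        a = LaserConfig.from_power(power, power / (ea * 1e-6))
        b = LaserConfig.from_power(power, power / (eb * 1e-6))
        assert signal_ratio(a, b, tissue, z) == pytest.approx((ea / eb) ** 2, rel=1e-6)

    @given(z=depths)
    def test_uniform_layer_decays_with_three_z_over_eal(self, z):
        """Signal at fixed surface config follows exp(-3z/EAL): brute-force
        evaluation of Pfocus^3/(f tau)^2 against the module's closed form."""
        tissue = TissueOpticsModel.uniform(300.0)
        cfg = LaserConfig.from_rep_rate(1e6, 100.0)
        a = math.exp(-z / 300.0)
        pfocus = cfg.surface_power_mw * a
        brute = pfocus**3 / (cfg.repetition_rate_hz * 1e-6 * cfg.pulse_width_s) ** 2
        got = relative_signal(cfg, tissue, z).relative_signal
        assert got == pytest.approx(brute, rel=1e-9)

    def test_unequal_tau_requires_flag(self, uniform_tissue):
        a = LaserConfig.from_rep_rate(1e6, 100.0, pulse_width_s=60e-15)
        b = LaserConfig.from_rep_rate(1e6, 100.0, pulse_width_s=120e-15)
        with pytest.raises(ValueError):
            signal_ratio(a, b, uniform_tissue, 0.0)
        assert signal_ratio(a, b, uniform_tissue, 0.0, allow_unequal_tau=True) == pytest.approx(4.0)


class TestConstraintsAndCalibration:
    def test_stated_maxima_pass(self):
        cfg = LaserConfig.from_power(100.0, 50e6, focus_pulse_energy_nj=2.0)
        assert check_constraints(cfg) == []

    @pytest.mark.parametrize(
        "power, rep_rate, efocus, bad_quantity",
        [(150.0, 50e6, 2.0, "surface_power_mw"), (50.0, 10e6, 3.0, "focus_pulse_energy_nj")],
    )
    def test_single_violation_named(self, power, rep_rate, efocus, bad_quantity):
        cfg = LaserConfig.from_power(power, rep_rate, focus_pulse_energy_nj=efocus)
        violations = check_constraints(cfg)
        assert [v.quantity for v in violations] == [bad_quantity]
        assert isinstance(violations[0], ConstraintViolation)

    @pytest.mark.parametrize("factor, expected", [(1.05, 2100.0), (1.10, 2200.0)])
    def test_depth_calibration_range(self, factor, expected):
        tissue = TissueOpticsModel.uniform(300.0, depth_calibration_factor=factor)
        assert calibrate_depth(2000.0, tissue) == pytest.approx(expected)
        assert calibrate_depth(0.0, tissue) == 0.0

    def test_negative_raw_depth_rejected(self, uniform_tissue):
        with pytest.raises(ValueError):
            calibrate_depth(-5.0, uniform_tissue)

    def test_inconsistent_laser_config_rejected(self):
        with pytest.raises(ValueError):
            LaserConfig(
                repetition_rate_hz=1e6,
                pulse_width_s=60e-15,
                surface_power_mw=50.0,  # should be 100 for 100 nJ @ 1 MHz
                surface_pulse_energy_nj=100.0,
            )
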