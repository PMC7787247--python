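"""Myelin capacitance, cable diffusion, velocity scaling and nuon
kinematics."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from inm.cable import (CableParams, MyelinGeometry, NuonKinematics,
                       NuonSection, accelerate_nuon, calibrate_nuon,
                       conduction_velocity, diffusion_coefficient,
                       gaussian_kernel_solution, myelin_capacitance,
                       optimal_core_radius, solve_cable)
from inm.errors import GeometryError, ValidationError


def geom(a1=0.6, a2=1.0, L=100.0, dm=10.0, cm=1.0):
    return MyelinGeometry(a1, a2, L, dm, cm)


class TestMyelinCapacitance:
    def test_thin_sheath_parallel_plate_limit(self):
        eps = 1e-6
        a1 = 5.0
        g = geom(a1=a1, a2=a1 * (1 + eps))
        # ln(1+eps) ~ eps: C -> c_m*2pi*d_m*L*a1/(a2-a1)
        c_m_si = 1.0 * 1e-2
        plate = c_m_si * 2 * np.pi * (10e-9) * (100e-6) / eps * 1e12
        assert myelin_capacitance(g) == pytest.approx(plate, rel=1e-4)

    def test_linear_in_length(self):
        assert myelin_capacitance(geom(L=200.0)) == pytest.approx(
            2 * myelin_capacitance(geom(L=100.0)))

    def test_discrete_shell_series_oracle(self):
        # 1000 concentric lamella capacitors in series
        g = geom()
        n_shell = 1000
        a = np.linspace(g.a1_um, g.a2_um, n_shell + 1)
        mid = 0.5 * (a[:-1] + a[1:]) * 1e-4          # cm
        da = np.diff(a) * 1e-4                       # cm
        d_m_cm = g.lamella_thickness_nm * 1e-7
        l_cm = g.length_um * 1e-4
        c_shell = 1e-6 * 2 * np.pi * mid * l_cm      # F per lamella
        inv_c = np.sum((da / d_m_cm) / c_shell)
        series = (1.0 / inv_c) * 1e12                # pF
        assert myelin_capacitance(g) == pytest.approx(series, rel=1e-3)

    def test_inverted_radii_rejected(self):
        with pytest.raises(GeometryError):
            geom(a1=1.0, a2=0.6)


class TestDiffusionCoefficient:
    def test_vanishes_at_both_radius_limits(self):
        cab = CableParams(100.0)
        assert diffusion_coefficient(geom(a1=1.0 - 1e-9), cab) == pytest.approx(
            0.0, abs=1e-9)
        assert diffusion_coefficient(geom(a1=1e-9), cab) == pytest.approx(
            0.0, abs=1e-12)

    def test_maximum_at_exp_minus_half(self):
        cab = CableParams(100.0)
        res = minimize_scalar(
            lambda a1: -diffusion_coefficient(geom(a1=a1), cab),
            bounds=(1e-3, 1.0 - 1e-9), method="bounded",
            options={"xatol": 1e-12})
        assert res.x == pytest.approx(np.exp(-0.5), abs=1e-6)

    def test_unit_bookkeeping_magnitude(self):
        # a1=0.6 um, a2=1 um, d_m=10 nm, c_m=1 uF/cm^2, r_L=100 ohm*cm
        d = diffusion_coefficient(geom(), CableParams(100.0))
        expected = ((0.6e-4) ** 2 * np.log(1 / 0.6)
                    / (2 * 1e-6 * 100.0 * 10e-7)) / 1e3
        assert d == pytest.approx(expected, rel=1e-12)


class TestOptimalRadius:
    def test_paper_scale_ratio(self):
        assert optimal_core_radius(1.0) == pytest.approx(0.6065, abs=5e-4)
        assert round(optimal_core_radius(1.0), 1) == 0.6

    def test_scale_invariance(self):
        for a2 in (0.2, 1.0, 7.5):
            assert optimal_core_radius(a2) / a2 == pytest.approx(
                np.exp(-0.5), abs=1e-12)

    def test_golden_section_agreement(self):
        cab = CableParams(35.4)
        g2 = lambda a1: -diffusion_coefficient(
            MyelinGeometry(a1, 2.0, 50.0, 15.0, 0.9), cab)
        res = minimize_scalar(g2, bounds=(1e-6, 2 - 1e-9), method="bounded",
                              options={"xatol": 1e-10})
        assert res.x / 2.0 == pytest.approx(np.exp(-0.5), abs=1e-8)


class TestCableSolver:
    def test_gaussian_variance_grows_as_2dt(self):
        d = 5e-3                     # cm^2/ms
        sigma0 = 0.02                # cm
        x = np.linspace(-0.5, 0.5, 801)
        v0 = np.exp(-x ** 2 / (2 * sigma0 ** 2))
        t = 1.0
        v = solve_cable(v0, d, t, (-0.5, 0.5), n_grid=801)
        var = np.sum(v * x ** 2) / np.sum(v)
        assert var == pytest.approx(sigma0 ** 2 + 2 * d * t, rel=0.01)

    def test_matches_heat_kernel_closed_form(self):
        d, sigma0 = 5e-3, 0.02
        x = np.linspace(-0.5, 0.5, 801)
        v0 = gaussian_kernel_solution(x, 0.0, d, sigma0)
        v = solve_cable(v0, d, 1.0, (-0.5, 0.5), n_grid=801)
        expected = gaussian_kernel_solution(x, 1.0, d, sigma0)
        assert np.max(np.abs(v - expected)) < 0.01 * expected.max()

    def test_time_zero_returns_initial_condition(self):
        x = np.linspace(0, 1, 64)
        v0 = np.sin(np.pi * x)
        np.testing.assert_array_equal(
            solve_cable(v0, 1e-3, 0.0, (0.0, 1.0), n_grid=64), v0)

    def test_zero_diffusion_is_frozen(self):
        x = np.linspace(0, 1, 64)
        v0 = np.sin(np.pi * x)
        np.testing.assert_array_equal(
            solve_cable(v0, 0.0, 5.0, (0.0, 1.0), n_grid=64), v0)

    def test_callable_initial_condition(self):
        v = solve_cable(lambda x: np.exp(-x ** 2), 1e-4, 0.1, (-1.0, 1.0),
                        n_grid=128)
        assert v.size == 128 and np.all(np.isfinite(v))


class TestVelocityScaling:
    def test_calibration_point(self):
        assert conduction_velocity(1.0, True, (1.0, 150.0)) == 150.0
        assert conduction_velocity(1.0, False, (1.0, 150.0)) == 150.0

    def test_myelinated_linear_in_radius(self):
        assert conduction_velocity(2.0, True, (1.0, 150.0)) == pytest.approx(300.0)

    def test_unmyelinated_square_root(self):
        assert conduction_velocity(4.0, False, (1.0, 5.0)) == pytest.approx(10.0)


class TestNuonKinematics:
    def intact(self, k=10):
        return tuple(NuonSection(100.0, 0.0) for _ in range(k))

    def test_energy_after_k_nodes(self):
        kin = NuonKinematics(effective_mass=1e-20,
                             effective_charge=1.602e-19, node_field=1e4,
                             node_gap_um=1.0, sections=self.intact(10))
        out = accelerate_nuon(kin)
        gain = kin.nodal_energy_gain
        np.testing.assert_allclose(out.energies,
                                   gain * np.arange(1, 11), rtol=1e-12)
        np.testing.assert_allclose(
            out.velocities,
            np.sqrt(2 * gain * np.arange(1, 11) / 1e-20), rtol=1e-12)

    def test_total_dissipation_stalls(self):
        secs = (NuonSection(100.0, 0.0), NuonSection(100.0, 1.0),
                NuonSection(100.0, 0.0))
        kin = NuonKinematics(1e-20, 1.6e-19, 1e4, 1.0, secs)
        out = accelerate_nuon(kin)
        assert out.velocities[1] == 0.0
        assert out.stalled

    def test_terminal_velocity_monotone_in_loss(self):
        terminal = []
        for loss in (0.0, 0.1, 0.3, 0.5, 0.7, 0.9):
            secs = tuple(NuonSection(100.0, loss) for _ in range(20))
            out = accelerate_nuon(NuonKinematics(1e-20, 1.6e-19, 1e4, 1.0,
                                                 secs))
            terminal.append(out.terminal_velocity)
        assert np.all(np.diff(terminal) < 0)
        assert terminal[0] > terminal[-1] > 0.0

    def test_exact_energy_bookkeeping(self):
        rng = np.random.default_rng(7)
        secs = tuple(NuonSection(50.0, lc)
                     for lc in rng.uniform(0, 0.4, size=15))
        kin = NuonKinematics(2e-20, 1.6e-19, 3e4, 1.5, secs)
        out = accelerate_nuon(kin)
        assert out.energies[-1] == pytest.approx(
            out.energy_gained - out.energy_lost, rel=1e-12)

    def test_calibration_round_trip(self):
        kin, degeneracy = calibrate_nuon(150.0, self.intact(100))
        out = accelerate_nuon(kin)
        assert out.terminal_velocity == pytest.approx(150.0, rel=1e-12)
        assert "q*E*gap" in degeneracy

    def test_doubling_mass_halves_v_squared(self):
        kin, _ = calibrate_nuon(100.0, self.intact(10))
        heavier = NuonKinematics(2 * kin.effective_mass,
                                 kin.effective_charge, kin.node_field,
                                 kin.node_gap_um, kin.sections)
        v2 = accelerate_nuon(heavier).terminal_velocity
        assert v2 ** 2 == pytest.approx(100.0 ** 2 / 2, rel=1e-12)

    def test_zero_nodes_cannot_calibrate(self):
        with pytest.raises(ValidationError):
            calibrate_nuon(150.0, ())

    def test_lossy_sections_cannot_calibrate(self):
        with pytest.raises(ValidationError):
            calibrate_nuon(150.0, (NuonSection(100.0, 0.5),))
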