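"""SST closure coefficients and the analytic flow fields."""

import numpy as np
import pytest
from scipy.integrate import quad

from aerodep.experiments import LPM
from aerodep.fields import (AirwayDuctField, BendField, PoiseuillePipeField,
                            UniformField, sst_alpha, sst_alpha_star,
                            sst_turbulent_viscosity)
from aerodep.geometry import ConfigurationError, make_bend_geometry


class TestSSTClosures:
    def test_alpha_star_low_re_constant(self):
        assert sst_alpha_star(0.0) == pytest.approx(0.024)

    def test_alpha_star_limits_and_midpoint(self):
        assert sst_alpha_star(6.0) == pytest.approx(0.512)
        assert sst_alpha_star(1e12) == pytest.approx(1.0, abs=1e-6)

    def test_alpha_star_monotone_bounded(self):
        ret = np.geomspace(1e-6, 1e8, 200)
        a = sst_alpha_star(ret)
        assert np.all(np.diff(a) > 0)
        assert np.all((a >= 0.024) & (a < 1.0))

    def test_alpha_high_re_limit(self):
        assert sst_alpha(1e10) == pytest.approx(0.52, abs=1e-6)
        # approach is monotone from above past moderate ret
        assert abs(sst_alpha(1e3) - 0.52) < abs(sst_alpha(10.0) - 0.52)

    def test_alpha_low_re_value(self):
        assert sst_alpha(0.0) == pytest.approx((0.52 / 0.024) / 9.0, rel=1e-12)

    def test_negative_ret_rejected(self):
        with pytest.raises(ValueError):
            sst_alpha_star(-1.0)
        with pytest.raises(ValueError):
            sst_alpha(-0.1)

    def test_turbulent_viscosity(self):
        # ret ~ 66.3 -> alpha* ~ 0.919
        assert sst_turbulent_viscosity(1.2, 1.0, 1000.0, 1.81e-5) == pytest.approx(
            1.10e-3, rel=1e-2)
        assert sst_turbulent_viscosity(1.2, 0.0, 1.0, 1.81e-5) == 0.0
        # high-ret limit: mu_t -> rho k / omega
        assert sst_turbulent_viscosity(1.2, 100.0, 10.0, 1.81e-5) == pytest.approx(
            1.2 * 100.0 / 10.0, rel=1e-4)

    def test_omega_must_be_positive_with_k(self):
        with pytest.raises(ValueError):
            sst_turbulent_viscosity(1.2, 1.0, 0.0, 1.81e-5)

    def test_coefficient_bundle_consistent(self):
        from aerodep.fields import TurbulenceClosureCoefficients
        c = TurbulenceClosureCoefficients.from_state(1.2, 1.0, 1000.0, 1.81e-5)
        assert c.ret == pytest.approx(1.2 / (1.81e-5 * 1000.0))
        assert c.alpha_star == pytest.approx(float(sst_alpha_star(c.ret)))
        assert 0.024 <= c.alpha_star < 1.0
        assert c.alpha > 0.52


class TestUniformField:
    def test_constant_everywhere(self, rng):
        f = UniformField([1.0, -2.0, 0.5])
        pts = rng.normal(size=(10, 3))
        u, k, _ = f.sample_batch(pts)
        assert np.all(u == [1.0, -2.0, 0.5])
        assert np.all(k == 0.0)

    def test_zero_vector_allowed(self):
        f = UniformField([0.0, 0.0, 0.0])
        assert np.all(f.sample([1, 2, 3]).velocity == 0.0)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            UniformField([np.nan, 0, 0])


class TestPoiseuillePipe:
    def test_profile(self):
        # Q = 10 L/min through R = 5 mm: U_mean ~ 2.122 m/s
        f = PoiseuillePipeField(0.005, 0.1, 10 * LPM)
        assert f.bulk_velocity == pytest.approx(2.122, abs=1e-3)
        center = f.sample([0.05, 0.0, 0.0]).velocity
        assert center[0] == pytest.approx(2 * f.bulk_velocity, rel=1e-12)
        wall = f.sample([0.05, 0.005, 0.0]).velocity
        assert np.linalg.norm(wall) == 0.0  # no-slip

    def test_flux_equals_q(self):
        f = PoiseuillePipeField(0.005, 0.1, 10 * LPM)
        R, Q = 0.005, 10 * LPM
        speed = lambda r: f.sample([0.05, r, 0.0]).velocity[0]
        flux, _ = quad(lambda r: speed(r) * 2 * np.pi * r, 0, R, epsabs=1e-14)
        assert flux == pytest.approx(Q, rel=1e-10)

    def test_classify_outside(self):
        f = PoiseuillePipeField(0.005, 0.1, 10 * LPM)
        assert f.classify([0.05, 0.006, 0.0])[0] == "wall"


class TestBendField:
    def test_direction_rotates_ninety_degrees(self, bend):
        f = BendField(bend, 10 * LPM)
        u_in = f.sample(np.asarray(bend.inlets[0]["center"])
                        + [1e-4, 0, 0]).velocity
        u_out = f.sample(bend.outlet_point - 1e-4 * bend.outlet_dir).velocity
        cosang = (u_in @ u_out) / (np.linalg.norm(u_in) * np.linalg.norm(u_out))
        assert cosang == pytest.approx(0.0, abs=1e-12)

    def test_plug_speed_conserves_flow(self, bend, rng):
        Q = 10 * LPM
        f = BendField(bend, Q)
        expected = Q / (np.pi * bend.info.tube_radius ** 2)
        # random interior points along the duct
        for _ in range(20):
            s = rng.uniform(0, bend.total_length)
            x = bend.tubes[0].centerline_point(s)
            assert np.linalg.norm(f.sample(x).velocity) == pytest.approx(
                expected, rel=1e-12)

    def test_plug_no_radial_component(self, bend):
        # uniform radius: velocity is purely axial
        f = BendField(bend, 10 * LPM)
        x = np.asarray(bend.inlets[0]["center"]) + [0.005, 0.002, 0.001]
        q = bend.query(x.reshape(1, 3))
        u = f.sample(x).velocity
        assert abs(u @ q.radial_unit[0]) < 1e-14

    def test_large_curvature_ratio_tends_to_straight(self):
        # over a fixed short arc the flow direction varies less and less
        for ratio, tol in ((10.0, 0.05), (1000.0, 5e-4)):
            g = make_bend_geometry(curvature_ratio=ratio, tube_radius=0.004)
            f = BendField(g, 10 * LPM)
            s0 = g.info.inlet_extension
            x0 = g.tubes[0].centerline_point(s0 + 1e-4)
            x1 = g.tubes[0].centerline_point(s0 + 0.004)  # one tube radius in
            u0 = f.sample(x0).velocity
            u1 = f.sample(x1).velocity
            misalign = 1 - (u0 @ u1) / (np.linalg.norm(u0) * np.linalg.norm(u1))
            assert misalign < tol

    def test_invalid_profile(self, bend):
        with pytest.raises(ConfigurationError):
            BendField(bend, 10 * LPM, profile="cubist")


class TestAirwayDuctField:
    def test_continuity_at_random_stations(self, airway, rng):
        """U(s) A(s) = Q_branch at 100 random stations (machine precision)."""
        Q = 10 * LPM
        f = AirwayDuctField(airway, Q)
        for _ in range(100):
            tube = airway.tubes[rng.integers(len(airway.tubes))]
            # skip the overlap just before the merge, where branch points
            # hand off to the (deeper) trunk tube by design
            s_hi = tube.s_end - (0.006 if tube.q_fraction < 1 else 1e-6)
            s = rng.uniform(tube.s_start + 1e-6, s_hi)
            x = tube.centerline_point(s)
            u = f.sample(x).velocity
            area = np.pi * float(tube.radius(s)) ** 2
            assert np.linalg.norm(u) * area == pytest.approx(
                Q * tube.q_fraction, rel=1e-10)

    def test_area_halves_speed_doubles(self, airway):
        f = AirwayDuctField(airway, 10 * LPM)
        trunk = airway.tubes[-1]
        speed_at = lambda s: np.linalg.norm(
            f.sample(trunk.centerline_point(s)).velocity)
        s_wide, s_glottis = 0.13, 0.20
        r_wide, r_gl = float(trunk.radius(s_wide)), float(trunk.radius(s_glottis))
        assert speed_at(s_glottis) / speed_at(s_wide) == pytest.approx(
            (r_wide / r_gl) ** 2, rel=1e-6)

    def test_branches_split_flow_equally(self, airway):
        f = AirwayDuctField(airway, 10 * LPM)
        uL = f.sample([-0.005, 0.0, 0.001]).velocity
        uR = f.sample([+0.005, 0.0, 0.001]).velocity
        assert np.linalg.norm(uL) == pytest.approx(np.linalg.norm(uR), rel=1e-12)

    def test_laminar_below_transition(self, airway):
        # at 10 L/min every station is laminar: k = 0 along the duct
        f = AirwayDuctField(airway, 10 * LPM)
        pts = [airway.tubes[-1].centerline_point(s)
               for s in np.linspace(0.115, 0.24, 30)]
        _, k, _ = f.sample_batch(np.array(pts))
        assert np.all(k == 0.0)

    def test_turbulent_at_high_rate(self, airway):
        # 45 L/min exceeds the transition threshold at the constrictions
        f = AirwayDuctField(airway, 45 * LPM)
        x_glottis = airway.tubes[-1].centerline_point(0.20)
        s = f.sample(x_glottis)
        assert s.k > 0.0
        assert s.omega > 0.0

    def test_no_slip_at_wall_point(self, airway):
        f = AirwayDuctField(airway, 10 * LPM)
        # radially outside the trunk: classified wall, zero velocity
        x = airway.tubes[-1].centerline_point(0.13) + np.array([0.02, 0, 0])
        assert np.linalg.norm(f.sample(x).velocity) == 0.0
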