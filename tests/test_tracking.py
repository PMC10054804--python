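"""Particle equation-of-motion integration, wall capture, dispersion."""

import numpy as np
import pandas as pd
import pytest

from aerodep.experiments import LPM
from aerodep.fields import (AirwayDuctField, BendField, FlowSample,
                            PoiseuillePipeField, UniformField)
from aerodep.physics import AIR, ParticleSpec
from aerodep.tracking import (ParticleState, TrackingConfig, detect_wall_crossing,
                              sample_eddy, step, track, track_ensemble)


def _state(x, v):
    return ParticleState(x=np.asarray(x, dtype=float),
                         v=np.asarray(v, dtype=float))


class TestStep:
    def test_no_slip_no_force(self, spec_6um):
        """u = v and g = 0: pure advection, velocity unchanged."""
        cfg = TrackingConfig(gravity=(0, 0, 0))
        u = np.array([0.5, 0.0, 0.0])
        s0 = _state([0, 0, 0], u)
        s1 = step(s0, FlowSample(velocity=u), spec_6um, AIR, 1e-3, cfg)
        assert np.allclose(s1.v, u, atol=1e-15)
        assert np.allclose(s1.x, u * 1e-3, rtol=1e-12)
        assert s1.t == pytest.approx(1e-3)

    def test_exponential_step_matches_closed_form(self, spec_6um):
        """One semi-analytic step equals the linear-ODE solution
        v(dt) = u + (v0 - u) exp(-f dt / tau_p) + gravity term."""
        cfg = TrackingConfig(gravity=(0, 0, -9.81))
        u = np.array([1.0, 0.0, 0.0])
        v0 = np.array([0.0, 0.2, 0.0])
        dt = 5e-5
        s1 = step(_state([0, 0, 0], v0), FlowSample(velocity=u),
                  spec_6um, AIR, dt, cfg)
        # slip < 1 m/s at 6 um -> Stokes regime, f = 1
        a = 1.0 / spec_6um.tau_p
        g = np.array([0, 0, -9.81])
        v_expect = (u + g / a) + (v0 - u - g / a) * np.exp(-a * dt)
        assert np.allclose(s1.v, v_expect, rtol=1e-12)

    def test_exponential_agrees_with_rk4_at_small_dt(self, spec_6um):
        u = np.array([1.0, -0.5, 0.0])
        v0 = np.array([0.0, 0.0, 0.3])
        dt = 0.02 * spec_6um.tau_p
        args = (FlowSample(velocity=u), spec_6um, AIR, dt)
        s_exp = step(_state([0, 0, 0], v0), *args, TrackingConfig())
        s_rk4 = step(_state([0, 0, 0], v0), *args, TrackingConfig(scheme="rk4"))
        assert np.allclose(s_exp.v, s_rk4.v, rtol=1e-9)
        assert np.allclose(s_exp.x, s_rk4.x, rtol=1e-9)

    def test_nan_flow_raises(self, spec_6um):
        from aerodep.tracking import NumericalStateError
        with pytest.raises(NumericalStateError):
            step(_state([0, 0, 0], [0, 0, 0]),
                 FlowSample(velocity=np.array([np.nan, 0, 0])),
                 spec_6um, AIR, 1e-4, TrackingConfig())

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrackingConfig(dt_tau_fraction=0.0)
        with pytest.raises(ValueError):
            TrackingConfig(scheme="leapfrog")


class TestTerminalVelocity:
    @pytest.mark.parametrize("dp_um", [1.0, 3.0, 6.0])
    def test_stokes_settling(self, dp_um):
        """Settling in quiescent air reaches tau_p * g within 0.1%."""
        spec = ParticleSpec.from_diameter(dp_um * 1e-6)
        cfg = TrackingConfig(dt_max=spec.tau_p, max_time=50 * spec.tau_p)
        field = UniformField([0.0, 0.0, 0.0])
        state = _state([0, 0, 0], [0, 0, 0])
        for _ in range(200):
            state = step(state, field.sample(state.x), spec, AIR,
                         spec.tau_p, cfg)
        v_term = np.linalg.norm(state.v)
        assert v_term == pytest.approx(spec.tau_p * 9.81, rel=1e-3)

    def test_six_micron_terminal_speed_value(self):
        spec = ParticleSpec.from_diameter(6e-6)
        assert spec.tau_p * 9.81 == pytest.approx(1.11e-3, rel=5e-3)


class TestWallCrossing:
    def test_interior_chord_empty(self, bend):
        c = np.asarray(bend.inlets[0]["center"], dtype=float)
        assert detect_wall_crossing(c + [1e-4, 0, 0], c + [2e-3, 0, 0],
                                    bend) is None

    def test_radial_hit_at_tube_radius(self, bend):
        c = np.asarray(bend.inlets[0]["center"], dtype=float)
        R = bend.info.tube_radius
        hit = detect_wall_crossing(c + [1e-3, 0, 0], c + [1e-3, 2 * R, 0], bend)
        assert hit is not None
        point, region, _ = hit
        radial = np.linalg.norm(point[1:] - c[1:])
        assert radial == pytest.approx(R, abs=1e-8)
        assert region == "inlet_extension"

    def test_grazing_chord_against_dense_oracle(self, bend):
        """A chord leaving and re-entering the duct is caught; brute-force
        dense sampling of the segment is the oracle."""
        R = bend.info.tube_radius
        c = np.asarray(bend.inlets[0]["center"], dtype=float)
        x0 = c + np.array([1e-3, 0.90 * R, 0.0])
        x1 = c + np.array([9e-3, 0.90 * R, 0.0])
        # push the midpoint outside by bowing the chord in +y: emulate with
        # a straight chord whose ends are inside but midpoint outside the
        # curved wall of the bend entrance
        ts = np.linspace(0, 1, 10001)
        pts = x0 + ts[:, None] * (x1 - x0)
        depths = bend.query(pts).depth
        oracle_crosses = bool(np.any(depths >= 0))
        hit = detect_wall_crossing(x0, x1, bend, n_probe=64)
        assert (hit is not None) == oracle_crosses

    def test_exterior_start_is_logic_error(self, bend):
        c = np.asarray(bend.inlets[0]["center"], dtype=float)
        with pytest.raises(RuntimeError):
            detect_wall_crossing(c + [1e-3, 0.01, 0], c, bend)


class TestSampleEddy:
    def test_laminar_degeneracy(self, rng):
        fluct, life = sample_eddy(0.0, 1.0, rng, TrackingConfig())
        assert np.all(fluct == 0.0)
        assert life == np.inf

    def test_component_variance(self):
        rng = np.random.default_rng(7)
        k = 0.15
        draws = np.array([sample_eddy(k, 100.0, rng, TrackingConfig())[0]
                          for _ in range(30000)])
        var = draws.var(axis=0)
        expected = 2 * k / 3
        se = expected * np.sqrt(2 / 30000)
        assert np.all(np.abs(var - expected) < 4 * se)

    def test_lifetime_formula(self, rng):
        cfg = TrackingConfig()
        _, life = sample_eddy(0.5, 200.0, rng, cfg)
        assert life == pytest.approx(0.15 / (0.09 * 200.0))

    def test_seed_determinism(self):
        cfg = TrackingConfig()
        a = sample_eddy(0.2, 50.0, np.random.default_rng(3), cfg)[0]
        b = sample_eddy(0.2, 50.0, np.random.default_rng(3), cfg)[0]
        assert np.array_equal(a, b)


class TestTrack:
    def test_tracer_follows_streamline_in_pipe(self):
        """tau_p -> 0 limit: an off-axis tracer in laminar pipe flow exits
        with negligible lateral displacement."""
        field = PoiseuillePipeField(0.005, 0.05, 10 * LPM)
        spec = ParticleSpec.from_diameter(0.05e-6)  # 50 nm tracer
        y0 = 0.002
        st = _state([1e-6, y0, 0.0], field.sample([1e-6, y0, 0.0]).velocity)
        rec = track(spec, st, field, config=TrackingConfig(gravity=(0, 0, 0)))
        assert rec.fate == "escaped"
        # lateral displacement check via a second tracer run with recording
        rec2 = track(spec, st, field, config=TrackingConfig(gravity=(0, 0, 0)),
                     trajectory_every=1)
        lateral = np.abs(rec2.trajectory[:, 2] - y0).max()
        assert lateral < 1e-6 * 0.005

    def test_ballistic_limit_deposits_on_outer_bend(self, bend):
        field = BendField(bend, 10 * LPM)
        spec = ParticleSpec.from_diameter(80e-6)  # Stk >> 1
        c = np.asarray(bend.inlets[0]["center"], dtype=float)
        st = _state(c + [1e-4, 0, 0], field.sample(c + [1e-4, 0, 0]).velocity)
        rec = track(spec, st, field, config=TrackingConfig(gravity=(0, 0, 0)))
        assert rec.fate == "deposited"
        assert rec.region_at_fate == "bend"

    def test_airway_record_structurally_valid(self, airway, airway_field_10lpm):
        spec = ParticleSpec.from_diameter(16e-6)
        x0 = np.array([-0.005, 0.0, 1e-6])
        st = _state(x0, airway_field_10lpm.sample(x0).velocity)
        rec = track(spec, st, airway_field_10lpm, airway)
        assert rec.fate in ("deposited", "escaped")
        if rec.fate == "deposited":
            assert rec.region_at_fate in airway.regions
        assert rec.arc_length_at_fate <= airway.total_length + 1e-12


class TestTrackEnsemble:
    def test_determinism_and_conservation(self, airway, airway_field_10lpm):
        spec = ParticleSpec.from_diameter(6e-6)
        cfg = TrackingConfig(seed=21)
        a = track_ensemble(400, spec, airway_field_10lpm, airway, config=cfg)
        b = track_ensemble(400, spec, airway_field_10lpm, airway, config=cfg)
        pd.testing.assert_frame_equal(a, b)
        counts = a["fate"].value_counts()
        assert counts.sum() == 400
        assert counts.get("active", 0) == 0

    def test_fate_positions_not_interior(self, airway, airway_field_10lpm):
        """Trap-on-contact: deposited fate positions sit on the wall."""
        spec = ParticleSpec.from_diameter(16e-6)
        rec = track_ensemble(300, spec, airway_field_10lpm, airway,
                             config=TrackingConfig(seed=5))
        dep = rec[rec["fate"] == "deposited"]
        assert len(dep) > 0
        assert dep["region"].notna().all()
        assert (dep["s_m"] <= airway.total_length).all()

    def test_scheme_agreement_on_bend(self, bend):
        """Exponential and rk4 fates agree for >= 99% of particles."""
        field = BendField(bend, 10 * LPM)
        fates = {}
        for scheme in ("semi_analytic_exponential", "rk4"):
            cfg = TrackingConfig(seed=13, scheme=scheme, gravity=(0, 0, 0))
            spec = ParticleSpec.from_diameter(12e-6)
            rec = track_ensemble(500, spec, field, bend, config=cfg)
            fates[scheme] = rec["fate"].astype(str).to_numpy()
        agree = np.mean(fates["semi_analytic_exponential"] == fates["rk4"])
        assert agree >= 0.99

    def test_drw_with_zero_k_is_bitwise_laminar(self, airway):
        """Eddy-interaction mode degenerates to laminar tracking when the
        carrier field is laminar everywhere (k = 0)."""
        field = AirwayDuctField(airway, 10 * LPM)  # all laminar at 10 L/min
        spec = ParticleSpec.from_diameter(3e-6)
        base = TrackingConfig(seed=17)
        off = track_ensemble(200, spec, field, airway, config=base)
        from dataclasses import replace
        drw = track_ensemble(200, spec, field, airway,
                             config=replace(base, dispersion="eddy_interaction"))
        pd.testing.assert_frame_equal(off, drw)

    def test_drw_disperses_when_turbulent(self, airway):
        field = AirwayDuctField(airway, 45 * LPM)
        spec = ParticleSpec.from_diameter(3e-6)
        base = TrackingConfig(seed=17)
        off = track_ensemble(200, spec, field, airway, config=base)
        from dataclasses import replace
        drw = track_ensemble(200, spec, field, airway,
                             config=replace(base, dispersion="eddy_interaction"))
        assert not off["t_s"].equals(drw["t_s"])
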