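"""Particle tracking: RK4 accuracy, arrest rules, conservation."""

import numpy as np
import pandas as pd
import pytest

from reefsources.dispersal import (DispersalParams, run_event,
                                   simulate_release, step_rk4)
from reefsources.synth.currents import VelocityField
from reefsources.synth.seascape import Seascape

from conftest import square_reef, uniform_field


def rotation_field(omega_per_h: float, cx: float, cy: float,
                   extent: float = 200.0, spacing: float = 2.0) -> VelocityField:
    """Solid-body rotation about (cx, cy); angular rate in rad/hour."""
    x = np.arange(0.0, extent + spacing, spacing)
    y = np.arange(0.0, extent + spacing, spacing)
    X, Y = np.meshgrid(x, y)
    # km/h converted to m/s for storage
    u = (-omega_per_h * (Y - cy)) / 3.6
    v = (omega_per_h * (X - cx)) / 3.6
    t = np.array([0.0, 1e6])
    return VelocityField(x=x, y=y, times=t,
                         u=np.stack([u, u]), v=np.stack([v, v]))


class TestStepRK4:
    def test_zero_field_leaves_position(self):
        fld = uniform_field(0.0, 0.0)
        out = step_rk4(np.array([[50.0, 50.0]]), fld, t=0.0, dt=1.0)
        assert np.allclose(out, [[50.0, 50.0]])

    def test_uniform_flow_exact_displacement(self):
        # 0.1 m/s for one hour = 0.36 km, exact for a constant field
        fld = uniform_field(0.1, 0.0)
        out = step_rk4(np.array([[50.0, 50.0]]), fld, t=0.0, dt=1.0)
        assert out[0, 0] == pytest.approx(50.36, abs=1e-9)
        assert out[0, 1] == pytest.approx(50.0, abs=1e-12)

    def test_solid_body_rotation_radius_drift(self):
        # oracle: analytic circle; RK4 at hourly steps over one full period
        period_h = 96.0
        omega = 2 * np.pi / period_h
        fld = rotation_field(omega, 100.0, 100.0)
        pos = np.array([[130.0, 100.0]])  # radius 30 km
        for step in range(int(period_h)):
            pos = step_rk4(pos, fld, t=float(step), dt=1.0)
        radius = np.hypot(pos[0, 0] - 100.0, pos[0, 1] - 100.0)
        assert abs(radius - 30.0) / 30.0 < 1e-3

    def test_halving_dt_converges(self):
        omega = 2 * np.pi / 96.0
        fld = rotation_field(omega, 100.0, 100.0)

        def integrate(dt):
            pos = np.array([[130.0, 100.0]])
            for i in range(int(48 / dt)):
                pos = step_rk4(pos, fld, t=i * dt, dt=dt)
            return pos

        err = np.abs(integrate(1.0) - integrate(0.5)).max()
        assert err < 1e-3  # km over half a period


def _line_field_scape():
    """A small source reef and a wide target reef downstream of a uniform
    0.1 m/s (+x) flow, sized so the arrest halo cannot be jumped between
    two 12-h proximity checks."""
    reefs = [square_reef("A", 10, 50), square_reef("B", 40, 50, half=3.0)]
    scape = Seascape(reefs=reefs, domain=(0, 0, 200, 100), grid_spacing=4.0)
    return scape, uniform_field(0.1, 0.0)


class TestSimulateRelease:
    def test_downstream_arrest_at_hand_computed_age(self):
        # oracle: constant-flow kinematics. 0.1 m/s = 0.36 km/h; B spans
        # x in [37, 43], halo entry at x = 36.  A particle released at
        # x0 in [9, 11] enters at t = (36 - x0)/0.36 in [69.4, 75.0] h and
        # stays in the halo for 8/0.36 = 22 h, so the first 12-h check
        # inside the halo is at 72 h (for x0 >= 10.08) or 84 h: arrest age
        # is exactly 3.0 or 3.5 days at B.
        scape, fld = _line_field_scape()
        params = DispersalParams(n_runs=1, particles_per_run=200,
                                 diffusivity_m2_s=0.0, max_days=10)
        rec = simulate_release(scape.reefs[0], scape, fld, 0.0, params, seed=3)
        assert (rec["fate"] == "arrested").all()
        assert set(rec["sink_id"]) == {"B"}
        assert set(rec["arrest_age_days"]) == {3.0, 3.5}

    def test_arrest_zone_boundary(self):
        # a particle 0.9 km from the reef boundary is arrested, 1.1 km is not
        from reefsources.dispersal import _nearest_eligible
        import shapely
        scape, _ = _line_field_scape()
        tree = shapely.STRtree([scape.reefs[0].polygon])  # A spans x in [9, 11]
        hit, _ = _nearest_eligible(np.array([[11.9, 50.0]]), tree, 1.0)
        assert hit[0] == 0
        hit, _ = _nearest_eligible(np.array([[12.1, 50.0]]), tree, 1.0)
        assert hit[0] == -1

    def test_nearest_reef_wins_with_id_tiebreak(self):
        from reefsources.dispersal import _nearest_eligible
        import shapely
        a = square_reef("A", 10, 50).polygon
        b = square_reef("B", 14, 50).polygon   # edges at x=11 and x=13
        tree = shapely.STRtree([a, b])
        hit, _ = _nearest_eligible(np.array([[11.8, 50.0]]), tree, 1.0)
        assert hit[0] == 0   # nearer to A
        hit, _ = _nearest_eligible(np.array([[12.0, 50.0]]), tree, 1.0)
        assert hit[0] == 0   # exact tie -> smaller index

    def test_never_near_reef_is_lost_at_max_days(self):
        reefs = [square_reef("A", 100, 50)]
        scape = Seascape(reefs=reefs, domain=(0, 0, 200, 100), grid_spacing=4.0)
        fld = uniform_field(0.0, 0.05)  # slow drift away from the reef
        params = DispersalParams(n_runs=1, particles_per_run=50,
                                 diffusivity_m2_s=0.0, max_days=5)
        rec = simulate_release(reefs[0], scape, fld, 0.0, params, seed=2)
        # self-arrest requires first exiting the 1-km zone: drift 0.18 km/h
        # leaves the zone (>= 2 km travel) after ~11-22 h, then no reef is
        # ever within 1 km again except the source itself behind it
        lost = rec[rec["fate"] == "lost"]
        assert len(lost) > 0
        assert lost["arrest_age_days"].isna().all()

    def test_out_of_domain_particles_lost(self):
        reefs = [square_reef("A", 195, 50)]
        scape = Seascape(reefs=reefs, domain=(0, 0, 200, 100), grid_spacing=4.0)
        fld = uniform_field(1.0, 0.0, extent=200.0)  # 3.6 km/h toward +x edge
        params = DispersalParams(n_runs=1, particles_per_run=50,
                                 diffusivity_m2_s=0.0, max_days=10)
        rec = simulate_release(reefs[0], scape, fld, 0.0, params, seed=5)
        assert (rec["fate"] == "lost").all()


class TestRunEvent:
    def _toy(self):
        scape, fld = _line_field_scape()
        params = DispersalParams(n_runs=2, particles_per_run=50,
                                 diffusivity_m2_s=5.0, max_days=10)
        return scape, fld, params

    def test_conservation_per_source_reef(self):
        scape, fld, params = self._toy()
        tab = run_event(scape, fld, "E00", 0.0, params, seed=11)
        tab.check_conservation()
        counts = tab.records.groupby("source_id").size()
        for rid in scape.ids:
            assert counts[rid] == params.n_runs * params.particles_per_run

    def test_arrest_ages_are_check_multiples(self):
        scape, fld, params = self._toy()
        tab = run_event(scape, fld, "E00", 0.0, params, seed=11)
        ages = tab.arrivals()["arrest_age_days"].to_numpy()
        assert len(ages) > 0
        steps = ages * 24.0 / params.check_interval_hours
        assert np.allclose(steps, np.round(steps))
        assert (ages > 0).all() and (ages <= params.max_days).all()

    def test_zero_diffusivity_bitwise_deterministic(self):
        scape, fld, _ = self._toy()
        params = DispersalParams(n_runs=1, particles_per_run=40,
                                 diffusivity_m2_s=0.0, max_days=5)
        a = run_event(scape, fld, "E00", 0.0, params, seed=11)
        b = run_event(scape, fld, "E00", 0.0, params, seed=11)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_brute_force_oracle_on_designed_flow(self):
        """Independent straight-line integrator at dt = 0.1 h reproduces the
        arrest counts of the RK4 pipeline in a uniform field."""
        scape, fld, _ = self._toy()
        params = DispersalParams(n_runs=1, particles_per_run=100,
                                 diffusivity_m2_s=0.0, max_days=10)
        tab = run_event(scape, fld, "E00", 0.0, params, seed=4)

        # oracle: re-simulate with explicit Euler at dt=0.1 h (uniform flow
        # makes Euler exact too), applying the same arrest rules
        from reefsources.dispersal import _uniform_in_polygon
        import shapely
        rng_states = {}
        oracle_counts = {}
        for ir, reef in enumerate(scape.reefs):
            from reefsources.dispersal import _release_seed
            rng = np.random.default_rng(_release_seed(4, ir, 0))
            pos = _uniform_in_polygon(reef.polygon, 100, rng)
            vel = np.array([0.1 * 3.6, 0.0])  # km/h
            arrested = {}
            active = np.ones(100, dtype=bool)
            exited = np.zeros(100, dtype=bool)
            for check in range(1, int(params.max_days * 2) + 1):
                t_h = check * 12.0
                cur = pos + vel * t_h
                for k in np.flatnonzero(active):
                    pt = shapely.Point(cur[k])
                    d_src = reef.polygon.distance(pt)
                    if d_src > 1.0:
                        exited[k] = True
                    best, bestd = None, np.inf
                    for jr, other in enumerate(scape.reefs):
                        if jr == ir and not exited[k]:
                            continue
                        d = other.polygon.distance(pt)
                        if d < 1.0 and d < bestd:
                            best, bestd = jr, d
                    if best is not None:
                        arrested[k] = (scape.ids[best], t_h / 24.0)
                        active[k] = False
            oracle_counts[reef.id] = {}
            for sink, age in arrested.values():
                key = (sink, age)
                oracle_counts[reef.id][key] = oracle_counts[reef.id].get(key, 0) + 1

        arr = tab.arrivals()
        for rid in scape.ids:
            sub = arr[arr["source_id"] == rid]
            got = sub.groupby(["sink_id", "arrest_age_days"]).size().to_dict()
            assert got == oracle_counts[rid]

    def test_event_window_must_fit_record(self):
        scape, fld, params = self._toy()
        with pytest.raises(ValueError):
            run_event(scape, fld, "E00", fld.times[-1] - 24.0, params, seed=0)
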