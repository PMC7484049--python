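"""Map, feedback kernel, drive, and orbit-iteration behavior."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import rrochaos as rc
from rrochaos.dynamics import evolve


class TestMapF:
    def test_zero_fixed_point(self):
        assert rc.map_F(0.0, rc.ModelParams(A=9.8)) == 0.0

    def test_high_precision_value(self):
        # 5.82*tanh(1.487) - 13*tanh(0.2223), evaluated independently
        expected = 5.82 * math.tanh(1.487) - 13.0 * math.tanh(0.2223)
        assert rc.map_F(1.0, rc.ModelParams(A=13.0)) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(2.411, abs=5e-4)

    @given(x=st.floats(-4, 4), A=st.floats(0, 15))
    @settings(deadline=None, max_examples=50)
    def test_odd(self, x, A):
        m = rc.ModelParams(A=A)
        assert rc.map_F(-x, m) == pytest.approx(-float(rc.map_F(x, m)), abs=1e-12)

    @given(x=st.floats(-50, 50), A=st.floats(0, 15))
    @settings(deadline=None, max_examples=50)
    def test_bounded(self, x, A):
        m = rc.ModelParams(A=A)
        assert abs(rc.map_F(x, m)) <= m.B + m.A

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            rc.map_F(float("nan"), rc.ModelParams(A=9.8))


class TestRROFeedback:
    def test_zero_at_merging_point(self):
        assert rc.rro_u(0.3, rc.ControlParams(x_d=0.3)) == 0.0

    def test_closed_form(self):
        assert rc.rro_u(1.0, rc.ControlParams()) == pytest.approx(-math.exp(-0.5), abs=1e-15)

    @given(t=st.floats(0, 3), x_d=st.floats(-1, 1), sigma=st.floats(0.2, 3))
    @settings(deadline=None, max_examples=50)
    def test_antisymmetric_about_xd(self, t, x_d, sigma):
        c = rc.ControlParams(x_d=x_d, sigma=sigma)
        assert rc.rro_u(x_d + t, c) == pytest.approx(-float(rc.rro_u(x_d - t, c)), abs=1e-12)

    def test_extrema_location_and_magnitude(self):
        c = rc.ControlParams(sigma=1.7, x_d=0.4)
        peak = float(rc.rro_u(c.x_d - c.sigma, c))
        assert peak == pytest.approx(c.sigma * math.exp(-0.5), abs=1e-12)
        eps = 1e-4
        assert peak >= rc.rro_u(c.x_d - c.sigma + eps, c)
        assert peak >= rc.rro_u(c.x_d - c.sigma - eps, c)


class TestDrive:
    def test_zero_amplitude(self):
        assert np.all(rc.drive_S(np.arange(100), rc.DriveParams(alpha=0.0)) == 0.0)

    def test_peak_at_quarter_period(self):
        d = rc.DriveParams(alpha=0.15, p=32)
        assert rc.drive_S(8, d) == pytest.approx(0.15, abs=1e-15)

    def test_periodicity(self):
        d = rc.DriveParams(alpha=0.3, p=16)
        n = np.arange(200)
        np.testing.assert_allclose(rc.drive_S(n + d.p, d), rc.drive_S(n, d), atol=1e-14)


class TestCompositeMap:
    def test_reduces_to_F_at_K0(self):
        m, c = rc.ModelParams(A=12.0), rc.ControlParams(K=0.0)
        xs = np.linspace(-4, 4, 100)
        np.testing.assert_array_equal(rc.composite_map(xs, m, c), rc.map_F(xs, m))

    def test_odd_with_centered_feedback(self):
        m, c = rc.ModelParams(A=12.0), rc.ControlParams(K=0.7)
        xs = np.linspace(-4, 4, 100)
        np.testing.assert_allclose(rc.composite_map(-xs, m, c),
                                   -rc.composite_map(xs, m, c), atol=1e-12)

    @given(A=st.floats(0, 15), K=st.floats(0, 1))
    @settings(deadline=None, max_examples=30)
    def test_origin_fixed(self, A, K):
        assert rc.composite_map(0.0, rc.ModelParams(A=A), rc.ControlParams(K=K)) == 0.0

    def test_derivative_matches_finite_difference(self):
        m, c = rc.ModelParams(A=9.8), rc.ControlParams(K=0.3)
        xs = np.linspace(-3, 3, 41)
        h = 1e-6
        fd = (rc.composite_map(xs + h, m, c) - rc.composite_map(xs - h, m, c)) / (2 * h)
        np.testing.assert_allclose(rc.composite_deriv(xs, m, c), fd, atol=1e-7)


class TestIterate:
    def test_origin_stays_fixed(self):
        traj = rc.iterate(rc.ModelParams(A=9.8), rc.ControlParams(K=0.5),
                          rc.DriveParams(alpha=0.0),
                          rc.SimulationConfig(n_transient=10, n_measure=100), 0.0)
        assert np.all(traj.x == 0.0)

    def test_period4_state(self, cfg):
        traj = rc.iterate(rc.ModelParams(A=13.0), rc.ControlParams(),
                          rc.DriveParams(), cfg, 0.5)
        vals = np.unique(np.round(traj.x[-400:], 9))
        assert len(vals) == 4

    def test_deterministic(self, cfg):
        args = (rc.ModelParams(A=9.8), rc.ControlParams(K=0.06),
                rc.DriveParams(alpha=0.15, p=32), cfg, 0.731)
        a, b = rc.iterate(*args), rc.iterate(*args)
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.s, b.s)
        np.testing.assert_array_equal(a.u_applied, b.u_applied)

    @given(x0=st.floats(-2.5, 2.5).filter(lambda v: abs(v) > 1e-3),
           A=st.floats(5, 15), K=st.floats(0, 1))
    @settings(deadline=None, max_examples=15)
    def test_negated_initial_condition_mirrors_orbit(self, x0, A, K):
        m, c, d = rc.ModelParams(A=A), rc.ControlParams(K=K), rc.DriveParams(alpha=0.0)
        cfg = rc.SimulationConfig(n_transient=50, n_measure=200)
        a = evolve(x0, m, c, d, cfg.n_transient, cfg.n_measure)
        b = evolve(-x0, m, c, d, cfg.n_transient, cfg.n_measure)
        np.testing.assert_allclose(b, -a, atol=1e-12)

    @given(x0=st.floats(-2.5, 2.5), A=st.floats(5, 15), K=st.floats(0, 1),
           alpha=st.floats(0, 0.3))
    @settings(deadline=None, max_examples=15)
    def test_bounded_orbits(self, x0, A, K, alpha):
        """Post-transient confinement |x| < 4 over the studied weak-drive regime."""
        xs = evolve(x0, rc.ModelParams(A=A), rc.ControlParams(K=K),
                    rc.DriveParams(alpha=alpha, p=32), 200, 500)
        assert np.abs(xs).max() < 4.0

    def test_bounded_orbit_at_strongest_forcing(self):
        """The strongest forced-baseline drive still keeps the orbit confined."""
        xs = evolve(0.5, rc.ModelParams(A=12.0), rc.ControlParams(),
                    rc.DriveParams(alpha=1.2, p=32), 1000, 5000)
        assert np.abs(xs).max() < 4.0

    def test_drive_and_feedback_channels_match_states(self, cfg):
        m, c, d = rc.ModelParams(A=9.8), rc.ControlParams(K=0.06), rc.DriveParams(alpha=0.15, p=32)
        traj = rc.iterate(m, c, d, cfg, 0.5)
        np.testing.assert_allclose(traj.s, rc.drive_S(traj.steps(), d), atol=1e-15)
        np.testing.assert_allclose(traj.u_applied, c.K * rc.rro_u(traj.x, c), atol=1e-15)
        # the recorded channels reproduce the recursion itself
        pred = rc.map_F(traj.x[:-1], m) + traj.u_applied[:-1] + traj.s[:-1]
        np.testing.assert_allclose(pred, traj.x[1:], atol=1e-12)

    def test_nonfinite_x0_rejected(self, cfg):
        with pytest.raises(ValueError):
            rc.iterate(rc.ModelParams(A=9.8), rc.ControlParams(), rc.DriveParams(),
                       cfg, float("inf"))

    def test_csv_roundtrip(self, tmp_path, cfg):
        traj = rc.iterate(rc.ModelParams(A=9.8), rc.ControlParams(K=0.06),
                          rc.DriveParams(alpha=0.15, p=32),
                          rc.SimulationConfig(n_transient=10, n_measure=50), 0.5)
        path = tmp_path / "orbit.csv"
        traj.save(path)
        back = pd.read_csv(path, float_precision="round_trip")
        np.testing.assert_array_equal(back["x"].to_numpy(), traj.x)
        assert (tmp_path / "orbit.csv.meta.json").exists()


class TestParamValidation:
    @pytest.mark.parametrize("bad", [
        lambda: rc.ModelParams(A=-1.0),
        lambda: rc.ModelParams(A=9.8, w1=0.0),
        lambda: rc.ControlParams(sigma=0.0),
        lambda: rc.ControlParams(K=-0.1),
        lambda: rc.DriveParams(alpha=-0.2),
        lambda: rc.DriveParams(p=1),
        lambda: rc.SimulationConfig(n_measure=0),
    ])
    def test_invariant_violations_raise(self, bad):
        with pytest.raises(ValueError):
            bad()
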