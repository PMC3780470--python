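"""Forward model: impulse response, compartment ODEs, measurement equation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from renalkin.kinetic_model import (
    FrameSchedule,
    ImpulseResponse,
    InputFunction,
    RateConstants,
    TimeActivityCurve,
    distribution_volumes,
    impulse_response,
    model_tac,
    retention_from_irf,
    retention_from_tac,
    solve_compartments,
)

rate_constants = st.builds(
    RateConstants,
    K1=st.floats(0.1, 3.0), k2=st.floats(0.15, 0.6),
    K3=st.floats(0.05, 0.5), k4=st.floats(0.005, 0.05),
)


class TestFrameSchedule:
    def test_mid_times_and_span(self):
        s = FrameSchedule.from_durations([0.5, 0.5, 1.0])
        assert np.allclose(s.mid_times, [0.25, 0.75, 1.5])
        assert s.end_time == 2.0

    @pytest.mark.parametrize(
        "starts,durs",
        [
            ([0.0, 0.4], [0.5, 0.5]),       # overlap
            ([0.0, 0.6], [0.5, 0.5]),       # gap
            ([0.1, 0.6], [0.5, 0.5]),       # first start not 0
            ([0.0, 0.5], [0.5, -0.5]),      # negative duration
            ([0.5, 0.0], [0.5, 0.5]),       # decreasing starts
        ],
    )
    def test_invalid_schedules_rejected(self, starts, durs):
        with pytest.raises(ValueError):
            FrameSchedule(np.array(starts), np.array(durs))


class TestImpulseResponse:
    @pytest.mark.parametrize(
        "rc,t,expected",
        [
            ((1.0, 0.3, 1.0, 0.013), 0.0, 2.0),
            ((0.985, 0.246, 0.212, 0.013), 0.0, 1.197),
            ((1.0, 0.3, 1.0, 0.013), 80.0, np.exp(-24.0) + np.exp(-1.04)),
        ],
    )
    def test_pointwise_values(self, rc, t, expected):
        assert impulse_response(RateConstants(*rc), t) == pytest.approx(expected, rel=1e-12)

    def test_negative_time_rejected(self, control_rc):
        with pytest.raises(ValueError):
            impulse_response(control_rc, np.array([-0.1, 1.0]))

    @given(rc=rate_constants)
    def test_strictly_decreasing(self, rc):
        t = np.linspace(0.0, 90.0, 200)
        f = impulse_response(rc, t)
        assert np.all(np.diff(f) < 0)


class TestSolveCompartments:
    def test_zero_input_gives_zero_trajectories(self, control_rc):
        t = np.arange(0.0, 10.0, 0.01)
        zero = InputFunction(np.array([0.0, 10.0]), np.array([0.0, 0.0]))
        c_ns, c_s = solve_compartments(control_rc, zero, t)
        assert np.all(c_ns == 0) and np.all(c_s == 0)

    def test_narrow_unit_bolus_approaches_impulse_response(self, control_rc):
        # triangular pulse of unit area with knots on the integration grid
        inp = InputFunction(np.array([0.0, 0.01, 0.02, 90.0]),
                            np.array([0.0, 100.0, 0.0, 0.0]))
        t = np.arange(0.0, 60.0, 0.01)
        c_ns, c_s = solve_compartments(control_rc, inp, t)
        late = t > 1.0
        expect_ns = control_rc.K1 * np.exp(-control_rc.k2 * t[late])
        expect_s = control_rc.K3 * np.exp(-control_rc.k4 * t[late])
        assert np.allclose(c_ns[late], expect_ns, rtol=2e-2)
        assert np.allclose(c_s[late], expect_s, rtol=2e-2)

    def test_matches_stiff_ode_integration(self, input_fn):
        rc = RateConstants(1.4, 0.42, 0.15, 0.009)
        t = np.arange(0.0, 90.0 + 0.005, 0.01)
        c_ns, c_s = solve_compartments(rc, input_fn, t)

        def rhs(ti, y):
            ca = input_fn(ti)
            return [rc.K1 * ca - rc.k2 * y[0], rc.K3 * ca - rc.k4 * y[1]]

        eval_t = t[::500][1:]
        sol = solve_ivp(rhs, (0.0, 90.0), [0.0, 0.0], method="LSODA",
                        t_eval=eval_t, rtol=1e-10, atol=1e-12, max_step=0.01)
        ours = np.vstack([c_ns[::500][1:], c_s[::500][1:]])
        assert np.max(np.abs(ours - sol.y) / np.maximum(np.abs(sol.y), 1e-9)) < 1e-6

    def test_nonuniform_grid_rejected(self, control_rc, input_fn):
        with pytest.raises(ValueError, match="uniform"):
            solve_compartments(control_rc, input_fn, np.array([0.0, 0.1, 0.3, 0.4]))

    def test_component_sum_matches_convolution_oracle(self, control_rc, input_fn):
        t = np.arange(0.0, 90.0 + 0.005, 0.01)
        c_ns, c_s = solve_compartments(control_rc, input_fn, t)
        x = input_fn(t)
        f = impulse_response(control_rc, t)
        idx = np.arange(500, t.size, 1500)
        oracle = np.array([np.trapezoid(x[: n + 1][::-1] * f[: n + 1], dx=0.01) for n in idx])
        ours = (c_ns + c_s)[idx]
        assert np.max(np.abs(ours - oracle) / np.abs(oracle)) < 1e-4


class TestModelTac:
    def test_zero_input_gives_zero_tac(self, control_rc, schedule):
        zero = InputFunction(np.array([0.0, 90.0]), np.array([0.0, 0.0]))
        tac = model_tac(control_rc, zero, 0.15, schedule)
        assert np.all(tac.activity == 0)

    def test_blood_volume_out_of_range_rejected(self, control_rc, input_fn, schedule):
        for bv in (1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                model_tac(control_rc, input_fn, bv, schedule)

    def test_matches_fine_grid_convolution_oracle(self, control_rc, input_fn, schedule):
        bv = 0.15
        tac = model_tac(control_rc, input_fn, bv, schedule)
        mids = schedule.mid_times
        oracle = np.empty_like(mids)
        for i, tm in enumerate(mids):
            tau = np.linspace(0.0, tm, 40001)
            conv = np.trapezoid(input_fn(tm - tau) * impulse_response(control_rc, tau), tau)
            oracle[i] = bv * input_fn(tm) + (1 - bv) * conv
        peak = oracle.max()
        strong = oracle > 0.01 * peak
        assert np.max(np.abs(tac.activity - oracle)[strong] / oracle[strong]) < 1e-4
        assert np.max(np.abs(tac.activity - oracle)) < 1e-4 * peak

    def test_linear_in_input(self, control_rc, schedule):
        grid = np.arange(0.0, 90.0 + 0.005, 0.01)
        a = InputFunction(grid, np.exp(-0.1 * grid) * grid)
        b = InputFunction(grid, 50.0 * np.exp(-0.5 * grid))
        combo = InputFunction(grid, 2.0 * a.activity + 0.5 * b.activity)
        lhs = model_tac(control_rc, combo, 0.15, schedule).activity
        rhs = (2.0 * model_tac(control_rc, a, 0.15, schedule).activity
               + 0.5 * model_tac(control_rc, b, 0.15, schedule).activity)
        assert np.allclose(lhs, rhs, rtol=1e-9, atol=1e-12)

    def test_frame_average_close_to_midpoint_for_slow_frames(self, control_rc, input_fn, schedule):
        mid = model_tac(control_rc, input_fn, 0.15, schedule, sampling="midpoint")
        avg = model_tac(control_rc, input_fn, 0.15, schedule, sampling="average")
        late = schedule.mid_times > 30
        assert np.allclose(mid.activity[late], avg.activity[late], rtol=1e-3)


class TestDistributionVolumes:
    def test_unit_parameters(self):
        b = distribution_volumes(RateConstants(1.0, 1.0, 1.0, 0.5))
        assert b.dv_ns == 1.0 and b.dv_s == 2.0 and b.dv_t == 3.0 and b.dvr == 2.0

    def test_control_mean_values(self, control_rc):
        b = distribution_volumes(control_rc)
        assert b.dv_ns == pytest.approx(4.004, abs=5e-4)
        assert b.dv_s == pytest.approx(16.308, abs=5e-4)
        assert b.dvr == pytest.approx(4.073, abs=5e-4)

    @given(rc=rate_constants, scale=st.floats(0.1, 10.0))
    def test_dvr_invariant_under_uptake_scaling(self, rc, scale):
        b0 = distribution_volumes(rc)
        b1 = distribution_volumes(
            RateConstants(scale * rc.K1, rc.k2, scale * rc.K3, rc.k4))
        assert b1.dvr == pytest.approx(b0.dvr, rel=1e-12)

    @given(rc=rate_constants)
    def test_total_volume_identity_exact(self, rc):
        b = distribution_volumes(rc)
        assert b.dv_t - (b.dv_s + b.dv_ns) == 0.0

    def test_degenerate_equal_washout_rejected(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            distribution_volumes(RateConstants(1.0, 0.1, 1.0, 0.1))


class TestRetention:
    def test_constant_curve_retains_fully(self, schedule):
        tac = TimeActivityCurve(schedule, np.full(len(schedule), 7.0))
        assert retention_from_tac(tac) == 1.0

    def test_maximum_at_retention_time(self, schedule):
        mids = schedule.mid_times
        vals = np.where(mids <= 80.0, mids, 160.0 - mids)
        tac = TimeActivityCurve(schedule, vals)
        assert retention_from_tac(tac, 80.0) == pytest.approx(1.0, rel=1e-6)

    def test_consistent_with_forward_model(self, control_rc, input_fn, schedule, noiseless_tac):
        y = retention_from_tac(noiseless_tac, 80.0)
        mids = schedule.mid_times
        expect = (np.interp(80.0, mids, noiseless_tac.activity)
                  / noiseless_tac.activity.max())
        assert y == pytest.approx(expect, rel=1e-12)
        assert 0.0 < y <= 1.0

    def test_retention_time_beyond_curve_rejected(self, schedule):
        tac = TimeActivityCurve(schedule, np.ones(len(schedule)))
        with pytest.raises(ValueError, match="beyond"):
            retention_from_tac(tac, 89.0)

    @pytest.mark.parametrize(
        "rc,expected",
        [
            ((1.0, 0.3, 1.0, 0.013), (np.exp(-24.0) + np.exp(-1.04)) / 2.0),
            # vanishing specific component: retention is the fast tail alone
            ((1.0, 0.3, 1e-12, 0.013), np.exp(-24.0)),
        ],
    )
    def test_analytic_irf_retention(self, rc, expected):
        f = retention_from_irf(ImpulseResponse(rc=RateConstants(*rc)), 80.0)
        assert f == pytest.approx(expected, rel=1e-6)

    def test_sampled_matches_analytic_on_shared_grid(self, control_rc):
        t = np.arange(0.0, 90.0, 0.05)
        sampled = ImpulseResponse(times=t, values=impulse_response(control_rc, t))
        analytic = ImpulseResponse(rc=control_rc)
        assert retention_from_irf(sampled, 80.0) == pytest.approx(
            retention_from_irf(analytic, 80.0), rel=1e-12)
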