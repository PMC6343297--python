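"""Two-compartment PK solver: micro constants, exactness, linearity."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import solve_ivp

from propofol_pkpd import DoseEvent, PKParameters, micro_constants, solve_pk
from propofol_pkpd.params import InvalidParameterError
from propofol_pkpd.pk import pk_matrix

from conftest import FINAL_PK


class TestMicroConstants:
    def test_reference_values(self):
        mc = micro_constants(FINAL_PK)
        assert mc["k10"] == pytest.approx(0.3806, rel=1e-3)
        assert mc["k12"] == pytest.approx(0.3194, rel=1e-3)
        assert mc["k21"] == pytest.approx(0.01497, rel=1e-3)

    def test_eigenvalue_identities(self):
        mc = micro_constants(FINAL_PK)
        s = mc["k10"] + mc["k12"] + mc["k21"]
        assert mc["lambda1"] + mc["lambda2"] == pytest.approx(s, rel=1e-12)
        assert mc["lambda1"] * mc["lambda2"] == pytest.approx(mc["k10"] * mc["k21"], rel=1e-12)
        assert mc["lambda1"] >= mc["lambda2"] > 0

    def test_decoupling_limit_small_q(self):
        p = PKParameters(CL=1.37, Q=1e-8, V1=3.6, V2=76.8)
        mc = micro_constants(p)
        assert mc["lambda1"] == pytest.approx(mc["k10"], rel=1e-6)
        assert mc["lambda2"] == pytest.approx(mc["k21"], rel=1e-4)

    @given(
        cl=st.floats(0.1, 5.0),
        q=st.floats(0.05, 5.0),
        v1=st.floats(1.0, 20.0),
        v2=st.floats(5.0, 200.0),
    )
    def test_characteristic_polynomial_identity(self, cl, q, v1, v2):
        mc = micro_constants(PKParameters(cl, q, v1, v2))
        assert abs(mc["lambda1"] * mc["lambda2"] - mc["k10"] * mc["k21"]) < 1e-12 * max(
            1.0, mc["k10"] * mc["k21"]
        )

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            PKParameters(CL=-1.0, Q=1.0, V1=3.6, V2=76.8)
        with pytest.raises(InvalidParameterError):
            PKParameters(CL=1.0, Q=0.0, V1=3.6, V2=76.8)


def _ode_oracle(p, events, times):
    """High-accuracy adaptive ODE integration, piecewise between dose breakpoints."""
    A = pk_matrix(p)
    times = np.asarray(times, dtype=float)
    t_end = float(times.max()) if times.size else 0.0
    grid = sorted(
        {0.0, t_end}
        | {ev.start for ev in events}
        | {ev.end for ev in events if ev.duration > 0}
        | set(times.tolist())
    )
    grid = [g for g in grid if g <= t_end + 1e-12]
    x = np.zeros(2)
    out = np.zeros(times.size)

    def record(t_val, state):
        hit = np.isclose(times, t_val, rtol=0, atol=1e-9)
        out[hit] = state[0] / p.V1

    for ev in events:
        if ev.duration == 0 and abs(ev.start - grid[0]) < 1e-12:
            x[0] += ev.amount
    record(grid[0], x)
    for t0, t1 in zip(grid[:-1], grid[1:]):
        rate = sum(
            ev.amount / ev.duration
            for ev in events
            if ev.duration > 0 and ev.start <= t0 + 1e-12 and ev.end >= t1 - 1e-12
        )

        def rhs(t, s):
            ds = A @ s
            ds[0] += rate
            return ds

        sol = solve_ivp(rhs, (t0, t1), x, rtol=1e-11, atol=1e-13, method="DOP853")
        x = sol.y[:, -1]
        for ev in events:
            if ev.duration == 0 and abs(ev.start - t1) < 1e-12:
                x[0] += ev.amount
        record(t1, x)
    return out


class TestSolvePK:
    def test_bolus_concentration_against_ode_oracle(self):
        events = [DoseEvent(start=0.0, amount=204.0, duration=10.0 / 60.0)]
        t = [10.0 / 60.0, 1.0, 5.0, 30.0, 120.0]
        cb = solve_pk(FINAL_PK, events, t).cb
        oracle = _ode_oracle(FINAL_PK, events, t)
        np.testing.assert_allclose(cb, oracle, rtol=1e-8)
        # just after a 10-s 204 mg bolus: a bit below amount/V1 = 56.7 mg/L
        assert 0.85 * 204 / 3.6 < cb[0] < 204 / 3.6

    def test_steady_state_equals_rate_over_clearance(self):
        rate = 5.1  # mg/min
        horizon = 50000.0
        prof = solve_pk(FINAL_PK, [DoseEvent(0.0, rate * horizon, horizon)], [horizon - 1.0])
        assert prof.cb[0] == pytest.approx(rate / FINAL_PK.CL, rel=1e-6)

    def test_no_events_zero_everywhere(self):
        prof = solve_pk(FINAL_PK, [], [0.0, 10.0, 100.0])
        assert np.all(prof.cb == 0.0) and np.all(prof.peripheral == 0.0)

    def test_zero_before_first_dose(self):
        prof = solve_pk(FINAL_PK, [DoseEvent(60.0, 100.0, 1.0)], [0.0, 30.0, 59.9, 61.0])
        assert np.all(prof.cb[:3] == 0.0)
        assert prof.cb[3] > 0.0

    def test_oracle_equivalence_randomized_schedules(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            p = PKParameters(
                CL=rng.uniform(0.3, 3.0), Q=rng.uniform(0.2, 3.0),
                V1=rng.uniform(2.0, 10.0), V2=rng.uniform(10.0, 150.0),
            )
            events = []
            t0 = 0.0
            for _k in range(rng.integers(1, 5)):
                start = t0 + rng.uniform(0.0, 60.0)
                dur = rng.uniform(0.2, 120.0)
                events.append(DoseEvent(start, rng.uniform(20.0, 400.0), dur))
                t0 = start
            times = np.sort(rng.uniform(0.0, t0 + 240.0, size=12))
            cb = solve_pk(p, events, times).cb
            oracle = _ode_oracle(p, events, times)
            np.testing.assert_allclose(cb, oracle, rtol=1e-7, atol=1e-10)

    def test_superposition_and_linearity(self):
        a = [DoseEvent(0.0, 200.0, 0.2), DoseEvent(30.0, 300.0, 60.0)]
        b = [DoseEvent(10.0, 150.0, 5.0)]
        t = np.linspace(0.0, 300.0, 61)
        cb_a = solve_pk(FINAL_PK, a, t).cb
        cb_b = solve_pk(FINAL_PK, b, t).cb
        cb_ab = solve_pk(FINAL_PK, a + b, t).cb
        np.testing.assert_allclose(cb_ab, cb_a + cb_b, rtol=1e-10, atol=1e-12)
        doubled = [DoseEvent(ev.start, 2 * ev.amount, ev.duration) for ev in a]
        np.testing.assert_allclose(solve_pk(FINAL_PK, doubled, t).cb, 2 * cb_a, rtol=1e-10)

    @given(
        cl=st.floats(0.2, 4.0),
        amount=st.floats(10.0, 500.0),
        dur=st.floats(0.1, 200.0),
    )
    def test_nonnegative_states(self, cl, amount, dur):
        p = PKParameters(CL=cl, Q=1.15, V1=3.6, V2=76.8)
        t = np.linspace(0.0, 2 * dur + 300.0, 50)
        prof = solve_pk(p, [DoseEvent(0.0, amount, dur)], t)
        assert np.all(prof.cb >= 0.0)
        assert np.all(prof.peripheral >= 0.0)

    def test_monotone_decay_after_dosing_stops(self):
        events = [DoseEvent(0.0, 200.0, 0.2), DoseEvent(0.2, 2000.0, 400.0)]
        t = np.arange(500.0, 2000.0, 5.0)  # well past the distribution phase
        cb = solve_pk(FINAL_PK, events, t).cb
        assert np.all(np.diff(cb) < 0.0)

    def test_instantaneous_bolus_option(self):
        prof = solve_pk(FINAL_PK, [DoseEvent(0.0, 204.0, 0.0)], [0.0, 1.0])
        assert prof.cb[0] == pytest.approx(204.0 / 3.6, rel=1e-12)

    def test_unsorted_times_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            solve_pk(FINAL_PK, [DoseEvent(0.0, 100.0, 1.0)], [10.0, 5.0])

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            DoseEvent(start=0.0, amount=-5.0, duration=1.0)
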