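"""RCR splitting, simulation against closed forms, limit cycle, tuning."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aneushear import (
    MMHG_TO_BARYE,
    InvalidParameterError,
    OutletSet,
    PressureTrace,
    RCRSet,
    TuningError,
    Waveform,
    build_rcr,
    limit_cycle_converged,
    make_waveform,
    simulate_rcr,
    simulate_to_limit_cycle,
    split_resistances,
    tune_rcr,
)


class TestSplit:
    def test_single_outlet_takes_all(self):
        r = split_resistances(OutletSet(np.array([0.7])), 1234.0)
        assert r == pytest.approx([1234.0])

    def test_two_outlet_example(self):
        r = split_resistances(OutletSet(np.array([1.0, 3.0])), 1000.0)
        assert r == pytest.approx([4000.0, 4000.0 / 3.0])
        assert 1.0 / np.sum(1.0 / r) == pytest.approx(1000.0, rel=1e-12)

    def test_equal_outlets_symmetry(self):
        r = split_resistances(OutletSet(np.full(5, 0.2)), 800.0)
        assert r == pytest.approx(np.full(5, 5 * 800.0))

    @pytest.mark.parametrize("seed", range(20))
    def test_parallel_combination_conserved(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 8)
        areas = rng.uniform(0.01, 2.0, n)
        r_total = rng.uniform(10.0, 1e5)
        r = split_resistances(OutletSet(areas), r_total)
        assert 1.0 / np.sum(1.0 / r) == pytest.approx(r_total, rel=1e-12)

    def test_nonpositive_area_rejected(self):
        with pytest.raises(InvalidParameterError):
            OutletSet(np.array([1.0, -0.1]))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        areas=st.lists(st.floats(1e-3, 5.0), min_size=1, max_size=10),
        r_total=st.floats(1e-2, 1e7),
    )
    def test_parallel_identity_any_configuration(self, areas, r_total):
        r = split_resistances(OutletSet(np.array(areas)), r_total)
        assert np.all(r >= r_total)  # each branch carries at least the total
        assert 1.0 / np.sum(1.0 / r) == pytest.approx(r_total, rel=1e-12)


def rk4_oracle(waveform, rcr, n_cycles, steps_per_cycle=4000):
    """Fixed-step classical RK4 on the same ODE (fine-step reference)."""
    eq = rcr.parallel_equivalent() if rcr.n_outlets > 1 else rcr
    rp, c, rd, p_ref = eq.r_proximal[0], eq.capacitance[0], eq.r_distal[0], eq.p_ref
    h = waveform.period / steps_per_cycle
    n = n_cycles * steps_per_cycle
    t = 0.0
    y = waveform.mean_flow * rd + p_ref
    ts = np.empty(n + 1)
    ys = np.empty(n + 1)
    ts[0], ys[0] = t, y

    def f(t, y):
        return (waveform(t) - (y - p_ref) / rd) / c

    for i in range(n):
        k1 = f(t, y)
        k2 = f(t + h / 2, y + h / 2 * k1)
        k3 = f(t + h / 2, y + h / 2 * k2)
        k4 = f(t + h, y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += h
        ts[i + 1], ys[i + 1] = t, y
    p = ys + rp * np.asarray(waveform(ts))
    return PressureTrace(time=ts, pressure=p, period=waveform.period)


class TestSimulate:
    def test_constant_inflow_steady_state(self):
        w = make_waveform(3.0, 0.0)
        rcr = RCRSet(np.array([100.0]), np.array([1e-4]), np.array([900.0]), p_ref=500.0)
        n = int(np.ceil(10 * 900.0 * 1e-4 / w.period)) + 2
        tr = simulate_rcr(w, rcr, n_cycles=n)
        expect = 3.0 * 1000.0 + 500.0
        assert tr.pressure[-1] == pytest.approx(expect, rel=1e-3)

    def test_sinusoid_amplitude_matches_impedance(self):
        t = np.linspace(0.0, 1.0, 301)
        q0, q1 = 4.0, 1.5
        w = Waveform(time=t, flow=q0 + q1 * np.sin(2 * np.pi * t), period=1.0)
        rp, c, rd = 150.0, 8e-4, 1350.0
        rcr = RCRSet(np.array([rp]), np.array([c]), np.array([rd]))
        tr, ok = simulate_to_limit_cycle(w, rcr, tol=0.001)
        table = tr.per_cycle_extrema()
        amp = (table[-1, 0] - table[-1, 1]) / 2.0
        omega = 2 * np.pi
        z = rp + rd / (1 + 1j * omega * rd * c)
        assert amp == pytest.approx(q1 * abs(z), rel=0.005)

    def test_large_compliance_limit_pulse_is_proximal(self):
        t = np.linspace(0.0, 1.0, 301)
        q1 = 2.0
        w = Waveform(time=t, flow=5.0 + q1 * np.sin(2 * np.pi * t), period=1.0)
        rp, rd = 200.0, 1800.0
        rcr = RCRSet(np.array([rp]), np.array([0.5]), np.array([rd]))
        tr, _ = simulate_to_limit_cycle(w, rcr, tol=0.001, max_cycles=40)
        table = tr.per_cycle_extrema()
        pulse = table[-1, 0] - table[-1, 1]
        assert pulse == pytest.approx(2 * q1 * rp, rel=0.02)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_fine_step_rk4(self, seed, ica_waveform):
        rng = np.random.default_rng(seed)
        rp = rng.uniform(50.0, 500.0)
        rd = 9.0 * rp
        c = rng.uniform(1e-5, 5e-3)
        rcr = RCRSet(np.array([rp]), np.array([c]), np.array([rd]))
        n = 6
        tr = simulate_rcr(ica_waveform, rcr, n_cycles=n)
        oracle = rk4_oracle(ica_waveform, rcr, n)
        sys_a, dia_a = tr.per_cycle_extrema()[-1]
        sys_b, dia_b = oracle.per_cycle_extrema()[-1]
        assert sys_a == pytest.approx(sys_b, rel=1e-3)
        assert dia_a == pytest.approx(dia_b, rel=1e-3)

    def test_dt_above_cap_rejected(self, ica_waveform):
        rcr = RCRSet(np.array([100.0]), np.array([1e-4]), np.array([900.0]))
        with pytest.raises(InvalidParameterError):
            simulate_rcr(ica_waveform, rcr, dt=ica_waveform.period / 100)

    def test_multi_outlet_equivalent_matches_single(self, ica_waveform):
        outlets = OutletSet(np.array([0.05, 0.03, 0.08]))
        multi = build_rcr(outlets, 1500.0, 1e-3)
        single = RCRSet(np.array([150.0]), np.array([1e-3]), np.array([1350.0]))
        tr_m = simulate_rcr(ica_waveform, multi, n_cycles=4)
        tr_s = simulate_rcr(ica_waveform, single, n_cycles=4)
        np.testing.assert_allclose(tr_m.pressure, tr_s.pressure, rtol=1e-5)


class TestLimitCycle:
    def _trace_from_cycles(self, sys_values):
        # synthetic trace: each cycle a sine with given systolic peak, dia = peak/2
        period = 1.0
        t_all, p_all = [], []
        for c, s in enumerate(sys_values):
            t = np.linspace(0, period, 100, endpoint=False) + c * period
            p = (s * 0.75) + (s * 0.25) * np.sin(2 * np.pi * t)
            t_all.append(t)
            p_all.append(p)
        return PressureTrace(np.concatenate(t_all), np.concatenate(p_all), period)

    def test_identical_cycles_converged_at_zero_tol(self):
        tr = self._trace_from_cycles([120.0, 120.0, 120.0])
        ok, table = limit_cycle_converged(tr, tol=0.0)
        assert ok and table.shape[0] == 3

    def test_paper_style_sequence(self):
        tr = self._trace_from_cycles([150.0, 130.0, 124.0, 121.0])
        ok, _ = limit_cycle_converged(tr, tol=0.05)
        assert ok  # |121-124|/124 = 2.4% <= 5%

    def test_monotone_drift_not_converged(self):
        tr = self._trace_from_cycles([100.0, 110.0, 121.0])
        ok, _ = limit_cycle_converged(tr, tol=0.05)
        assert not ok

    def test_single_cycle_errors(self):
        tr = self._trace_from_cycles([120.0])
        with pytest.raises(InvalidParameterError):
            limit_cycle_converged(tr)


class TestTuning:
    def test_hits_targets_within_tolerance(self, ica_waveform):
        res = tune_rcr(ica_waveform, OutletSet(np.array([0.05, 0.03])))
        assert res.converged
        assert abs(res.systolic_mmhg - 120.0) / 120.0 <= 0.05
        assert abs(res.diastolic_mmhg - 80.0) / 80.0 <= 0.05
        assert len(res.audit_log) == res.iterations
        # proximal fraction preserved per outlet
        np.testing.assert_allclose(res.rcr.proximal_fraction, 0.1, rtol=1e-12)

    def test_mean_pressure_identity(self, ica_waveform):
        res = tune_rcr(ica_waveform, OutletSet(np.array([0.04])))
        eq = res.rcr.parallel_equivalent()
        r_total = float(eq.r_proximal[0] + eq.r_distal[0])
        mean_p = res.trace.last_cycle_mean()
        expect = ica_waveform.mean_flow * r_total + res.rcr.p_ref
        assert mean_p == pytest.approx(expect, rel=0.02)

    def test_deterministic(self, ica_waveform):
        r1 = tune_rcr(ica_waveform, OutletSet(np.array([0.05])))
        r2 = tune_rcr(ica_waveform, OutletSet(np.array([0.05])))
        assert r1.systolic_mmhg == r2.systolic_mmhg
        np.testing.assert_array_equal(r1.rcr.capacitance, r2.rcr.capacitance)

    def test_constant_inflow_infeasible(self):
        w = make_waveform(4.0, pulsatility_index=0.0)
        with pytest.raises(TuningError, match="pulsatility"):
            tune_rcr(w, OutletSet(np.array([0.05])))

    def test_limit_cycle_mean_pressure_vs_targets(self, ica_waveform):
        # cycle-mean pressure approximately the (s + 2d)/3 proxy in mmHg
        res = tune_rcr(ica_waveform, OutletSet(np.array([0.05, 0.03])))
        mean_mmhg = res.trace.last_cycle_mean() / MMHG_TO_BARYE
        assert 80.0 < mean_mmhg < 120.0
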