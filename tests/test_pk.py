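"""ODE solvers (adaptive reference and vectorized batch) and the
concentration-effect mapping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from ecusim.parameters import IndividualParameters
from ecusim.pk import (ConcentrationProfile, DoseEvent,
                       cp_threshold_concentration, predict_cp_activity,
                       simulate_batch, solve_concentration_profile,
                       trough_before)

K_LIN = 0.163 / 6.42  # typical linear elimination rate constant, 1/day


def linear_superposition(doses, v, k, times):
    """Closed-form bolus superposition for purely linear elimination."""
    conc = np.zeros_like(times, dtype=float)
    for d in doses:
        mask = times > d.time
        conc[mask] += (d.amount / v) * np.exp(-k * (times[mask] - d.time))
    return conc


class TestAdaptiveSolver:
    def test_no_doses_gives_zero(self, typical_ind):
        times = np.arange(0.0, 10.0, 0.5)
        prof = solve_concentration_profile(typical_ind, [], times)
        assert np.all(prof.conc == 0.0)

    def test_linear_single_bolus_closed_form(self, linear_ind):
        """With Vmax=0 a 1200-mg bolus decays as 186.92*exp(-0.02539 t)."""
        times = np.arange(0.0, 28.1, 0.1)
        prof = solve_concentration_profile(
            linear_ind, [DoseEvent(0.0, 1200.0)], times)
        expected = linear_superposition([DoseEvent(0.0, 1200.0)], 6.42,
                                        K_LIN, times)
        mask = times > 0
        rel = np.abs(prof.conc[mask] - expected[mask]) / expected[mask]
        assert rel.max() < 1e-6
        c14 = prof.conc[np.searchsorted(times, 14.0)]
        assert c14 == pytest.approx(1200 / 6.42 * math.exp(-K_LIN * 14),
                                    rel=1e-8)
        assert c14 == pytest.approx(130.96, abs=0.05)

    def test_linear_multi_bolus_superposition(self, linear_ind):
        doses = [DoseEvent(0.0, 900.0), DoseEvent(7.0, 900.0),
                 DoseEvent(21.0, 1200.0)]
        times = np.arange(0.0, 42.1, 0.1)
        prof = solve_concentration_profile(linear_ind, doses, times)
        expected = linear_superposition(doses, 6.42, K_LIN, times)
        mask = expected > 0
        rel = np.abs(prof.conc[mask] - expected[mask]) / expected[mask]
        assert rel.max() < 1e-6

    def test_mass_balance_linear(self, linear_ind):
        """Amount eliminated over [0, inf) equals the administered dose."""
        times = np.arange(0.0, 1500.0, 0.1)
        prof = solve_concentration_profile(
            linear_ind, [DoseEvent(0.0, 1200.0)], times)
        conc = prof.conc.copy()
        conc[0] = 1200.0 / linear_ind.v_i  # post-dose value (grid stores the
        # pre-dose left limit at dose instants)
        eliminated = linear_ind.cl_i * np.trapezoid(conc, times)
        assert eliminated == pytest.approx(1200.0, rel=1e-4)

    def test_saturable_pathway_lowers_profile(self, typical_ind, linear_ind):
        doses = [DoseEvent(0.0, 900.0), DoseEvent(14.0, 1200.0)]
        times = np.arange(0.0, 28.1, 0.1)
        with_mm = solve_concentration_profile(typical_ind, doses, times)
        without = solve_concentration_profile(linear_ind, doses, times)
        assert np.all(with_mm.conc <= without.conc + 1e-12)

    def test_explicit_euler_oracle(self, typical_ind):
        """Adaptive solver matches explicit Euler (dt=1e-4 d) to <0.1%."""
        doses = [DoseEvent(0.0, 900.0), DoseEvent(14.0, 1200.0)]
        t_grid = np.arange(0.0, 28.1, 0.5)
        prof = solve_concentration_profile(typical_ind, doses, t_grid)
        dt = 1e-4
        n = int(round(28.0 / dt))
        a = 0.0
        cl, v = typical_ind.cl_i, typical_ind.v_i
        vmax, kmv = typical_ind.vmax_i, typical_ind.km_i * v
        euler = {}
        dose_steps = {int(round(d.time / dt)): d.amount for d in doses}
        record_steps = {int(round(t / dt)): t for t in t_grid}
        for step in range(n + 1):
            if step in record_steps:
                euler[record_steps[step]] = a / v
            if step in dose_steps:
                a += dose_steps[step]
            a -= dt * ((cl / v) * a + vmax * a / (kmv + a))
        for i, t in enumerate(t_grid):
            if euler[t] > 1.0:
                assert prof.conc[i] == pytest.approx(euler[t], rel=1e-3)

    def test_occasion_multiplier_switches_clearance(self, linear_ind):
        linear_ind.occasion_cl_multipliers = np.array([1.0, 2.0])
        doses = [DoseEvent(0.0, 1200.0), DoseEvent(14.0, 1200.0)]
        times = np.arange(0.0, 28.1, 0.1)
        prof = solve_concentration_profile(linear_ind, doses, times)
        # second interval decays at twice the rate
        c14 = trough_before(prof, 14.0)
        c28 = prof.conc[-1]
        expected = (c14 + 1200 / 6.42) * math.exp(-2 * K_LIN * 14)
        assert c28 == pytest.approx(expected, rel=1e-6)

    def test_infusion_reduces_peak(self, linear_ind):
        times = np.arange(0.0, 7.05, 0.05)
        bolus = solve_concentration_profile(
            linear_ind, [DoseEvent(0.0, 1200.0)], times)
        infusion = solve_concentration_profile(
            linear_ind, [DoseEvent(0.0, 1200.0, infusion_duration=1.0)], times)
        assert infusion.conc.max() < bolus.conc.max()
        # same dose, nearly equal tail once infusion is complete
        assert infusion.conc[-1] == pytest.approx(
            bolus.conc[-1], rel=0.05)

    def test_unsorted_times_rejected(self, typical_ind):
        with pytest.raises(ValueError):
            solve_concentration_profile(typical_ind, [],
                                        np.array([0.0, 2.0, 1.0]))


class TestBatchSolver:
    def test_matches_adaptive_solver(self, pop):
        rng = np.random.default_rng(5)
        n = 8
        cl = 0.163 * np.exp(0.4 * rng.standard_normal(n))
        v = 6.42 * np.exp(0.35 * rng.standard_normal(n))
        occ = np.exp(0.3 * rng.standard_normal((n, 6)))
        schedules = []
        for i in range(n):
            t_doses = np.sort(rng.choice(np.arange(0, 50), size=4,
                                         replace=False)).astype(float)
            amts = rng.choice([300.0, 600.0, 900.0, 1200.0], size=4)
            schedules.append(np.column_stack([t_doses, amts]))
        times, conc = simulate_batch(cl, v, np.full(n, 29.6),
                                     np.full(n, 37.9), occ, schedules,
                                     t_end=60.0, dt=0.1)
        for i in range(n):
            ind = IndividualParameters(
                subject_id=i, cl_i=cl[i], v_i=v[i], vmax_i=29.6, km_i=37.9,
                base_i=100.7, ic50_i=22.0, gamma_i=5.42, imax_i=0.96,
                occasion_cl_multipliers=occ[i])
            doses = [DoseEvent(t, a) for t, a in schedules[i]]
            ref = solve_concentration_profile(ind, doses, times)
            mask = ref.conc > 0.5
            rel = np.abs(conc[i, mask] - ref.conc[mask]) / ref.conc[mask]
            assert rel.max() < 1e-3

    def test_nonnegative_concentrations(self):
        rng = np.random.default_rng(99)
        n = 20
        cl = 0.163 * np.exp(rng.standard_normal(n))
        v = 6.42 * np.exp(0.4 * rng.standard_normal(n))
        schedules = [np.array([[0.0, 300.0]])] * n
        _, conc = simulate_batch(cl, v, np.full(n, 29.6), np.full(n, 37.9),
                                 np.ones((n, 1)), schedules, 400.0, 0.1)
        assert np.all(conc >= 0.0)

    def test_off_grid_dose_time_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            simulate_batch(np.array([0.163]), np.array([6.42]),
                           np.array([29.6]), np.array([37.9]),
                           np.ones((1, 1)), [np.array([[0.05, 300.0]])],
                           t_end=10.0, dt=0.1)

    def test_grid_values_are_predose_left_limits(self):
        times, conc = simulate_batch(
            np.array([0.163]), np.array([6.42]), np.array([0.0]),
            np.array([37.9]), np.ones((1, 1)),
            [np.array([[0.0, 1200.0], [14.0, 1200.0]])], 14.0, 0.1)
        # at t=14 the stored value excludes the dose given at t=14
        expected = 1200 / 6.42 * math.exp(-K_LIN * 14)
        assert conc[0, -1] == pytest.approx(expected, rel=1e-6)
        assert conc[0, 0] == 0.0  # pre-dose at t=0


class TestEmaxModel:
    def test_baseline_at_zero_concentration(self, typical_ind):
        assert predict_cp_activity(typical_ind, 0.0) \
            == pytest.approx(100.7)

    def test_half_maximal_inhibition_at_ic50(self, typical_ind):
        # E = Base*(1 - Imax/2) at C = IC50
        assert predict_cp_activity(typical_ind, 22.0) \
            == pytest.approx(100.7 * (1 - 0.96 / 2), rel=1e-12)

    def test_asymptote(self, typical_ind):
        assert predict_cp_activity(typical_ind, 1e9) \
            == pytest.approx(100.7 * (1 - 0.96), rel=1e-6)

    def test_negative_concentration_rejected(self, typical_ind):
        with pytest.raises(ValueError):
            predict_cp_activity(typical_ind, -1.0)

    @settings(deadline=None, max_examples=50)
    @given(st.floats(min_value=1.0, max_value=500.0),
           st.floats(min_value=0.01, max_value=100.0))
    def test_strictly_decreasing_and_bounded(self, c1, delta):
        # range where the strict decrease is representable in floats
        # (beyond ~500 mg/L the curve sits at its asymptote to within eps)
        ind = IndividualParameters(
            subject_id=0, cl_i=0.163, v_i=6.42, vmax_i=29.6, km_i=37.9,
            base_i=100.7, ic50_i=22.0, gamma_i=5.42, imax_i=0.96)
        e1 = predict_cp_activity(ind, c1)
        e2 = predict_cp_activity(ind, c1 + delta)
        assert e2 < e1
        assert 100.7 * (1 - 0.96) < e1 <= 100.7

    def test_threshold_crossing_against_root_solve(self, typical_ind):
        """Analytic inversion agrees with brentq on the Emax equation."""
        thr = cp_threshold_concentration(typical_ind, 10.0)
        root = brentq(lambda c: predict_cp_activity(typical_ind, c) - 10.0,
                      1e-6, 1e4, xtol=1e-12)
        assert thr == pytest.approx(root, rel=1e-9)
        assert thr == pytest.approx(36.3, abs=0.1)

    def test_threshold_degenerate_cases(self, typical_ind):
        # asymptote above threshold: unreachable
        assert cp_threshold_concentration(typical_ind, 3.0) == math.inf
        # baseline below threshold: reached already at C = 0
        typical_ind.base_i = 8.0
        assert cp_threshold_concentration(typical_ind, 10.0) == 0.0


class TestTroughBefore:
    def test_constant_profile(self):
        prof = ConcentrationProfile(times=np.arange(0.0, 10.0, 1.0),
                                    conc=np.full(10, 120.0))
        assert trough_before(prof, 5.0) == 120.0

    def test_left_limit_of_decaying_bolus(self, linear_ind):
        times = np.arange(0.0, 28.1, 0.1)
        prof = solve_concentration_profile(
            linear_ind, [DoseEvent(0.0, 1200.0)], times)
        assert trough_before(prof, 14.0) == pytest.approx(130.96, abs=0.05)

    def test_no_predose_point_is_an_error(self):
        prof = ConcentrationProfile(times=np.arange(0.0, 5.0, 1.0),
                                    conc=np.zeros(5))
        with pytest.raises(ValueError):
            trough_before(prof, 0.0)

    def test_out_of_range_rejected(self):
        prof = ConcentrationProfile(times=np.arange(0.0, 5.0, 1.0),
                                    conc=np.zeros(5))
        with pytest.raises(ValueError):
            trough_before(prof, 99.0)
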