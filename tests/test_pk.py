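"""Uptake-model simulation: exactness, conservation laws, equivalent dose."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

from eqdose.pk import PKParams, TreatmentCourse, equivalent_dose, simulate_pk

from conftest import random_pk_params


def _oracle_piecewise_expm(params, course, times):
    """Independent closed-form reference: per-segment matrix exponential."""
    A = params.system_matrix()
    boundaries = [t for t, _ in course.events]
    concs = dict(course.events)
    out = []
    for t in times:
        x = np.zeros(3)
        prev = 0.0
        for tb in boundaries:
            if tb > t:
                break
            x = expm(A * (tb - prev)) @ x
            x[0] = concs[tb]
            prev = tb
        out.append(expm(A * (t - prev)) @ x)
    return np.array(out)


class TestSimulate:
    def test_no_influx_leaves_cell_empty(self, uptake_course):
        p = PKParams(k_EF=0.0, k_FE=0.1, k_FB=0.05)
        traj = simulate_pk(p, uptake_course, np.linspace(0, 7.9, 30))
        assert np.all(traj.C_F == 0) and np.all(traj.C_B == 0)
        np.testing.assert_allclose(traj.C_E, 1000.0)

    def test_no_binding_equilibrates_free_pool(self):
        p = PKParams(k_EF=1e-3, k_FE=0.2, k_FB=0.0, v_ratio=100.0)
        course = TreatmentCourse(events=((0.0, 1000.0),), horizon=5000.0)
        traj = simulate_pk(p, course, np.array([0.0, 4999.0, 5000.0]))
        assert np.all(traj.C_B == 0)
        ratio = traj.C_F[-1] / traj.C_E[-1]
        np.testing.assert_allclose(ratio, p.k_EF * p.v_ratio / p.k_FE, rtol=1e-6)

    def test_matches_piecewise_expm_oracle(self, base_params, uptake_course):
        times = np.arange(0.0, 24.001, 25 / 60)
        traj = simulate_pk(base_params, uptake_course, times)
        oracle = _oracle_piecewise_expm(base_params, uptake_course, times)
        mine = np.column_stack([traj.C_E, traj.C_F, traj.C_B])
        scale = np.abs(oracle).max(axis=0)
        assert np.max(np.abs(mine - oracle) / scale) <= 1e-6

    def test_event_resets_extracellular_only(self, base_params):
        course = TreatmentCourse.pulse(1000.0, 8.0, 24.0)
        eps = 1e-7
        t = simulate_pk(base_params, course, np.array([8.0 - eps, 8.0]))
        assert t.C_E[1] <= 1e-12 and t.C_E[0] > 990.0
        np.testing.assert_allclose(t.C_F[0], t.C_F[1], rtol=1e-5)
        np.testing.assert_allclose(t.C_B[0], t.C_B[1], rtol=1e-5)

    def test_bound_pool_never_decreases(self, base_params, uptake_course):
        traj = simulate_pk(base_params, uptake_course, np.linspace(0, 24, 400))
        assert np.all(np.diff(traj.C_B) >= -1e-12)

    @pytest.mark.parametrize(
        "bad",
        [
            {"times": []},
            {"times": [2.0, 1.0]},
            {"times": [-1.0, 3.0]},
            {"times": [1.0, 30.0]},
        ],
    )
    def test_invalid_sample_grids_rejected(self, base_params, uptake_course, bad):
        with pytest.raises(ValueError):
            simulate_pk(base_params, uptake_course, np.asarray(bad["times"], dtype=float))

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            PKParams(k_EF=-1e-6, k_FE=0.1, k_FB=0.1)
        with pytest.raises(ValueError):
            PKParams(k_EF=1e-6, k_FE=0.1, k_FB=0.1, v_ratio=0.0)

    def test_course_validation(self):
        with pytest.raises(ValueError):
            TreatmentCourse(events=((1.0, 10.0), (1.0, 0.0)), horizon=5.0)
        with pytest.raises(ValueError):
            TreatmentCourse(events=((0.0, -5.0),), horizon=5.0)
        with pytest.raises(ValueError):
            TreatmentCourse(events=((0.0, 5.0), (8.0, 0.0)), horizon=6.0)


class TestConservationAndOracles:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_mass_conserved_and_states_nonnegative(self, seed):
        """v*C_E + C_F + C_B is constant within segments; states stay >= 0."""
        rng = np.random.default_rng(seed)
        p = random_pk_params(rng)
        course = TreatmentCourse.pulse(1000.0, 8.0, 24.0)
        times = np.linspace(0, 24, 200)
        traj = simulate_pk(p, course, times)
        for arr in (traj.C_E, traj.C_F, traj.C_B):
            assert np.all(arr >= 0)
        mass = traj.total_mass(p.v_ratio)
        for mask in ((times >= 0) & (times < 8), times > 8):
            seg = mass[mask]
            if seg.size and seg[0] > 0:
                assert np.max(np.abs(seg - seg[0])) / seg[0] <= 1e-9

    def test_adaptive_agrees_with_exact(self):
        """Stiff-capable integration vs the analytic path on random rates."""
        course = TreatmentCourse.pulse(1000.0, 8.0, 24.0)
        times = np.linspace(0, 24, 50)
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = random_pk_params(rng)
            a = simulate_pk(p, course, times)
            b = simulate_pk(p, course, times, method="adaptive")
            for x, y in ((a.C_E, b.C_E), (a.C_F, b.C_F), (a.C_B, b.C_B)):
                scale = max(np.abs(x).max(), 1e-12)
                assert np.max(np.abs(x - y)) / scale <= 1e-6


class TestEquivalentDose:
    def test_zero_schedule_gives_zero(self, base_params):
        course = TreatmentCourse(events=((0.0, 0.0), (8.0, 0.0)), horizon=24.0)
        assert equivalent_dose(base_params, course) == 0.0

    def test_no_binding_gives_zero(self, uptake_course):
        p = PKParams(k_EF=1e-3, k_FE=0.2, k_FB=0.0)
        assert equivalent_dose(p, uptake_course) == 0.0

    def test_equals_final_bound_concentration(self, base_params, uptake_course):
        """C_B is non-decreasing, so D_eq is C_B at the end of evaluation."""
        d = equivalent_dose(base_params, uptake_course, washout_tail=False)
        traj = simulate_pk(base_params, uptake_course, np.linspace(0, 24, 2000))
        assert d >= traj.C_B.max() * (1 - 1e-9)
        np.testing.assert_allclose(d, traj.C_B[-1], rtol=1e-6)

    def test_monotone_in_concentration_and_duration(self, base_params):
        """Brute-force grid: higher or longer exposure never lowers D_eq."""
        concs = np.linspace(100.0, 2000.0, 10)
        durs = np.linspace(2.0, 24.0, 10)
        grid = np.array(
            [
                [
                    equivalent_dose(
                        base_params,
                        TreatmentCourse(events=((0.0, c), (t, 0.0)), horizon=max(t, 24.0)),
                    )
                    for t in durs
                ]
                for c in concs
            ]
        )
        assert np.all(np.diff(grid, axis=0) >= -1e-9 * grid[:-1, :])
        assert np.all(np.diff(grid, axis=1) >= -1e-9 * grid[:, :-1])

    @pytest.mark.parametrize("rate,sign", [("k_EF", 1), ("k_FB", 1), ("k_FE", -1)])
    def test_monotone_in_rates(self, base_params, sign, rate):
        course = TreatmentCourse.pulse(1000.0, 24.0, 24.0)
        values = np.logspace(-4, 0.5, 25) if rate != "k_EF" else np.logspace(-7, -4, 25)
        d = np.array(
            [equivalent_dose(base_params.replace(**{rate: v}), course) for v in values]
        )
        assert np.all(sign * np.diff(d) >= -1e-9 * np.abs(d[:-1]))

    def test_params_roundtrip_serialization(self, base_params, uptake_course):
        assert PKParams.from_dict(base_params.to_dict()) == base_params
        assert TreatmentCourse.from_dict(uptake_course.to_dict()) == uptake_course
        with pytest.raises(ValueError):
            PKParams.from_dict({"k_EF": 1e-6, "k_FE": 0.1, "k_FB": 0.1, "bogus": 1})
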