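"""Parameter estimation: round-trip exactness, degeneracy flags, CIs."""

import numpy as np
import pytest

from eqdose.fitting import HillModel, ResponseModel, UptakeModel
from eqdose.pd import PDParams, simulate_counts
from eqdose.pk import TreatmentCourse, simulate_pk
from eqdose.synthetic import UPTAKE_PK, StudyDesign, gen_pk_dataset


@pytest.fixture(scope="module")
def uptake_noiseless(design=StudyDesign()):
    course = design.uptake_course()
    times = design.uptake_times
    means = simulate_pk(UPTAKE_PK, course, times).intracellular
    return times, means, course


class TestUptakeModel:
    def test_noiseless_roundtrip_recovers_rates(self, uptake_noiseless):
        times, means, course = uptake_noiseless
        res = UptakeModel(times, means, course).fit(n_starts=8, seed=0)
        for name in ("k_EF", "k_FE", "k_FB"):
            true = getattr(UPTAKE_PK, name)
            assert abs(res.estimates[name] - true) / true <= 1e-3
        assert res.converged and res.mae <= 1e-6 * means.max()

    def test_zero_observations_pin_influx_at_lower_bound(self, uptake_noiseless):
        times, _, course = uptake_noiseless
        res = UptakeModel(times, np.zeros_like(times), course).fit(n_starts=4, seed=0)
        assert res.estimates["k_EF"] <= 1e-8 * 1.01
        assert "k_EF" in res.at_bound and res.degenerate

    def test_zero_drug_schedule_with_signal_warns(self):
        course = TreatmentCourse(events=((0.0, 0.0),), horizon=10.0)
        times = np.linspace(0, 10, 20)
        with pytest.warns(UserWarning, match="all-zero drug schedule"):
            UptakeModel(times, np.full_like(times, 50.0), course)

    def test_nonfinite_observations_rejected(self, uptake_noiseless):
        times, means, course = uptake_noiseless
        bad = means.copy()
        bad[3] = np.nan
        with pytest.raises(ValueError):
            UptakeModel(times, bad, course)

    def test_multistart_consistency(self, uptake_noiseless):
        """Best objective agrees across independent restarts on clean data."""
        times, means, course = uptake_noiseless
        costs = [
            UptakeModel(times, means, course).fit(n_starts=3, seed=seed).cost
            for seed in range(5)
        ]
        # on noiseless data the optimum cost is ~0; compare on the scale of
        # the data's total sum of squares
        floor = 1e-12 * float(np.sum(means**2))
        assert (max(costs) - min(costs)) <= 1e-6 * max(min(costs), floor)


class TestResponseModel:
    def test_noiseless_roundtrip(self):
        p = PDParams(k_p=0.0212, theta=18000.0, k_d_a=0.02, k_d_b=0.04, r=0.12, lam=0.5)
        times = np.arange(-72.0, 361.0, 24.0)
        counts = simulate_counts(p, 1500.0, times)
        res = ResponseModel(times, counts, lam=0.5).fit(n_starts=8, seed=0)
        for name in ("k_p", "theta", "k_d_a", "k_d_b", "r"):
            true = getattr(p, name)
            assert abs(res.estimates[name] - true) / true <= 1e-3, name
        assert abs(res.N0 - 1500.0) / 1500.0 <= 1e-3

    def test_untreated_control_reports_no_death(self):
        p = PDParams(k_p=0.025, theta=2e4)
        times = np.arange(-72.0, 241.0, 24.0)
        rng = np.random.default_rng(3)
        means = simulate_counts(p, 1200.0, times)
        counts = means[None, :] * np.exp(rng.normal(0, 0.05, (6, times.size)) - 0.05**2 / 2)
        res = ResponseModel(times, counts, lam=0.5, loss="log").fit(n_starts=8, seed=0)
        # death rates are zero within their own confidence intervals
        assert res.estimates["k_d_a"] <= 2e-3
        assert res.conf_int["k_d_a"][0] <= 1e-3
        assert res.conf_int["k_d_b"][0] <= 1e-3

    def test_fixed_parameters_are_honoured(self):
        p = PDParams(k_p=0.0212, theta=18000.0, k_d_a=0.02, k_d_b=0.04, r=0.12, lam=0.5)
        times = np.arange(-72.0, 361.0, 24.0)
        counts = simulate_counts(p, 1500.0, times)
        res = ResponseModel(times, counts, lam=0.5, fixed={"k_p": 0.0212}).fit(
            n_starts=6, seed=0
        )
        assert "k_p" not in res.estimates
        assert res.params.k_p == 0.0212
        assert abs(res.estimates["k_d_a"] - p.k_d_a) / p.k_d_a <= 1e-3

    def test_underdetermined_and_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            ResponseModel(np.array([0.0, 1.0]), np.array([[10.0, 12.0]]))
        with pytest.raises(ValueError):
            ResponseModel(np.arange(10.0), np.zeros((2, 10)))


class TestHillModel:
    @staticmethod
    def _curve(dose, ec50=100.0, h=1.0, e_inf=0.0):
        return e_inf + (1 - e_inf) / (1 + (dose / ec50) ** h)

    def test_exact_roundtrip(self):
        dose = 5000.0 / 2.0 ** np.arange(10)
        res = HillModel(dose, self._curve(dose)).fit(n_starts=8, seed=0)
        np.testing.assert_allclose(res.EC50, 100.0, rtol=1e-3)
        np.testing.assert_allclose(res.estimates["hill"], 1.0, rtol=1e-3)
        assert res.estimates["E_inf"] <= 1e-3

    def test_flat_survival_is_non_identifiable(self):
        dose = np.array([10.0, 20.0, 40.0, 80.0])
        res = HillModel(dose, np.ones(4)).fit()
        assert not res.identifiable and res.EC50 is None
        assert "non-identifiable" in res.summary()

    def test_dose_rescaling_rescales_ec50_exactly(self):
        dose = 5000.0 / 2.0 ** np.arange(10)
        surv = self._curve(dose, ec50=150.0, h=1.4, e_inf=0.1)
        a = HillModel(dose, surv).fit(n_starts=8, seed=0)
        c = 37.0
        b = HillModel(dose * c, surv).fit(n_starts=8, seed=0)
        np.testing.assert_allclose(b.EC50 / a.EC50, c, rtol=1e-6)
        np.testing.assert_allclose(b.estimates["hill"], a.estimates["hill"], rtol=1e-6)
        np.testing.assert_allclose(
            b.estimates["E_inf"], a.estimates["E_inf"], rtol=1e-5, atol=1e-8
        )

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError):
            HillModel(np.array([1.0, 2.0, 4.0]), np.array([1.0, 0.6, 0.2]))


class TestConfidenceIntervals:
    def test_pk_ci_coverage_is_near_nominal(self):
        """Curvature-based 95% CIs cover the truth in most noisy refits."""
        design = StudyDesign()
        course = design.uptake_course()
        n_runs, covered = 120, {"k_FE": 0, "k_FB": 0}
        for seed in range(n_runs):
            df, _ = gen_pk_dataset(UPTAKE_PK, course, design, seed=seed)
            res = UptakeModel.from_dataframe(df, course).fit(n_starts=4, seed=0)
            for name in covered:
                lo, hi = res.conf_int[name]
                if lo <= getattr(UPTAKE_PK, name) <= hi:
                    covered[name] += 1
        for name, hits in covered.items():
            assert hits / n_runs >= 0.85, (name, hits)

    def test_bootstrap_intervals_bracket_truth(self):
        design = StudyDesign()
        course = design.uptake_course()
        df, _ = gen_pk_dataset(UPTAKE_PK, course, design, seed=5)
        res = UptakeModel.from_dataframe(df, course).fit(n_starts=4, seed=0)
        boot = res.bootstrap_conf_int(n_boot=40, seed=0)
        for name in ("k_FE", "k_FB"):
            lo, hi = boot[name]
            assert lo < hi
            assert lo <= getattr(UPTAKE_PK, name) * 1.1
            assert hi >= getattr(UPTAKE_PK, name) * 0.9

    def test_summary_lists_all_parameters(self, uptake_noiseless):
        times, means, course = uptake_noiseless
        res = UptakeModel(times, means, course).fit(n_starts=4, seed=0)
        text = res.summary()
        for name in ("k_EF", "k_FE", "k_FB"):
            assert name in text
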