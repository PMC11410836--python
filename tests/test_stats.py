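"""Agreement statistics: MAE test, error bands, Diff statistics, power analysis."""

import numpy as np
import pytest
from scipy import stats as sps

from halluxmetry.errors import ConfigurationError
from halluxmetry.geometry import AngleSet
from halluxmetry.stats import (CaseMeasurements, compare_mae_vs_diff123,
                               error_bands, interrater_diffs, mae_test,
                               power_one_sided, rater_median,
                               required_sample_size, validation_report)


def _angles(value: float) -> AngleSet:
    return AngleSet(PH1a=value, MT1a=value, MT2a=value, MT3a=value,
                    MT4a=value, MT5a=value, HVA=value, IMA=value)


class TestRaterMedian:
    def test_odd_count(self):
        med = rater_median([_angles(10.0), _angles(12.0), _angles(30.0)])
        assert med.HVA == 12.0

    def test_identical_raters(self):
        med = rater_median([_angles(7.5)] * 3)
        assert med.HVA == 7.5

    def test_even_count_averages_middle_pair(self):
        med = rater_median([_angles(10.0), _angles(20.0)])
        assert med.HVA == 15.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rater_median([])


class TestMaeTest:
    def test_perfect_agreement(self):
        res = mae_test([10.0, 12.0, 14.0], [10.0, 12.0, 14.0])
        assert res.mae == 0.0
        assert res.p_value == 0.0  # zero-variance convention, MAE < bound

    def test_constant_error_below_bound(self):
        res = mae_test([11.0, 13.0, 15.0], [10.0, 12.0, 14.0], bound=3.0)
        assert res.mae == pytest.approx(1.0)
        assert res.p_value == 0.0

    def test_hand_computed_four_cases(self):
        """AE = (1, 2, 2, 3): MAE 2, sd sqrt(2/3); t = (2-3)/(sd/2) and the
        one-sided p is the lower tail of t_3 — computed by hand."""
        auto = [11.0, 14.0, 10.0, 3.0]
        ref = [10.0, 12.0, 12.0, 6.0]
        res = mae_test(auto, ref, bound=3.0)
        assert res.mae == pytest.approx(2.0)
        sd = np.sqrt(2.0 / 3.0)
        t = (2.0 - 3.0) / (sd / 2.0)
        assert res.p_value == pytest.approx(float(sps.t.cdf(t, df=3)), rel=1e-9)
        ci = 2.0 + float(sps.t.ppf(0.95, 3)) * sd / 2.0
        assert res.ci95_upper == pytest.approx(ci, rel=1e-9)

    def test_p_value_matches_bootstrap(self):
        """One-sample t-test p against a shifted-resampling bootstrap of the
        same hypothesis, within Monte-Carlo error (n=30, 10k resamples)."""
        rng = np.random.default_rng(42)
        ae = np.abs(rng.normal(1.8, 1.2, size=30))
        res = mae_test(ae + 10.0, np.full(30, 10.0), bound=3.0)
        shifted = ae - ae.mean() + 3.0  # impose H0: mean == bound
        boot = rng.choice(shifted, size=(10_000, 30), replace=True).mean(axis=1)
        p_boot = float((boot <= ae.mean()).mean())
        assert res.p_value == pytest.approx(p_boot, abs=0.02)

    def test_too_few_cases(self):
        with pytest.raises(ValueError):
            mae_test([1.0], [0.0])


class TestErrorBands:
    def test_boundary_convention(self):
        assert error_bands([2.9, 3.0, 5.0, 5.1]) == (1, 2, 1)

    def test_all_zero(self):
        assert error_bands(np.zeros(7)) == (7, 0, 0)

    def test_empty(self):
        assert error_bands([]) == (0, 0, 0)

    def test_counts_sum_to_n(self, rng):
        ae = rng.exponential(2.5, size=200)
        assert sum(error_bands(ae)) == 200

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            error_bands([-0.1])


class TestInterraterDiffs:
    def test_direct_arithmetic(self):
        d = interrater_diffs(np.array([[10.0, 12.0, 14.0]]))
        assert d.loc[0, "Diff_12"] == 2.0
        assert d.loc[0, "Diff_23"] == 2.0
        assert d.loc[0, "Diff_31"] == 4.0
        assert d.loc[0, "Diff_123"] == pytest.approx(8.0 / 3.0)

    def test_identical_raters_zero(self):
        d = interrater_diffs(np.full((5, 3), 9.0))
        assert (d.to_numpy() == 0.0).all()

    def test_diff123_permutation_invariant(self, rng):
        v = rng.normal(size=(20, 3))
        base = interrater_diffs(v)["Diff_123"].to_numpy()
        for perm in ([1, 0, 2], [2, 1, 0], [1, 2, 0]):
            permuted = interrater_diffs(v[:, perm])["Diff_123"].to_numpy()
            assert np.allclose(permuted, base)

    def test_wrong_rater_count_rejected(self):
        with pytest.raises(ValueError):
            interrater_diffs(np.zeros((4, 2)))


class TestCompareMaeVsDiff:
    def test_identical_vectors_give_p_one(self):
        assert compare_mae_vs_diff123([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_constant_shift_gives_p_zero(self):
        assert compare_mae_vs_diff123([1.0, 2.0, 3.0], [2.0, 3.0, 4.0]) == 0.0

    def test_detects_smaller_mae_in_simulation(self, rng):
        """Automatic errors drawn tighter than inter-rater spread: the paired
        test must reject, with the MAE on the smaller side."""
        n = 200
        ae = np.abs(rng.normal(0.0, 0.5, size=n))
        diff123 = np.abs(rng.normal(0.0, 2.0, size=n)) + 0.5
        p = compare_mae_vs_diff123(ae, diff123)
        assert p < 0.001
        assert ae.mean() < diff123.mean()


class TestPowerAnalysis:
    def test_reproduces_published_cohort_size(self):
        assert required_sample_size(assumed_mae=1.5, sd=3.58, bound=3.0,
                                    power=0.99, alpha=0.05) == 92

    def test_agrees_with_statsmodels_solver(self):
        """Independent oracle: statsmodels' noncentral-t power solver,
        ceiled, over a parameter grid."""
        from statsmodels.stats.power import TTestPower
        solver = TTestPower()
        for mae, sd, power in [(1.5, 3.58, 0.99), (1.5, 1.79, 0.99),
                               (2.0, 3.0, 0.9), (1.0, 4.0, 0.8)]:
            expected = solver.solve_power(effect_size=(3.0 - mae) / sd,
                                          alpha=0.05, power=power,
                                          alternative="larger")
            got = required_sample_size(assumed_mae=mae, sd=sd, power=power)
            assert got == int(np.ceil(expected))

    def test_halved_sd_quarters_n(self):
        base = required_sample_size(assumed_mae=1.5, sd=3.58)
        small = required_sample_size(assumed_mae=1.5, sd=1.79)
        assert small == pytest.approx(base / 4, abs=3)

    def test_monotone_in_power_and_sd(self):
        grid_power = [required_sample_size(power=p) for p in (0.5, 0.8, 0.9, 0.99)]
        assert grid_power == sorted(grid_power)
        grid_sd = [required_sample_size(sd=s) for s in (1.0, 2.0, 3.0, 4.0)]
        assert grid_sd == sorted(grid_sd)
        grid_gap = [required_sample_size(assumed_mae=m) for m in (2.5, 2.0, 1.0, 0.5)]
        assert grid_gap == sorted(grid_gap, reverse=True)

    def test_vanishing_power_needs_minimal_n(self):
        assert required_sample_size(power=1e-6) == 2

    def test_zero_effect_rejected(self):
        with pytest.raises(ConfigurationError):
            required_sample_size(assumed_mae=3.0)

    def test_power_formula_matches_monte_carlo(self, rng):
        """Simulation oracle for the noncentral-t power at n=20."""
        n, mae, sd, bound, alpha = 20, 1.5, 3.58, 3.0, 0.05
        analytic = power_one_sided(n, mae, sd, bound, alpha)
        rejections = 0
        trials = 4000
        for _ in range(trials):
            x = rng.normal(mae, sd, size=n)
            t = (x.mean() - bound) / (x.std(ddof=1) / np.sqrt(n))
            if t <= sps.t.ppf(alpha, n - 1):
                rejections += 1
        assert rejections / trials == pytest.approx(analytic, abs=0.03)


class TestValidationReport:
    def _cases(self, rng, n=40):
        cases = []
        for i in range(n):
            truth = rng.normal(0.0, 10.0)
            auto = _angles(truth + rng.normal(0.0, 0.5))
            raters = tuple(_angles(truth + rng.normal(0.0, 2.0)) for _ in range(3))
            cases.append(CaseMeasurements(f"c{i}", auto, raters))
        return cases

    def test_band_counts_sum_to_n(self, rng):
        report = validation_report(self._cases(rng))
        sums = report.table[["n_lt3", "n_3to5", "n_gt5"]].sum(axis=1)
        assert (sums == report.n_cases).all()

    def test_tight_auto_beats_interrater_spread(self, rng):
        report = validation_report(self._cases(rng, n=100))
        row = report.table.loc["HVA"]
        assert row["MAE"] < row["Diff_123_mean"]
        assert row["p_MAE_vs_Diff123"] < 0.05
        assert row["p_vs_bound"] < 0.01

    def test_synthetic_end_to_end_mae_below_interrater_spread(self, rng):
        """Phantoms + simulated raters + injected perfect heatmaps: the
        automatic HVA error is significantly below Diff_123 at n=100."""
        from halluxmetry.extraction import measure_stack
        from halluxmetry.geometry import derive_angles
        from halluxmetry.heatmaps import make_heatmaps
        from halluxmetry.phantoms import RaterModel, generate_phantom, random_spec, simulate_raters

        model = RaterModel(angular_noise_sd=1.5, endpoint_noise_sd=1.0)
        cases = []
        for i in range(100):
            sample = generate_phantom(random_spec(rng, size=256), rng)
            result = measure_stack(make_heatmaps(sample.annotation))
            assert result.ok
            raters = tuple(derive_angles(a) for a in
                           simulate_raters(sample.annotation, model, rng))
            cases.append(CaseMeasurements(f"c{i}", result.angles, raters))
        report = validation_report(cases)
        row = report.table.loc["HVA"]
        assert row["MAE"] < row["Diff_123_mean"]
        assert row["p_MAE_vs_Diff123"] < 0.05

    def test_requires_three_raters(self, rng):
        cases = self._cases(rng, n=4)
        bad = CaseMeasurements("x", _angles(0.0), (_angles(0.0),))
        with pytest.raises(ValueError):
            validation_report(cases[:-1] + [bad])
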