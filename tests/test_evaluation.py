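import numpy as np
import pytest
from scipy import stats

from cmjump import (
    DataError,
    agreement_metrics,
    bland_altman,
    calibration_regression,
    kendall_tau_hetero,
    paired_t,
)
from _oracles import brute_force_tau_b
from cmjump.evaluation import half_swap_importance, half_swap_permutation


class TestAgreement:
    def test_perfect_agreement_all_zero(self):
        m = agreement_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m["rmsd"] == m["bias"] == m["mae"] == m["precision_sd"] == 0.0

    def test_constant_offset(self):
        m = agreement_metrics([10.0, 20.0, 30.0], [12.0, 22.0, 32.0])
        assert m["bias"] == pytest.approx(2.0)
        assert m["precision_sd"] == 0.0
        assert m["rmsd"] == pytest.approx(2.0)
        assert m["mae"] == pytest.approx(2.0)

    def test_hand_computed_fixture(self):
        m = agreement_metrics([0.0, 0.0, 0.0], [-1.0, 0.0, 1.0])
        assert m["bias"] == pytest.approx(0.0)
        assert m["precision_sd"] == pytest.approx(1.0)
        assert m["rmsd"] == pytest.approx(np.sqrt(2.0 / 3.0))
        assert m["mae"] == pytest.approx(2.0 / 3.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            agreement_metrics([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_rmsd_decomposition_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(3, 40)
            t = rng.normal(25, 7, n)
            e = t + rng.normal(-5, 4, n)
            m = agreement_metrics(t, e)
            lhs = m["rmsd"] ** 2
            rhs = m["bias"] ** 2 + (n - 1) / n * m["precision_sd"] ** 2
            assert lhs == pytest.approx(rhs, abs=1e-10)


class TestKendallTau:
    def test_error_growing_with_magnitude_is_heteroscedastic(self):
        true = np.arange(10.0, 40.0)
        est = true + 0.1 * true  # |diff| strictly increasing with average
        tau, flag = kendall_tau_hetero(true, est)
        assert tau == pytest.approx(1.0)
        assert flag

    def test_magnitude_independent_error_is_homoscedastic(self):
        rng = np.random.default_rng(4)
        true = np.linspace(10, 40, 300)
        est = true + rng.permutation(np.resize([-3.0, -1.0, 1.5, 3.5], 300))
        tau, flag = kendall_tau_hetero(true, est)
        assert abs(tau) < 0.1
        assert not flag

    def test_matches_brute_force_on_small_fixtures(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(5, 9))
            true = rng.integers(0, 6, n).astype(float)
            est = true + rng.integers(-3, 4, n)
            means = (true + est) / 2.0
            absd = np.abs(true - est)
            if np.all(absd == absd[0]) or np.all(means == means[0]):
                continue  # undefined tau, covered elsewhere
            tau, _ = kendall_tau_hetero(true, est)
            assert tau == pytest.approx(brute_force_tau_b(means, absd), abs=1e-12)

    def test_all_tied_input_rejected(self):
        with pytest.raises(DataError):
            kendall_tau_hetero(np.full(6, 10.0), np.full(6, 12.0))


class TestPairedT:
    def test_zero_mean_difference(self):
        true = np.array([10.0, 20.0, 30.0, 40.0])
        est = true + np.array([-2.0, 2.0, -2.0, 2.0])
        t, p, dof, ci = paired_t(true, est)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert ci[0] < 0 < ci[1]

    def test_textbook_differences(self):
        true = np.zeros(5)
        est = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        t, p, dof, ci = paired_t(true, est)
        assert t == pytest.approx(3.0 / (np.std(est, ddof=1) / np.sqrt(5)), abs=1e-9)
        assert t == pytest.approx(4.2426, abs=1e-3)
        assert dof == 4

    def test_dof_is_n_minus_one(self):
        rng = np.random.default_rng(2)
        true = rng.normal(25, 7, 43)
        est = true + rng.normal(0, 3, 43)
        _, _, dof, _ = paired_t(true, est)
        assert dof == 42

    def test_zero_variance_rejected(self):
        with pytest.raises(DataError):
            paired_t(np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0]))


class TestCalibration:
    def test_identity_calibration(self):
        x = np.array([10.0, 20.0, 30.0])
        intercept, slope, see, r = calibration_regression(x, x)
        assert (intercept, slope, see, r) == pytest.approx((0.0, 1.0, 0.0, 1.0))

    def test_affine_map_recovered(self):
        est = np.array([5.0, 10.0, 15.0, 20.0])
        true = 2.0 * est + 3.0
        intercept, slope, see, r = calibration_regression(true, est)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(3.0)
        assert see == pytest.approx(0.0, abs=1e-9)
        assert r == pytest.approx(1.0)

    def test_three_point_normal_equations(self):
        est = np.array([0.0, 1.0, 2.0])
        true = np.array([1.0, 3.0, 4.0])
        # hand solution: slope = cov/var = 1.5, intercept = ybar - slope*xbar
        intercept, slope, see, r = calibration_regression(true, est)
        assert slope == pytest.approx(1.5)
        assert intercept == pytest.approx(8.0 / 3.0 - 1.5)
        resid = true - (intercept + slope * est)
        assert see == pytest.approx(np.sqrt(np.sum(resid**2) / 1.0))

    def test_zero_variance_estimate_rejected(self):
        with pytest.raises(DataError):
            calibration_regression(np.array([1.0, 2.0, 3.0]), np.full(3, 2.0))


class TestBlandAltman:
    def test_constant_difference_collapses(self):
        true = np.array([10.0, 20.0, 30.0])
        ba = bland_altman(true, true + 5.0)
        assert ba.bias == pytest.approx(5.0)
        assert ba.loa_low == ba.loa_high == pytest.approx(5.0)
        assert ba.degenerate

    def test_symmetric_differences_zero_standardized_bias(self):
        true = np.array([10.0, 20.0, 30.0])
        ba = bland_altman(true, true + np.array([-2.0, 0.0, 2.0]))
        assert ba.standardized_bias == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_differences_match_closed_forms(self):
        rng = np.random.default_rng(3)
        n = 1000
        true = rng.normal(25, 7, n)
        d = rng.normal(0, 1, n)
        ba = bland_altman(true, true + d)
        assert -0.1 < ba.bias < 0.1
        assert ba.loa_low == pytest.approx(-1.96, abs=0.15)
        assert ba.loa_high == pytest.approx(1.96, abs=0.15)
        # Giavarina CI widths recomputed from first principles
        sd = np.std(d, ddof=1)
        tq = stats.t.ppf(0.975, n - 1)
        assert ba.bias_ci[1] - ba.bias_ci[0] == pytest.approx(2 * tq * sd / np.sqrt(n))
        assert ba.loa_low_ci[1] - ba.loa_low_ci[0] == pytest.approx(
            2 * tq * np.sqrt(3 * sd**2 / n)
        )

    def test_loa_ci_shrinks_as_sqrt_n(self):
        rng = np.random.default_rng(6)
        widths = []
        for n in (50, 200, 800):
            true = rng.normal(25, 7, n)
            d = rng.normal(-2, 1.5, n)
            ba = bland_altman(true, true + d)
            widths.append(ba.loa_high_ci[1] - ba.loa_high_ci[0])
        assert widths[0] > widths[1] * 1.5 > widths[2] * 2.0


class TestHalfSwapImportance:
    def test_ignored_column_scores_exactly_one(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, (60, 3))
        y = 2.0 * x[:, 0] + rng.normal(0, 0.1, 60)
        predict = lambda m: 2.0 * m[:, 0]  # provably ignores columns 1 and 2
        e0, ej = half_swap_importance(predict, x, y, seed=0)
        fi = ej / e0
        assert fi[1] == 1.0
        assert fi[2] == 1.0
        assert fi[0] > 1.0

    def test_importance_ordering_informative_vs_noise(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, (200, 2))
        y = 3.0 * x[:, 0] + rng.normal(0, 0.5, 200)
        predict = lambda m: 3.0 * m[:, 0] + 0.01 * m[:, 1]
        e0, ej = half_swap_importance(predict, x, y, seed=1)
        fi = ej / e0
        assert fi[0] > fi[1]
        assert 0.8 <= fi[1] <= 1.3

    def test_half_swap_is_a_permutation(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(0, 1, 31)
        out = half_swap_permutation(vals, rng)
        np.testing.assert_allclose(np.sort(out), np.sort(vals))
        assert not np.array_equal(out, vals)
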