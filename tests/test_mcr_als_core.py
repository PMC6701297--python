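import numpy as np
import pytest

import mcrquant as mq
from mcrquant.mcr_als_core import (
    ALSConfig,
    apply_correlation_constraint,
    lack_of_fit,
    nonneg_ls_solve,
    run_mcr_als,
)
from mcrquant.simplisma import simplisma_select


class TestLackOfFit:
    def test_exact_reconstruction_is_zero(self):
        rng = np.random.default_rng(0)
        C = rng.uniform(0.1, 1, (6, 2))
        S = rng.uniform(0.1, 1, (2, 9))
        assert lack_of_fit(C @ S, C, S) == pytest.approx(0.0, abs=1e-10)

    def test_zero_model_is_hundred_percent(self):
        D = np.full((3, 4), 0.7)
        assert lack_of_fit(D, np.zeros((3, 1)), np.zeros((1, 4))) == pytest.approx(100.0)

    def test_rank_one_fit_matches_direct_formula_oracle(self):
        # frozen from an element-wise evaluation of the residual/total
        # sum-of-squares ratio scripted independently
        rng = np.random.default_rng(123)
        D = rng.uniform(0.1, 1.0, (4, 3))
        c = rng.uniform(0.5, 1.5, 4)[:, None]
        s = rng.uniform(0.2, 0.8, 3)[None, :]
        assert lack_of_fit(D, c, s) == pytest.approx(47.099645216632474, abs=1e-9)

    def test_all_zero_data_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            lack_of_fit(np.zeros((2, 2)), np.ones((2, 1)), np.ones((1, 2)))


class TestNonnegLeastSquares:
    def test_identity_design_clips_negatives(self):
        B = np.array([[1.0, -2.0], [-0.5, 3.0]])
        X = nonneg_ls_solve(np.eye(2), B)
        np.testing.assert_allclose(X, [[1.0, 0.0], [0.0, 3.0]])

    def test_inactive_constraints_match_ordinary_least_squares(self):
        rng = np.random.default_rng(1)
        A = rng.uniform(0.5, 1.5, (8, 3))
        x_true = rng.uniform(0.5, 2.0, (3, 2))
        B = A @ x_true
        X = nonneg_ls_solve(A, B)
        np.testing.assert_allclose(X, np.linalg.lstsq(A, B, rcond=None)[0],
                                   atol=1e-10)

    def test_toy_system_matches_active_set_enumeration_oracle(self):
        # frozen from exhaustive enumeration of active sets
        A = np.array([[1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        b = np.array([[1.0], [0.2], [-0.5]])
        X = nonneg_ls_solve(A, b)
        np.testing.assert_allclose(X.ravel(), [0.6, 0.0], atol=1e-12)

    def test_rank_deficient_design_warns(self):
        A = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        with pytest.warns(UserWarning, match="rank-deficient"):
            nonneg_ls_solve(A, np.ones((3, 1)))


class TestCorrelationConstraint:
    def test_identity_regression_leaves_column_unchanged(self):
        col = np.array([1.0, 2.0, 3.0, 4.0])
        mask = np.array([True, True, True, True])
        updated, b1, b0 = apply_correlation_constraint(col, col.copy(), mask)
        assert b1 == pytest.approx(1.0)
        assert b0 == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(updated, col)

    def test_pure_rescaling_maps_unknown_through_line(self):
        known = np.array([2.0, 4.0, 6.0, 8.0, np.nan])
        col = np.array([1.0, 2.0, 3.0, 4.0, 1.7])  # resolved = known / 2
        mask = ~np.isnan(known)
        updated, b1, b0 = apply_correlation_constraint(col, known, mask)
        assert b1 == pytest.approx(2.0)
        assert b0 == pytest.approx(0.0, abs=1e-12)
        assert updated[4] == pytest.approx(3.4)

    def test_five_point_regression_matches_closed_form_oracle(self):
        # slope/intercept frozen from the closed-form least-squares line of
        # resolved on known, inverted to the concentration mapping
        col = np.array([0.52, 1.03, 1.48, 2.01, 2.55, 1.7])
        known = np.array([1.0, 2.0, 3.0, 4.0, 5.0, np.nan])
        mask = ~np.isnan(known)
        updated, b1, b0 = apply_correlation_constraint(col, known, mask)
        assert b1 == pytest.approx(1.9841269841269843, rel=1e-12)
        assert b0 == pytest.approx(-0.0119047619047628, abs=1e-10)
        assert updated[5] == pytest.approx(3.3611111111111107, rel=1e-10)
        # calibration rows land on their references
        np.testing.assert_allclose(updated[:5], known[:5])

    def test_zero_variance_resolved_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate correlation"):
            apply_correlation_constraint(
                np.ones(4), np.array([1.0, 2, 3, 4]), np.full(4, True))


class TestRunMcrAls:
    def test_rank_one_system_recovers_in_one_sweep(self):
        c = np.array([1.0, 2.0, 3.0, 4.0])
        s = np.array([0.2, 0.5, 0.3, 0.8, 0.1])
        D = np.outer(c, s)
        known = mq.ConcentrationTable(
            [f"s{i}" for i in range(4)], ["X"], c[:, None],
            ["calibration"] * 4)
        res = run_mcr_als(D, known, s[None, :], ALSConfig(n_components=1))
        assert res.converged
        np.testing.assert_allclose(res.C_resolved.ravel(), c, atol=1e-10)
        assert res.lof_trace[-1] < 1e-8

    def test_noiseless_two_component_recovery(self, two_component_system):
        D, known, pure2, conc = two_component_system
        init = simplisma_select(D, 2)
        res = run_mcr_als(D, known, init, ALSConfig(n_components=2))
        assert res.converged
        preds = mq.analyte_predictions(res, known)
        np.testing.assert_allclose(preds, conc, atol=1e-4)

    def test_constrained_fit_never_ends_worse_than_first_sweep(
            self, D_noisy, cal_known):
        init = simplisma_select(D_noisy, 5)
        res = run_mcr_als(D_noisy, cal_known, init, ALSConfig())
        assert res.lof_trace[-1] <= res.lof_trace[0] * (1 + 1e-6)

    def test_unconstrained_descent_never_ends_worse_than_start(
            self, D_noisy, cal_known):
        init = simplisma_select(D_noisy, 5)
        cfg = ALSConfig(nonneg_C=False, nonneg_S=False,
                        correlation_components=frozenset())
        res = run_mcr_als(D_noisy, cal_known, init, cfg)
        assert res.lof_trace[-1] <= res.lof_initial + 1e-12

    def test_unconstrained_noiseless_fit_reaches_machine_lof(
            self, D_noiseless, cal_known):
        init = simplisma_select(D_noiseless, 5)
        cfg = ALSConfig(n_components=5, nonneg_C=False, nonneg_S=False,
                        correlation_components=frozenset())
        res = run_mcr_als(D_noiseless, cal_known, init, cfg)
        assert res.lof_trace[-1] < 1e-8

    def test_constrained_outputs_are_nonnegative(self, fitted_model):
        res = fitted_model.result
        assert np.all(res.C_resolved >= 0)
        assert np.all(res.S_resolved >= 0)

    def test_scale_invariance_of_quantitation(self, D_noisy, cal_known,
                                              fitted_model):
        scaled = mq.SpectraMatrix(list(D_noisy.sample_ids), D_noisy.grid,
                                  4.2 * D_noisy.absorbance)
        m2 = mq.fit_calibration(scaled, cal_known)
        np.testing.assert_allclose(m2.calibration_predictions,
                                   fitted_model.calibration_predictions,
                                   atol=1e-8)

    def test_iteration_cap_returns_unconverged_with_warning(
            self, D_noisy, cal_known):
        init = simplisma_select(D_noisy, 5)
        with pytest.warns(UserWarning, match="iteration cap"):
            res = run_mcr_als(D_noisy, cal_known, init, ALSConfig(max_iter=1))
        assert not res.converged
        assert res.n_iter == 1

    def test_non_finite_data_rejected(self, cal_known):
        D = np.full((25, 26), np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            run_mcr_als(D, cal_known, np.ones((5, 26)), ALSConfig())

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            ALSConfig(tol_pct=0.0)
        with pytest.raises(ValueError):
            ALSConfig(max_iter=0)
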