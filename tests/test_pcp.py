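"""Low-rank + sparse decomposition: loss oracle, recovery, model selection."""

import numpy as np
import numpy.linalg as la
import pytest

from expomix import (PCPParams, cross_validate, decompose, default_lambda,
                     default_mu, lod_aware_loss, scale_columns, substitute_lod)


def _loss_oracle(X, X_hat, lod, detect, missing):
    """Naive double-loop reference for the detected-cells-only loss."""
    total = 0.0
    n, p = X.shape
    for i in range(n):
        for j in range(p):
            if detect[i, j] and not missing[i, j]:
                total += (X[i, j] - X_hat[i, j]) ** 2
    return total


class TestLodAwareLoss:
    def test_perfect_reconstruction_is_zero(self):
        X = np.random.default_rng(0).normal(size=(6, 4)) + 5
        assert lod_aware_loss(X, X, np.ones(4), np.ones((6, 4), bool)) == 0.0

    def test_all_censored_is_zero_regardless_of_fit(self):
        X = np.abs(np.random.default_rng(1).normal(size=(5, 3)))
        X_hat = X + 100.0
        detect = np.zeros((5, 3), bool)
        assert lod_aware_loss(X, X_hat, np.ones(3), detect) == 0.0

    def test_two_by_two_against_hand_computation(self):
        X = np.array([[3.0, 1.0], [5.0, 0.4]])
        lod = np.array([2.0, 0.5])
        X_hat = np.array([[2.0, 1.0], [4.0, 0.4]])
        detect = X > lod[None, :]
        expected = (3.0 - 2.0) ** 2 + (5.0 - 4.0) ** 2   # the two detected cells
        got = lod_aware_loss(X, X_hat, lod, detect)
        assert got == pytest.approx(expected, abs=1e-14)
        assert got == pytest.approx(
            _loss_oracle(X, X_hat, lod, detect, np.zeros((2, 2), bool)), abs=1e-14)

    def test_matches_double_loop_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for k in range(100):
            X = rng.normal(size=(10, 10)) + 2
            X_hat = X + rng.normal(scale=0.3, size=(10, 10))
            lod = np.abs(rng.normal(size=10)) + 0.1
            detect = X > lod[None, :]
            if k == 0:
                detect[:] = False     # all-censored limit
            if k == 1:
                detect[:] = True      # no-censoring limit
            missing = rng.uniform(size=(10, 10)) < 0.1
            got = lod_aware_loss(X, X_hat, lod, detect, missing)
            want = _loss_oracle(X, X_hat, lod, detect, missing)
            assert abs(got - want) <= 1e-12 * max(1.0, want)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lod_aware_loss(np.zeros((3, 2)), np.zeros((2, 3)), np.ones(2),
                           np.ones((3, 2), bool))


class TestDefaultLambda:
    @pytest.mark.parametrize("n, p, expected", [(100, 25, 0.1), (4, 4, 0.5)])
    def test_known_values(self, n, p, expected):
        assert default_lambda(n, p) == pytest.approx(expected)

    def test_monotone_in_max_dimension(self):
        vals = [default_lambda(n, 10) for n in (10, 50, 100, 1000)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestDecompose:
    def test_zero_matrix_gives_zero_components(self):
        res = decompose(np.zeros((6, 5)), 0.1 * np.ones(5), np.ones((6, 5), bool),
                        None, PCPParams(lam=0.3, mu=10, rank=2))
        assert la.norm(res.L) == 0 and la.norm(res.S) == 0
        assert res.converged

    def test_exact_rank_one_clean_limit(self):
        rng = np.random.default_rng(7)
        u = np.abs(rng.normal(size=40)) + 0.1
        v = np.abs(rng.normal(size=8)) + 0.1
        X = np.outer(u, v)
        res = decompose(X, 1e-6 * np.ones(8), np.ones((40, 8), bool), None,
                        PCPParams(lam=default_lambda(40, 8), mu=default_mu(40, 8), rank=1))
        assert la.norm(res.S) < 1e-6 * la.norm(X)
        assert la.norm(res.L - X) < 1e-6 * la.norm(X)

    def test_clean_simulator_recovery(self, clean_study, scaled_clean):
        pan, scaled, factors, lod_scaled = scaled_clean
        params = PCPParams(lam=default_lambda(*scaled.shape),
                           mu=default_mu(*scaled.shape), rank=3)
        res = decompose(scaled.values, lod_scaled.values, pan.detect_flag.values,
                        pan.missing_mask.values, params)
        L_true = clean_study.true_L / factors.values[None, :]
        assert la.norm(res.L - L_true) / la.norm(L_true) < 1e-3

    def test_objective_trace_is_monotone(self, censored_study):
        pan = censored_study.panel
        scaled, _, lod_scaled = scale_columns(pan)
        params = PCPParams(lam=default_lambda(*scaled.shape),
                           mu=default_mu(*scaled.shape), rank=3, max_iter=300)
        res = decompose(scaled.values, lod_scaled.values, pan.detect_flag.values,
                        pan.missing_mask.values, params)
        assert np.all(np.diff(res.objective_trace) <= 1e-9)

    def test_censored_cells_fit_within_interval(self, censored_study):
        pan = censored_study.panel
        scaled, _, lod_scaled = scale_columns(pan)
        params = PCPParams(lam=default_lambda(*scaled.shape),
                           mu=default_mu(*scaled.shape), rank=3, max_iter=2000)
        res = decompose(scaled.values, lod_scaled.values, pan.detect_flag.values,
                        pan.missing_mask.values, params)
        cens = pan.censor_mask().values
        fitted = (res.L + res.S)[cens]
        lod_grid = (np.ones_like(res.L) * lod_scaled.values[None, :])[cens]
        inside = (fitted >= -1e-6) & (fitted <= lod_grid + 1e-6)
        assert inside.mean() > 0.95

    def test_nonnegativity_and_rank_bound(self, scaled_clean):
        pan, scaled, _, lod_scaled = scaled_clean
        params = PCPParams(lam=default_lambda(*scaled.shape),
                           mu=default_mu(*scaled.shape), rank=3)
        res = decompose(scaled.values, lod_scaled.values, pan.detect_flag.values,
                        pan.missing_mask.values, params)
        assert res.L.min() >= -1e-10
        s = la.svd(res.L, compute_uv=False)
        assert (s > 1e-8 * s[0]).sum() <= 3

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PCPParams(lam=-1, mu=1).validate()
        with pytest.raises(ValueError):
            PCPParams(lam=1, mu=1, rank=10).validate((4, 4))


class TestCrossValidate:
    @staticmethod
    def _inputs(study):
        pan = substitute_lod(study.panel)
        scaled, _, lod_scaled = scale_columns(pan)
        return (scaled.values, lod_scaled.values, pan.detect_flag.values,
                pan.missing_mask.values)

    def test_single_point_grid_is_best(self, clean_study):
        X, lod, detect, missing = self._inputs(clean_study)
        p = PCPParams(lam=default_lambda(*X.shape), mu=default_mu(*X.shape), rank=2,
                      max_iter=200)
        report = cross_validate(X, lod, detect, missing, [p])
        assert report.best is p and report.best_index == 0

    def test_duplicate_grid_points_give_identical_losses(self, clean_study):
        X, lod, detect, missing = self._inputs(clean_study)
        mk = lambda: PCPParams(lam=default_lambda(*X.shape), mu=default_mu(*X.shape),
                               rank=2, max_iter=150)
        report = cross_validate(X, lod, detect, missing, [mk(), mk()])
        assert report.losses[0] == report.losses[1]

    def test_holdout_mode_selects_adequate_rank(self, clean_study):
        X, lod, detect, missing = self._inputs(clean_study)
        lam, mu = default_lambda(*X.shape), default_mu(*X.shape)
        grid = [PCPParams(lam=lam, mu=mu, rank=r, max_iter=400) for r in (1, 2, 3, 4)]
        report = cross_validate(X, lod, detect, missing, grid, mode="holdout", seed=0)
        assert report.best.rank >= 3
        # the selected fit beats rank 1 on ground truth
        best = decompose(X, lod, detect, missing, report.best)
        rank1 = decompose(X, lod, detect, missing, grid[0])
        factors = clean_study.panel.values.std(ddof=1).values
        L_true_scaled = clean_study.true_L / factors[None, :]
        err = lambda L: la.norm(L - L_true_scaled)
        assert err(best.L) < err(rank1.L)

    def test_empty_grid_rejected(self, clean_study):
        X, lod, detect, missing = self._inputs(clean_study)
        with pytest.raises(ValueError):
            cross_validate(X, lod, detect, missing, [])
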