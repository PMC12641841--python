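"""Residual rescaling and High/Low/Sparse exposure-event classification."""

import numpy as np
import pytest

from expomix import (classify_events, rescale_sparse, residual_matrix,
                     tier_by_lod_median)
from expomix.anomaly import HIGH, LOW, MISSING, SPARSE


class TestResidualMatrix:
    def test_identical_matrices_give_zero(self):
        X = np.random.default_rng(0).normal(size=(8, 4))
        assert np.all(residual_matrix(X, X) == 0.0)

    def test_single_cell_difference(self):
        X = np.zeros((5, 3))
        L = np.zeros((5, 3))
        X[2, 1] = 2.0
        R = residual_matrix(X, L)
        assert R[2, 1] == 2.0 and np.count_nonzero(R) == 1

    def test_missing_cells_propagate(self):
        X = np.ones((4, 2))
        missing = np.zeros((4, 2), bool)
        missing[0, 0] = True
        R = residual_matrix(X, np.zeros((4, 2)), missing)
        assert np.isnan(R[0, 0]) and R[1, 1] == 1.0

    def test_residuals_larger_at_true_spike_cells(self, clean_study):
        from expomix import PCPParams, decompose, default_lambda, default_mu, scale_columns
        pan = clean_study.panel
        scaled, factors, lod_scaled = scale_columns(pan)
        res = decompose(scaled.values, lod_scaled.values, pan.detect_flag.values,
                        pan.missing_mask.values,
                        PCPParams(lam=default_lambda(*scaled.shape),
                                  mu=default_mu(*scaled.shape), rank=3))
        R = residual_matrix(scaled.values, res.L)
        spikes = clean_study.true_S != 0
        assert np.abs(R[spikes]).mean() > 5 * np.abs(R[~spikes]).mean()


class TestRescaleSparse:
    def test_divides_by_residual_sd(self):
        rng = np.random.default_rng(1)
        residuals = rng.normal(scale=2.0, size=(4001, 1))
        S = np.zeros((4001, 1))
        S[0, 0] = 4.0
        rescaled = rescale_sparse(S, residuals)
        assert rescaled[0, 0] == pytest.approx(4.0 / residuals.std(ddof=1), rel=1e-12)

    def test_zero_sparse_stays_zero(self):
        residuals = np.random.default_rng(2).normal(size=(50, 3))
        assert np.all(rescale_sparse(np.zeros((50, 3)), residuals) == 0.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        S = rng.normal(size=(30, 2))
        residuals = rng.normal(size=(30, 2))
        a = rescale_sparse(S, residuals)
        b = rescale_sparse(2 * S, 2 * residuals)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_zero_residual_sd_is_error(self):
        with pytest.raises(ValueError, match="0"):
            rescale_sparse(np.ones((5, 1)), np.ones((5, 1)))


class TestClassifyEvents:
    def test_thousand_distinct_values_give_fifty_fifty(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=1000)
        grid = classify_events(vals.reshape(100, 10))
        counts = grid.counts()
        assert abs(counts.get(HIGH, 0) - 50) <= 1
        assert abs(counts.get(LOW, 0) - 50) <= 1

    def test_all_zero_matrix_is_all_sparse(self):
        with pytest.warns(RuntimeWarning):
            grid = classify_events(np.zeros((10, 5)))
        assert np.all(grid.labels == SPARSE)

    def test_huge_outlier_becomes_high(self):
        rng = np.random.default_rng(5)
        M = rng.normal(size=(20, 5))
        M[3, 2] = 1e6
        grid = classify_events(M)
        assert grid.labels[3, 2] == HIGH

    def test_invariant_under_strictly_increasing_transform(self):
        rng = np.random.default_rng(6)
        M = rng.normal(size=(40, 8))
        a = classify_events(M).labels
        b = classify_events(np.exp(M)).labels  # strictly increasing map
        assert np.array_equal(a, b)

    def test_partition_is_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(7)
        M = rng.normal(size=(50, 6))
        M[rng.uniform(size=(50, 6)) < 0.1] = np.nan
        grid = classify_events(M)
        counts = grid.counts()
        assert sum(counts.values()) == M.size
        n_missing = int(np.isnan(M).sum())
        assert counts.get(MISSING, 0) == n_missing

    def test_spike_recall_exceeds_base_rate(self):
        """High labels concentrate on true spike cells at spike_scale >= 3."""
        from expomix import (MixtureSimConfig, PCPParams, decompose, default_lambda,
                             default_mu, generate_exposure_matrix, scale_columns)
        cfg = MixtureSimConfig(n_participants=200, n_analytes=20, true_rank=3,
                               spike_fraction=0.02, spike_scale=3.0,
                               lod_quantiles=0.0, noise_sd=0.3, seed=13)
        st = generate_exposure_matrix(cfg)
        pan = st.panel
        scaled, _, lod_scaled = scale_columns(pan)
        res = decompose(scaled.values, lod_scaled.values, pan.detect_flag.values,
                        pan.missing_mask.values,
                        PCPParams(lam=default_lambda(*scaled.shape),
                                  mu=default_mu(*scaled.shape), rank=3, max_iter=1000))
        R = residual_matrix(scaled.values, res.L)
        grid = classify_events(rescale_sparse(res.S, R))
        spikes = st.true_S != 0
        high = grid.labels == HIGH
        recall = high[spikes].mean()          # P(High | spike)
        base_rate = high.mean()               # P(High)
        assert recall >= 5 * base_rate

    def test_degenerate_quantile_order_rejected(self):
        with pytest.raises(ValueError):
            classify_events(np.random.default_rng(0).normal(size=(5, 5)),
                            q_hi=0.05, q_lo=0.95)


class TestTierByLodMedian:
    @staticmethod
    def _panel(values, lod, detect):
        import pandas as pd

        from expomix.panel import ExposurePanel
        values = pd.DataFrame(values, columns=["a0"])
        values.index = pd.Index([f"P{i}" for i in range(len(values))],
                                name="participant_id")
        return ExposurePanel(
            values=values, lod=pd.Series(lod, index=["a0"], dtype=float),
            detect_flag=pd.DataFrame(detect, index=values.index, columns=["a0"]),
            missing_mask=pd.DataFrame(False, index=values.index, columns=["a0"]),
            analyte_class=pd.Series(["metal"], index=["a0"]),
            units=pd.Series(["ug/L"], index=["a0"]))

    def test_below_lod_is_sparse_and_median_boundary_is_low(self):
        # detected values 1..5 → median 3; the cell at exactly 3 is Low
        vals = [[np.nan], [1.0], [2.0], [3.0], [4.0], [5.0]]
        detect = [[False], [True], [True], [True], [True], [True]]
        labels = tier_by_lod_median(self._panel(vals, [0.5], detect))
        assert labels[0, 0] == SPARSE
        assert labels[3, 0] == LOW     # value 3.0 == median → Low
        assert labels[5, 0] == HIGH

    def test_all_detected_distinct_gives_half_low(self):
        n = 10   # even n: exactly n/2 values fall at or below the median
        vals = [[float(i + 1)] for i in range(n)]
        detect = [[True]] * n
        labels = tier_by_lod_median(self._panel(vals, [0.1], detect))
        assert (labels == LOW).sum() == n // 2

    def test_no_detects_all_sparse_with_warning(self):
        vals = [[np.nan], [np.nan]]
        detect = [[False], [False]]
        with pytest.warns(RuntimeWarning):
            labels = tier_by_lod_median(self._panel(vals, [1.0], detect))
        assert np.all(labels == SPARSE)
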