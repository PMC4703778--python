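import numpy as np
import pytest
from scipy.stats import norm

import pwconsensus as pw
from pwconsensus.consensus_dynamic import (
    DenseTimeSeries, densify, fit_dbn, infer_network, select_hidden_dim,
    threshold_edges,
)
from pwconsensus.errors import ValidationError

GRID7 = np.array([0.0, 1.0, 4.0, 8.0, 13.0, 18.0, 24.0])


def dense_from(Y, T=None):
    Y = np.asarray(Y, dtype=float)
    T = Y.shape[1] if T is None else T
    molecules = [(f"M{i}", "gene") for i in range(Y.shape[0])]
    return DenseTimeSeries(molecules, np.arange(T, dtype=float), Y)


def simulate_var(D, T, noise_sd, seed):
    rng = np.random.default_rng(seed)
    P = D.shape[0]
    Y = np.zeros((P, T))
    for t in range(1, T):
        Y[:, t] = D @ Y[:, t - 1] + rng.normal(0, noise_sd, P)
    return Y


class TestDensify:
    def test_linear_series_reproduced(self):
        y = 0.5 * GRID7 - 1.0
        dense = densify(GRID7, y[None, :], ["A"], smoothing="interpolate",
                        standardize=False)
        assert np.abs(dense.values[0] - (0.5 * dense.grid - 1.0)).max() < 1e-8

    def test_cubic_polynomial_reproduced(self):
        poly = np.polynomial.Polynomial([0.2, 1.0, -0.2, 0.01])
        dense = densify(GRID7, poly(GRID7)[None, :], ["A"],
                        smoothing="interpolate", standardize=False)
        assert np.abs(dense.values[0] - poly(dense.grid)).max() < 1e-6

    def test_exact_at_measured_knots(self):
        rng = np.random.default_rng(2)
        values = np.cumsum(rng.normal(size=(3, 7)), axis=1)
        dense = densify(GRID7, values, ["A", "B", "C"], n_grid=47,
                        smoothing="interpolate", standardize=False)
        for t_idx, t in enumerate(GRID7):
            grid_idx = np.argmin(np.abs(dense.grid - t))
            if np.isclose(dense.grid[grid_idx], t):
                assert np.allclose(dense.values[:, grid_idx], values[:, t_idx])

    def test_standardized_output(self):
        rng = np.random.default_rng(3)
        dense = densify(GRID7, rng.normal(size=(2, 7)), ["A", "B"])
        assert np.allclose(dense.values.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(dense.values.std(axis=1), 1, atol=1e-9)

    def test_constant_series_rejected(self):
        with pytest.raises(ValidationError, match="A"):
            densify(GRID7, np.ones((1, 7)), ["A"])

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValidationError):
            densify([0, 1, 4], np.zeros((1, 3)), ["A"])


class TestSelectHiddenDim:
    def test_rank_one_latent_dynamic(self):
        rng = np.random.default_rng(3)
        T = 100
        x = np.zeros(T)
        for t in range(1, T):
            x[t] = 0.9 * x[t - 1] + rng.normal()
        loadings = np.array([[1.0], [0.5], [-0.7]])
        dense = dense_from(loadings @ x[None, :])
        assert select_hidden_dim(dense) == 1

    def test_all_zero_hankel(self):
        dense = dense_from(np.zeros((2, 20)))
        assert select_hidden_dim(dense) == 0

    def test_capped_at_max_K(self):
        rng = np.random.default_rng(5)
        dense = dense_from(rng.normal(size=(8, 40)))
        assert select_hidden_dim(dense, max_K=2) <= 2


class TestFitDbn:
    def test_var_recovery_and_z_ranking(self):
        D = np.array([[0.8, 0.0], [0.5, 0.3]])
        dense = dense_from(simulate_var(D, 200, 0.1, seed=0))
        result = infer_network(dense, K=0, seed=0)
        assert np.abs(result.fit.D - D).max() < 0.1
        true_mask = D != 0
        assert np.abs(result.z)[true_mask].min() > np.abs(result.z)[~true_mask].max()

    def test_scalar_ar1(self):
        Y = simulate_var(np.array([[0.7]]), 80, 0.2, seed=1)
        fit = fit_dbn(dense_from(Y), K=0)
        z = fit.D / fit.d_se
        assert np.isfinite(z[0, 0])
        assert abs(fit.D[0, 0] - 0.7) < 0.25

    def test_consistency_with_grid_length(self):
        D = np.array([[0.6, 0.2, 0.0],
                      [0.0, 0.5, -0.3],
                      [0.2, 0.0, 0.4]])
        errs = {T: [] for T in (50, 400)}
        for seed in range(7):
            for T in errs:
                Y = simulate_var(D, T, 0.3, seed=seed)
                fit = fit_dbn(dense_from(Y), K=0)
                errs[T].append(np.abs(fit.D - D).max())
        assert np.median(errs[400]) < np.median(errs[50])

    def test_hidden_state_model_runs_and_is_deterministic(self):
        rng = np.random.default_rng(8)
        T = 60
        x = np.zeros(T)
        for t in range(1, T):
            x[t] = 0.8 * x[t - 1] + rng.normal()
        Y = np.vstack([x, 0.5 * x]) + rng.normal(0, 0.1, (2, T))
        dense = dense_from(Y)
        fit1 = fit_dbn(dense, K=1, seed=4)
        fit2 = fit_dbn(dense, K=1, seed=4)
        assert fit1.K == 1 and fit1.C.shape == (2, 1)
        assert np.array_equal(fit1.D, fit2.D) and np.array_equal(fit1.A, fit2.A)
        assert np.all(fit1.obs_precision > 0)

    def test_negative_K_rejected(self):
        with pytest.raises(ValidationError):
            fit_dbn(dense_from(np.zeros((1, 20))), K=-1)

    def test_short_grid_rejected(self):
        with pytest.raises(ValidationError):
            fit_dbn(dense_from(np.zeros((1, 5))), K=0)


class TestThresholdEdges:
    def test_standard_normal_quantile_oracle(self):
        z = np.array([[0.0, 2.0], [1.0, 0.0]])
        D = np.sign(z) * 0.5
        edges = threshold_edges(z, D, alpha=0.15)
        # quantile ~ 1.4395; only |z|=2.0 passes: z[0, 1] is edge 1 -> 0
        assert norm.ppf(1 - 0.15 / 2) == pytest.approx(1.4395, abs=1e-4)
        assert edges == [(1, 0, "activation")]

    def test_alpha_one_keeps_everything(self):
        z = np.array([[0.2, -0.1], [0.3, 0.4]])
        assert len(threshold_edges(z, z, alpha=1.0)) == 4

    def test_tiny_alpha_keeps_nothing(self):
        z = np.array([[3.0, -2.0], [1.0, 4.0]])
        assert threshold_edges(z, z, alpha=1e-12) == []

    def test_nested_in_alpha(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=(5, 5)) * 2
        previous = set()
        for alpha in (0.01, 0.05, 0.15, 0.5, 1.0):
            edges = set(threshold_edges(z, z, alpha))
            assert previous <= edges
            previous = edges

    def test_sign_labels(self):
        z = np.array([[3.0, -3.0], [0.0, 0.0]])
        D = np.array([[0.5, -0.5], [0.0, 0.0]])
        edges = threshold_edges(z, D, alpha=0.05)
        assert (0, 0, "activation") in edges and (1, 0, "inhibition") in edges

    def test_invalid_alpha(self):
        with pytest.raises(ValidationError):
            threshold_edges(np.zeros((1, 1)), np.zeros((1, 1)), alpha=0.0)


class TestNullCalibration:
    def test_flagged_fraction_matches_alpha(self):
        """With no true interactions the chance-edge rate should sit at alpha."""
        P, T, alpha = 8, 50, 0.15
        fractions = []
        for seed in range(20):
            Y = np.random.default_rng([101, seed]).normal(size=(P, T))
            result = infer_network(dense_from(Y), K=0, alpha=alpha, seed=seed)
            fractions.append(len(result.adjacency) / P**2)
        mean = np.mean(fractions)
        mc_se = np.std(fractions, ddof=1) / np.sqrt(len(fractions))
        assert abs(mean - alpha) <= 3 * mc_se


def test_full_determinism_of_inference():
    Y = simulate_var(np.array([[0.6, 0.0], [0.4, 0.5]]), 60, 0.2, seed=3)
    dense = dense_from(Y)
    r1 = infer_network(dense, K=0, seed=7)
    r2 = infer_network(dense, K=0, seed=7)
    assert np.array_equal(r1.fit.D, r2.fit.D)
    assert np.array_equal(r1.z, r2.z)
    assert r1.adjacency == r2.adjacency
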