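"""Dynamic consensus analysis: spline densification and state-space network
inference.

The measured grids are too sparse for dynamic network inference, so each
consensus molecule's log2 fold-change course is first densified with a cubic
smoothing spline (smoothing parameter by generalized cross-validation) under
the assumption of gradually changing signaling, then standardized.  On the
dense series a linear feedback state-space model

    x_t = A x_{t-1} + B y_{t-1} + w_t,      w_t ~ N(0, I)
    y_t = C x_t + D y_{t-1} + v_t,          v_t ~ N(0, diag(1/v))

is fitted by an EM algorithm with hierarchical zero-mean priors on the rows
of A, B, C and D whose precision hyperparameters are re-estimated at every
iteration (empirical Bayes).  Hidden-state posteriors come from Kalman
filter/smoother recursions; the hidden dimension K is chosen from the
singular-value spectrum of a block-Hankel matrix of autocovariances.  The
observed-feedback matrix D is the inferred network: an edge i -> j is kept
when the z-score of D[j, i] exceeds the two-sided standard-normal quantile
for the configured chance-edge probability (default 0.15), signed by the
coefficient.

The z-score of an edge weight is its posterior mean divided by the standard
error of that posterior mean under the observation noise, which makes the
chance-edge probability exact for data without true interactions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import networkx as nx
import numpy as np
from scipy.interpolate import CubicSpline, make_smoothing_spline
from scipy.stats import norm

from .errors import PwConsensusError, ValidationError

logger = logging.getLogger(__name__)

Node = Tuple[str, str]  # (symbol, layer)


@dataclass
class DenseTimeSeries:
    """Equally spaced, spline-densified time courses of tagged molecules."""

    molecules: List[Node]
    grid: np.ndarray
    values: np.ndarray  # molecules x grid
    standardized: bool = True

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        steps = np.diff(self.grid)
        if len(self.grid) < 2 or np.any(steps <= 0) or not np.allclose(steps, steps[0]):
            raise ValidationError("grid must be strictly increasing with constant step")
        if self.values.shape != (len(self.molecules), len(self.grid)):
            raise ValidationError("values shape does not match molecules x grid")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("dense values contain non-finite entries")


def densify(
    times: Sequence[float],
    values: np.ndarray,
    molecules: Sequence[Union[Node, str]],
    n_grid: int = 50,
    smoothing: str = "gcv",
    standardize: bool = True,
) -> DenseTimeSeries:
    """Fit a cubic (smoothing) spline per molecule and sample it on an equally
    spaced grid spanning the measured interval.

    ``smoothing='gcv'`` selects the smoothing parameter by generalized
    cross-validation; ``'interpolate'`` fits an exact cubic interpolant.
    Output series are standardized to zero mean / unit variance unless
    ``standardize=False``; constant series are rejected.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    molecules = [m if isinstance(m, tuple) else (str(m), "unknown") for m in molecules]
    if times.ndim != 1 or len(times) < 4:
        raise ValidationError(f"need >=4 measured timepoints, got {len(times)}")
    if n_grid < len(times):
        raise ValidationError(f"n_grid={n_grid} smaller than number of measured points")
    if smoothing not in ("gcv", "interpolate"):
        raise ValidationError(f"unknown smoothing mode {smoothing!r}")
    grid = np.linspace(times[0], times[-1], n_grid)
    dense = np.empty((len(molecules), n_grid))
    for i, molecule in enumerate(molecules):
        y = values[i]
        if np.allclose(y, y[0]):
            raise ValidationError(f"constant series for molecule {molecule[0]!r}")
        if smoothing == "interpolate" or len(times) < 5:
            # GCV needs >= 5 knots; with 4 the cubic interpolant is the fit
            spline = CubicSpline(times, y)
        else:
            spline = make_smoothing_spline(times, y)
        dense[i] = spline(grid)
        if standardize:
            sd = dense[i].std()
            if sd < 1e-12:
                raise ValidationError(
                    f"zero-variance densified series for molecule {molecule[0]!r}"
                )
            dense[i] = (dense[i] - dense[i].mean()) / sd
    return DenseTimeSeries(list(molecules), grid, dense, standardized=standardize)


def select_hidden_dim(dense: DenseTimeSeries, max_K: int = 5, cutoff: float = 0.90) -> int:
    """Choose the hidden dimension from the block-Hankel autocovariance SVD.

    Returns the smallest K whose cumulative singular-value mass reaches
    ``cutoff``, capped at ``max_K``; 0 for a degenerate (all-zero) Hankel.
    """
    Y = dense.values - dense.values.mean(axis=1, keepdims=True)
    P, T = Y.shape
    n_blocks = max(1, min(4, (T - 1) // 2))
    lags = 2 * n_blocks - 1
    covs = [Y[:, : T - k] @ Y[:, k:].T / (T - k) for k in range(1, lags + 1)]
    hankel = np.block(
        [[covs[i + j] for j in range(n_blocks)] for i in range(n_blocks)]
    )
    s = np.linalg.svd(hankel, compute_uv=False)
    total = s.sum()
    if total < 1e-10:
        return 0
    frac = np.cumsum(s) / total
    K = int(np.searchsorted(frac, cutoff) + 1)
    return min(K, max_K)


@dataclass
class StateSpaceFit:
    """Parameter estimates of the linear feedback state-space model."""

    K: int
    A: np.ndarray  # K x K
    B: np.ndarray  # K x P
    C: np.ndarray  # P x K
    D: np.ndarray  # P x P, the network matrix
    alpha: np.ndarray  # per-row prior precision of A (length K)
    beta: np.ndarray  # per-row prior precision of B (length K)
    gamma: np.ndarray  # per-row prior precision of C (length P)
    delta: np.ndarray  # per-row prior precision of D (length P)
    obs_precision: np.ndarray  # length P
    d_se: np.ndarray  # P x P standard errors of D entries
    iterations: int
    converged: bool

    def __post_init__(self) -> None:
        P = self.D.shape[0]
        expected = {
            "A": (self.K, self.K), "B": (self.K, P), "C": (P, self.K),
            "D": (P, P), "d_se": (P, P),
        }
        for name, shape in expected.items():
            if getattr(self, name).shape != shape:
                raise ValidationError(f"{name} has shape {getattr(self, name).shape}, expected {shape}")
        for name in ("alpha", "beta", "gamma", "delta", "obs_precision"):
            arr = getattr(self, name)
            if np.any(arr <= 0):
                raise ValidationError(f"{name} must be strictly positive")


def _check_finite(arrays, iteration: int) -> None:
    for arr in arrays:
        if not np.all(np.isfinite(arr)):
            raise PwConsensusError(f"non-finite values during EM at iteration {iteration}")


def _rel_change(new: np.ndarray, old: np.ndarray) -> float:
    return float(np.max(np.abs(new - old) / np.maximum(np.abs(old), 1e-12)))


def fit_dbn(
    dense: DenseTimeSeries,
    K: int,
    max_iter: int = 100,
    tol: float = 1e-3,
    seed: int = 0,
) -> StateSpaceFit:
    """Empirical-Bayes EM estimation of the state-space model.

    Convergence is declared when the maximum relative change of all precision
    hyperparameters falls below ``tol``; otherwise the fit is returned with
    ``converged=False`` and a warning.  With ``K=0`` the model reduces to the
    first-order vector autoregression ``y_t = D y_{t-1} + v_t``.
    """
    if K < 0:
        raise ValidationError(f"K must be >= 0, got {K}")
    Y = dense.values
    P, T = Y.shape
    if T < 10:
        raise ValidationError(f"grid length {T} too short; need >= 10")
    rng = np.random.default_rng(seed)

    if K == 0:
        return _fit_var(Y, max_iter, tol)

    # initialization (seeded)
    A = rng.normal(0.0, 0.1, (K, K))
    B = rng.normal(0.0, 0.1, (K, P))
    C = rng.normal(0.0, 0.5, (P, K))
    D = rng.normal(0.0, 0.1, (P, P))
    v = np.ones(P)
    alpha, beta = np.ones(K), np.ones(K)
    gamma, delta = np.ones(P), np.ones(P)

    converged = False
    iteration = 0
    Mz = None
    sigma_obs = [np.eye(K + P) for _ in range(P)]
    for iteration in range(1, max_iter + 1):
        hyper_old = np.concatenate([alpha, beta, gamma, delta, v])

        xs, Ps, Pcross = _kalman_smoother(Y, A, B, C, D, v)
        # summed moments over t = 2..T (index 1..T-1)
        Exx_prev = Ps[:-1].sum(axis=0) + xs[:-1].T @ xs[:-1]
        Exx_cur = Ps[1:].sum(axis=0) + xs[1:].T @ xs[1:]
        Ex_xprev = Pcross.sum(axis=0) + xs[1:].T @ xs[:-1]
        Yprev = Y[:, :-1].T  # (T-1) x P
        Ycur = Y[:, 1:].T
        Sx_prev_y = xs[:-1].T @ Yprev  # K x P
        Sx_cur_y = xs[1:].T @ Yprev
        Syy = Yprev.T @ Yprev

        # hidden equation rows: regression of x_t on [x_{t-1}; y_{t-1}]
        Mu = np.block([[Exx_prev, Sx_prev_y], [Sx_prev_y.T, Syy]])
        for j in range(K):
            prior = np.concatenate([np.full(K, alpha[j]), np.full(P, beta[j])])
            Sigma = np.linalg.inv(Mu + np.diag(prior))
            target = np.concatenate([Ex_xprev[j], xs[1:, j] @ Yprev])
            mu = Sigma @ target
            A[j], B[j] = mu[:K], mu[K:]
            alpha[j] = K / max(np.sum(A[j] ** 2) + np.trace(Sigma[:K, :K]), 1e-12)
            beta[j] = P / max(np.sum(B[j] ** 2) + np.trace(Sigma[K:, K:]), 1e-12)

        # observation rows: regression of y_t on [x_t; y_{t-1}]
        Mz = np.block([[Exx_cur, Sx_cur_y], [Sx_cur_y.T, Syy]])
        for i in range(P):
            prior = np.concatenate([np.full(K, gamma[i]), np.full(P, delta[i])])
            Sigma = np.linalg.inv(v[i] * Mz + np.diag(prior))
            c_i = np.concatenate([xs[1:].T @ Ycur[:, i], Yprev.T @ Ycur[:, i]])
            mu = v[i] * Sigma @ c_i
            C[i], D[i] = mu[:K], mu[K:]
            sigma_obs[i] = Sigma
            expected_rss = (
                Ycur[:, i] @ Ycur[:, i]
                - 2 * mu @ c_i
                + mu @ Mz @ mu
                + np.trace(Sigma @ Mz)
            )
            v[i] = (T - 1) / max(expected_rss, 1e-12)
            gamma[i] = K / max(np.sum(C[i] ** 2) + np.trace(Sigma[:K, :K]), 1e-12)
            delta[i] = P / max(np.sum(D[i] ** 2) + np.trace(Sigma[K:, K:]), 1e-12)

        _check_finite([A, B, C, D, v, alpha, beta, gamma, delta], iteration)
        if _rel_change(np.concatenate([alpha, beta, gamma, delta, v]), hyper_old) < tol:
            converged = True
            break
    if not converged:
        logger.warning("EM did not converge within %d iterations", max_iter)

    d_se = np.empty((P, P))
    for i in range(P):
        cov = v[i] * sigma_obs[i] @ Mz @ sigma_obs[i]
        d_se[i] = np.sqrt(np.maximum(np.diag(cov)[K:], 1e-300))
    return StateSpaceFit(K, A, B, C, D, alpha, beta, gamma, delta, v, d_se,
                         iteration, converged)


def _fit_var(Y: np.ndarray, max_iter: int, tol: float) -> StateSpaceFit:
    """K=0 reduction: Bayesian ridge VAR(1) with empirical-Bayes precisions."""
    P, T = Y.shape
    Z = Y[:, :-1].T  # (T-1) x P
    targets = Y[:, 1:].T
    M = Z.T @ Z
    delta, v = np.ones(P), np.ones(P)
    D = np.zeros((P, P))
    sigmas = [np.eye(P) for _ in range(P)]
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        hyper_old = np.concatenate([delta, v])
        for i in range(P):
            Sigma = np.linalg.inv(v[i] * M + delta[i] * np.eye(P))
            c_i = Z.T @ targets[:, i]
            mu = v[i] * Sigma @ c_i
            D[i] = mu
            sigmas[i] = Sigma
            expected_rss = (
                targets[:, i] @ targets[:, i] - 2 * mu @ c_i + mu @ M @ mu
                + np.trace(Sigma @ M)
            )
            v[i] = (T - 1) / max(expected_rss, 1e-12)
            delta[i] = P / max(np.sum(mu ** 2) + np.trace(Sigma), 1e-12)
        _check_finite([D, v, delta], iteration)
        if _rel_change(np.concatenate([delta, v]), hyper_old) < tol:
            converged = True
            break
    if not converged:
        logger.warning("EM did not converge within %d iterations", max_iter)
    d_se = np.empty((P, P))
    for i in range(P):
        cov = v[i] * sigmas[i] @ M @ sigmas[i]
        d_se[i] = np.sqrt(np.maximum(np.diag(cov), 1e-300))
    empty = np.zeros((0, 0))
    return StateSpaceFit(
        0, empty, np.zeros((0, P)), np.zeros((P, 0)), D,
        np.ones(0), np.ones(0), np.ones(P), delta, v, d_se,
        iteration, converged,
    )


def _kalman_smoother(Y, A, B, C, D, v):
    """RTS smoother for the feedback model; y_1 is conditioned on, not modeled.

    Returns smoothed means (T x K), covariances (T x K x K) and lag-one cross
    covariances Cov(x_t, x_{t-1}) for t = 2..T ((T-1) x K x K).
    """
    P, T = Y.shape
    K = A.shape[0]
    R = np.diag(1.0 / v)
    I = np.eye(K)

    means = np.zeros((T, K))
    covs = np.zeros((T, K, K))
    pred_means = np.zeros((T, K))
    pred_covs = np.zeros((T, K, K))
    gains = np.zeros((T, K, P))

    means[0], covs[0] = np.zeros(K), I  # x_1 prior; no observation at t=1
    pred_means[0], pred_covs[0] = means[0], covs[0]
    for t in range(1, T):
        m_pred = A @ means[t - 1] + B @ Y[:, t - 1]
        P_pred = A @ covs[t - 1] @ A.T + I
        innov = Y[:, t] - C @ m_pred - D @ Y[:, t - 1]
        S = C @ P_pred @ C.T + R
        gain = np.linalg.solve(S.T, (P_pred @ C.T).T).T
        means[t] = m_pred + gain @ innov
        covs[t] = (I - gain @ C) @ P_pred
        pred_means[t], pred_covs[t], gains[t] = m_pred, P_pred, gain

    xs = np.zeros((T, K))
    Ps = np.zeros((T, K, K))
    xs[-1], Ps[-1] = means[-1], covs[-1]
    Js = np.zeros((T, K, K))
    for t in range(T - 2, -1, -1):
        J = np.linalg.solve(pred_covs[t + 1].T, (covs[t] @ A.T).T).T
        Js[t] = J
        xs[t] = means[t] + J @ (xs[t + 1] - pred_means[t + 1])
        Ps[t] = covs[t] + J @ (Ps[t + 1] - pred_covs[t + 1]) @ J.T

    Pcross = np.zeros((T - 1, K, K))  # Cov(x_t, x_{t-1}) for t = 2..T
    for t in range(1, T):
        Pcross[t - 1] = Ps[t] @ Js[t - 1].T
    return xs, Ps, Pcross


# ---------------------------------------------------------------------------
# Edge thresholding and the assembled result
# ---------------------------------------------------------------------------

def threshold_edges(
    z: np.ndarray, D: np.ndarray, alpha: float = 0.15
) -> List[Tuple[int, int, str]]:
    """Signed directed edges i -> j where |z[j, i]| exceeds the two-sided
    standard-normal quantile for chance-edge probability ``alpha``.

    Edge sign is ``activation`` for a positive coefficient, ``inhibition``
    for a negative one; self-loops are allowed.
    """
    if not 0 < alpha <= 1:
        raise ValidationError(f"alpha must be in (0, 1], got {alpha}")
    quantile = norm.ppf(1 - alpha / 2)
    absz = np.abs(z)
    mask = absz >= quantile if alpha == 1.0 else absz > quantile
    edges = []
    for j, i in zip(*np.nonzero(mask)):
        sign = "activation" if D[j, i] > 0 else "inhibition"
        edges.append((int(i), int(j), sign))
    return sorted(edges)


@dataclass
class DBNResult:
    """Fitted dynamic network: parameters, edge z-scores, thresholded edges."""

    fit: StateSpaceFit
    molecules: List[Node]
    z: np.ndarray
    alpha: float
    adjacency: List[Tuple[Node, Node, str]] = field(default_factory=list)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(alpha=self.alpha, K=self.fit.K)
        for symbol, layer in self.molecules:
            g.add_node(f"{layer}:{symbol}", symbol=symbol, layer=layer)
        index = {m: i for i, m in enumerate(self.molecules)}
        for source, target, sign in self.adjacency:
            i, j = index[source], index[target]
            g.add_edge(
                f"{source[1]}:{source[0]}", f"{target[1]}:{target[0]}",
                sign=sign, z=float(self.z[j, i]), weight=float(self.fit.D[j, i]),
            )
        return g


def infer_network(
    dense: DenseTimeSeries,
    K: Optional[int] = None,
    alpha: float = 0.15,
    max_iter: int = 100,
    tol: float = 1e-3,
    seed: int = 0,
    max_K: int = 5,
    cutoff: float = 0.90,
) -> DBNResult:
    """Full dynamic stage: hidden-dimension selection (when ``K=None``), EM
    fit, z-scores and thresholded signed network."""
    if K is None:
        K = select_hidden_dim(dense, max_K=max_K, cutoff=cutoff)
        logger.info("selected hidden dimension K=%d", K)
    fit = fit_dbn(dense, K, max_iter=max_iter, tol=tol, seed=seed)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(fit.d_se > 0, fit.D / fit.d_se, 0.0)
    edges = threshold_edges(z, fit.D, alpha)
    adjacency = [
        (dense.molecules[i], dense.molecules[j], sign) for i, j, sign in edges
    ]
    return DBNResult(fit, list(dense.molecules), z, alpha, adjacency)


def write_dense_tsv(dense: DenseTimeSeries, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("symbol\tlayer\t" + "\t".join(f"{t:.6g}" for t in dense.grid) + "\n")
        for (symbol, layer), row in zip(dense.molecules, dense.values):
            fh.write(f"{symbol}\t{layer}\t" + "\t".join(f"{x:.12g}" for x in row) + "\n")


def write_network_sif(result: DBNResult, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for source, target, sign in result.adjacency:
            fh.write(f"{source[1]}:{source[0]}\t{sign}\t{target[1]}:{target[0]}\n")
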