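"""Enhanced configuration model (ECM): maximum-entropy null constraining
both the degree and the strength sequence.

The ensemble assigns each node a pair of multipliers (x_i, y_i); for a
node pair (i, j) write u = x_i x_j and z = y_i y_j.  The per-pair weight
law is

    q_ij(0) = (1 - z) / D,     q_ij(w) = u z^w (1 - z) / D  for w >= 1,

with D = 1 - z + u z, so the connection probability is p_ij = u z / D and
the conditional weight given connection is geometric with ratio z.  The
multipliers are fitted so the ensemble reproduces every node's observed
degree and strength in expectation:

    sum_{j != i} p_ij = k_i,      sum_{j != i} p_ij / (1 - z_ij) = s_i.

The multipliers are the unique maximizer of the ensemble's concave
log-likelihood (the model is an exponential family whose sufficient
statistics are exactly the degree and strength sequences), fitted by
quasi-Newton ascent; the per-edge p-value is the geometric tail
P(W_ij >= w) = u z^w / D.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ..graph import WeightedNetwork, edge_key
from ._base import EdgePValues, FilterError

logger = logging.getLogger(__name__)

__all__ = ["ECMParameters", "ecm_fit", "ecm_pvalues", "ECMConvergenceError"]


class ECMConvergenceError(FilterError):
    """The ECM solver failed; carries the last residuals."""

    def __init__(self, message: str, residual_k: float, residual_s: float):
        super().__init__(message)
        self.residual_k = residual_k
        self.residual_s = residual_s


@dataclass
class ECMParameters:
    """Fitted per-node multipliers of the maximum-entropy ensemble.

    ``x`` are the degree multipliers (positive), ``y`` the strength
    multipliers (in (0, 1)); ``residual_k``/``residual_s`` are the largest
    absolute deviations of the ensemble-expected degree and strength from
    their observed values.
    """

    net: WeightedNetwork
    x: dict[str, float]
    y: dict[str, float]
    residual_k: float
    residual_s: float
    iterations: int

    def arrays(self) -> tuple[list[str], np.ndarray, np.ndarray]:
        nodes = self.net.nodes
        return (
            nodes,
            np.array([self.x[n] for n in nodes]),
            np.array([self.y[n] for n in nodes]),
        )


def _expected(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble-expected degree and strength vectors for multipliers x, y."""
    U = np.outer(x, x)
    Z = np.outer(y, y)
    D = 1.0 - Z + U * Z
    P = U * Z / D
    np.fill_diagonal(P, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        W = P / (1.0 - Z)
    np.fill_diagonal(W, 0.0)
    return P.sum(axis=1), W.sum(axis=1)


def ecm_fit(
    net: WeightedNetwork,
    tol: float = 1e-6,
    max_iter: int = 5000,
) -> ECMParameters:
    """Fit the ECM multipliers to a network's degree and strength sequence.

    Maximizes the ensemble log-likelihood (concave in the log-multipliers)
    by L-BFGS-B from the deterministic initialization
    ``x_i = k_i / sqrt(sum k)``, ``y_i = s_i / (1 + sum s)``; at the
    optimum the likelihood gradient — the vector of constraint residuals
    ``k_i - <k_i>``, ``s_i - <s_i>`` — vanishes.  A damped Newton
    iteration with the analytic Hessian (the covariance matrix of the
    sufficient statistics) polishes the warm start to ``tol``.

    Raises
    ------
    FilterError
        If the network has non-integer weights, or a node is adjacent to
        all others (its degree constraint ``sum_j p_ij = n - 1`` cannot be
        met by any finite multipliers — every p_ij is strictly below 1).
    ECMConvergenceError
        If the residuals do not fall below ``tol`` within ``max_iter``
        iterations.
    """
    if not net.has_integer_weights:
        raise FilterError(
            "ecm requires integer weights; run graph.validate_for_method "
            "for scale-and-round guidance"
        )
    nodes = net.nodes
    n = len(nodes)
    if n < 3:
        raise FilterError("ecm needs at least 3 nodes")
    k = np.array([net.degree(v) for v in nodes], dtype=float)
    s = np.array([net.strength(v) for v in nodes], dtype=float)

    saturated = [nodes[i] for i in range(n) if k[i] >= n - 1]
    if saturated:
        raise FilterError(
            "ecm constraints saturated: node(s) adjacent to all others "
            f"({', '.join(saturated)}); sum_j p_ij = n-1 is unattainable "
            "since every p_ij < 1"
        )

    # the ensemble is an exponential family in (ln x, ln y): the observed
    # degrees/strengths are the sufficient statistics, so the multipliers
    # maximize the concave log-likelihood
    #   L = sum_i k_i ln x_i + sum_i s_i ln y_i
    #       + sum_{i<j} [ln(1 - z_ij) - ln D_ij]
    # whose gradient components are exactly the constraint residuals
    # k_i - <k_i> and s_i - <s_i>.  We minimize -L with L-BFGS-B starting
    # from the deterministic point x_i = k_i / sqrt(sum k),
    # y_i = s_i / (1 + sum s); the gradient norm doubles as the residual.
    from scipy.optimize import minimize

    x0 = k / np.sqrt(k.sum())
    y0 = s / (1.0 + s.sum())
    theta0 = np.concatenate([np.log(x0), np.log(y0)])

    def negloglik(theta: np.ndarray) -> tuple[float, np.ndarray]:
        a, b = theta[:n], theta[n:]
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            U = np.exp(a[:, None] + a[None, :])
            Z = np.exp(b[:, None] + b[None, :])
            D = 1.0 - Z + U * Z
            pair = np.log1p(-Z) - np.log(D)
            np.fill_diagonal(pair, 0.0)
            ll = float(k @ a + s @ b + 0.5 * pair.sum())
            P = U * Z / D
            np.fill_diagonal(P, 0.0)
            W = P / (1.0 - Z)
            np.fill_diagonal(W, 0.0)
            grad = np.concatenate([k - P.sum(axis=1), s - W.sum(axis=1)])
        if not np.isfinite(ll) or not np.all(np.isfinite(grad)):
            return np.inf, np.zeros_like(theta)
        return -ll, -grad

    bounds = [(None, None)] * n + [(None, -1e-12)] * n  # keep y < 1
    warmup = min(1500, max_iter)
    res = minimize(
        negloglik,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={
            "maxiter": warmup,
            "maxfun": 4 * warmup,
            "ftol": 1e-18,
            "gtol": 0.1 * tol,
        },
    )
    theta, it, rk, rs, at_bound = _newton_polish(
        k, s, res.x, tol, max_iter - min(warmup, int(res.nit))
    )
    it += int(res.nit)
    x = np.exp(theta[:n])
    y = np.exp(theta[n:])
    if rk > tol or rs > tol:
        if at_bound.any():
            # a strength multiplier pinned at the y -> 1 boundary with a
            # non-vanishing residual means the degree/strength sequence is
            # infeasible for the ensemble: no finite multipliers satisfy
            # the constraints (typically a low-degree node whose strength
            # far exceeds what its neighbors' weight scales support)
            offenders = ", ".join(np.asarray(nodes)[at_bound])
            raise FilterError(
                "ecm constraints saturated: strength constraint of node(s) "
                f"{offenders} unattainable (multiplier at the y=1 boundary; "
                f"residual_k={rk:.3g}, residual_s={rs:.3g})"
            )
        raise ECMConvergenceError(
            f"ecm did not converge (residual_k={rk:.3g}, "
            f"residual_s={rs:.3g}, tol={tol:g})",
            rk,
            rs,
        )

    return ECMParameters(
        net=net,
        x=dict(zip(nodes, x.tolist())),
        y=dict(zip(nodes, y.tolist())),
        residual_k=rk,
        residual_s=rs,
        iterations=it,
    )


def _newton_polish(
    k: np.ndarray,
    s: np.ndarray,
    theta0: np.ndarray,
    tol: float,
    max_steps: int,
) -> tuple[np.ndarray, int, float, float, np.ndarray]:
    """Damped Newton iteration on the stationarity system.

    The residual vector is the gradient of the log-likelihood in
    (ln x, ln y); its Jacobian is the likelihood Hessian, which for this
    exponential family is the covariance matrix of the sufficient
    statistics — closed-form Bernoulli/geometric moments per node pair:

        Cov(1_ij, 1_ij) = p (1 - p)
        Cov(1_ij, w_ij) = <w> (1 - p)
        Cov(w_ij, w_ij) = (p (1 + z) - p^2) / (1 - z)^2

    Returns (theta, steps, residual_k, residual_s, y-at-boundary mask).
    """
    n = len(k)
    b_cap = -1e-12  # keep y < 1
    theta = theta0.copy()
    theta[n:] = np.minimum(theta[n:], b_cap)

    def residual(theta: np.ndarray):
        a, b = theta[:n], theta[n:]
        U = np.exp(a[:, None] + a[None, :])
        Z = np.exp(b[:, None] + b[None, :])
        D = 1.0 - Z + U * Z
        P = U * Z / D
        np.fill_diagonal(P, 0.0)
        W = P / (1.0 - Z)
        np.fill_diagonal(W, 0.0)
        return np.concatenate([k - P.sum(1), s - W.sum(1)]), P, W, Z

    r, P, W, Z = residual(theta)
    steps = 0
    for steps in range(1, max(1, max_steps) + 1):
        rk = float(np.max(np.abs(r[:n])))
        rs = float(np.max(np.abs(r[n:])))
        if rk <= tol and rs <= tol:
            break
        Haa = P * (1.0 - P)
        Hab = W * (1.0 - P)
        Hbb = (P * (1.0 + Z) - P * P) / (1.0 - Z) ** 2
        np.fill_diagonal(Hbb, 0.0)
        H = np.block([[Haa, Hab], [Hab.T, Hbb]])
        # diagonals: each node's stat covaries with all of its own pairs
        idx = np.arange(n)
        H[idx, idx] += Haa.sum(1)
        H[n + idx, n + idx] += Hbb.sum(1)
        H[idx, n + idx] += Hab.sum(1)
        H[n + idx, idx] += Hab.sum(1)
        H[np.arange(2 * n), np.arange(2 * n)] += 1e-12  # near-singular jitter
        try:
            delta = np.linalg.solve(H, r)
        except np.linalg.LinAlgError:
            break
        # backtracking line search on the residual norm
        base = float(np.linalg.norm(r))
        step = 1.0
        for _ in range(40):
            cand = theta + step * delta
            cand[n:] = np.minimum(cand[n:], b_cap)
            with np.errstate(over="ignore", invalid="ignore"):
                r_new, P_new, W_new, Z_new = residual(cand)
            if np.all(np.isfinite(r_new)) and np.linalg.norm(r_new) < base:
                theta, r, P, W, Z = cand, r_new, P_new, W_new, Z_new
                break
            step *= 0.5
        else:
            break  # no descent direction left
    rk = float(np.max(np.abs(r[:n])))
    rs = float(np.max(np.abs(r[n:])))
    at_bound = (theta[n:] >= b_cap - 1e-9) & (np.abs(r[n:]) > tol)
    return theta, steps, rk, rs, at_bound


def ecm_pvalues(net: WeightedNetwork, params: ECMParameters | None = None,
                tol: float = 1e-6, max_iter: int = 5000) -> EdgePValues:
    """ECM p-values: geometric-tail survival of the per-pair weight law.

    ``P(W_ij >= w) = x_i x_j (y_i y_j)^w / (1 - y_i y_j + x_i x_j y_i y_j)``.
    Fits the multipliers first if ``params`` is not supplied.
    """
    if params is None:
        params = ecm_fit(net, tol=tol, max_iter=max_iter)
    if params.net is not net:
        raise FilterError("ecm parameters were fitted on a different network")
    p: dict[tuple[str, str], float] = {}
    for u, v, w in net.edges():
        xu, xv = params.x[u], params.x[v]
        yu, yv = params.y[u], params.y[v]
        z = yu * yv
        uu = xu * xv
        d = 1.0 - z + uu * z
        p[edge_key(u, v)] = float(min(1.0, uu * z ** int(round(w)) / d))
    return EdgePValues(
        net=net,
        method="ecm",
        p=p,
        params={
            "tol": tol,
            "residual_k": params.residual_k,
            "residual_s": params.residual_s,
        },
    )


def ecm_sample_weights(
    params: ECMParameters, rng: np.random.Generator
) -> dict[tuple[str, str], int]:
    """Draw one network from the fitted ensemble (for Monte-Carlo checks).

    Each node pair independently receives an edge with probability
    p_ij = u z / D; a present edge's weight is 1 + Geometric(1 - z).
    """
    nodes, x, y = params.arrays()
    n = len(nodes)
    out: dict[tuple[str, str], int] = {}
    for i in range(n):
        for j in range(i + 1, n):
            z = y[i] * y[j]
            u = x[i] * x[j]
            d = 1.0 - z + u * z
            if rng.random() < u * z / d:
                # conditional weight law P(W = w | edge) = z^(w-1) (1 - z)
                out[edge_key(nodes[i], nodes[j])] = int(rng.geometric(1.0 - z))
    return out
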