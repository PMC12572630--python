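"""Stochastic neighbour embedding (SNE) implemented from first principles.

High-dimensional features are converted to conditional neighbour
probabilities

    p_{j|i} = exp(-||f_i - f_j||^2 / 2 sigma_i^2) / sum_{k != i} exp(...)

with per-point bandwidths sigma_i calibrated by bisection so that the
realized perplexity 2^H(P_i) matches a target.  Low-dimensional coordinates
y_i induce

    q_{j|i} = exp(-||y_i - y_j||^2) / sum_{k != i} exp(-||y_i - y_k||^2)

(Gaussian kernel, fixed unit bandwidth) and are optimized by gradient
descent with momentum on the summed Kullback-Leibler divergence

    C = sum_i KL(P_i || Q_i) = sum_i sum_j p_{j|i} log(p_{j|i} / q_{j|i}).

The default ``variant="gaussian"`` follows these conditional-SNE equations
exactly; ``variant="student-t"`` swaps in the symmetric-affinity, heavy-tail
(1 + ||.||^2)^-1 low-dimensional kernel of t-SNE for users who want the
conventional modern variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "compute_high_dim_affinities",
    "compute_low_dim_affinities",
    "kl_objective",
    "kl_gradient",
    "run_embedding",
    "EmbeddingResult",
]

_EPS = 1e-300


@dataclass
class AffinityP:
    P: np.ndarray
    sigmas: np.ndarray
    perplexity: float


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray            # n x d
    kl_trace: np.ndarray               # objective per iteration
    config: dict = field(default_factory=dict)


def _sq_dists(X: np.ndarray) -> np.ndarray:
    return squareform(pdist(np.asarray(X, float), "sqeuclidean"))


def _row_affinity(d2_row: np.ndarray, beta: float, i: int) -> np.ndarray:
    """Unnormalized then normalized conditional affinities for one point;
    beta = 1 / (2 sigma^2)."""
    w = np.exp(-d2_row * beta)
    w[i] = 0.0
    s = w.sum()
    return w / s if s > 0 else w


def _row_perplexity(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(2.0 ** (-np.sum(nz * np.log2(nz))))


def compute_high_dim_affinities(features: np.ndarray, perplexity: float = 30.0,
                                tol: float = 1e-5,
                                max_bisect: int = 100) -> AffinityP:
    """Conditional affinities P with per-point sigma found by bisection.

    Each row's bandwidth is tuned until 2^entropy matches ``perplexity``
    within ``tol``.  Duplicate points that defeat the bisection are jittered
    with a warning.
    """
    X = np.asarray(features, float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    if not perplexity < n:
        raise ValueError(f"perplexity {perplexity} must be < n = {n}")
    D2 = _sq_dists(X)
    if np.any((D2 + np.eye(n)) == 0):
        warnings.warn("duplicate points detected; adding tiny jitter")
        rng = np.random.default_rng(0)
        X = X + rng.normal(0, 1e-8 * (np.ptp(X) + 1.0), X.shape)
        D2 = _sq_dists(X)
    P = np.zeros((n, n))
    sigmas = np.zeros(n)
    for i in range(n):
        beta, lo, hi = 1.0, 0.0, np.inf
        for _ in range(max_bisect):
            p = _row_affinity(D2[i], beta, i)
            perp = _row_perplexity(p)
            if abs(perp - perplexity) < tol:
                break
            if perp > perplexity:      # too flat -> narrow the kernel
                lo = beta
                beta = beta * 2.0 if hi == np.inf else (beta + hi) / 2.0
            else:
                hi = beta
                beta = (lo + beta) / 2.0
        P[i] = _row_affinity(D2[i], beta, i)
        sigmas[i] = np.sqrt(1.0 / (2.0 * beta))
    return AffinityP(P=P, sigmas=sigmas, perplexity=float(perplexity))


def compute_low_dim_affinities(Y: np.ndarray) -> np.ndarray:
    """Conditional affinities Q from coordinates, unit-bandwidth Gaussian."""
    Y = np.asarray(Y, float)
    if not np.all(np.isfinite(Y)):
        raise ValueError("non-finite coordinates")
    n = Y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    W = np.exp(-_sq_dists(Y))
    np.fill_diagonal(W, 0.0)
    rows = W.sum(axis=1, keepdims=True)
    if np.any(rows == 0):
        raise FloatingPointError(
            "low-dimensional points too dispersed: a Gaussian affinity row "
            "underflowed to zero (optimization diverging?)")
    return W / rows


def kl_objective(P: np.ndarray, Q: np.ndarray) -> float:
    """C = sum_i sum_j p_{j|i} log(p_{j|i} / q_{j|i}); nonnegative, zero iff
    the two conditional distributions agree rowwise."""
    P, Q = np.asarray(P, float), np.asarray(Q, float)
    if P.shape != Q.shape:
        raise ValueError("shape mismatch between P and Q")
    bad = (P > 0) & (Q == 0)
    if np.any(bad):
        raise ValueError("infinite KL divergence: q_(j|i)=0 where p_(j|i)>0")
    mask = P > 0
    return float(np.sum(P[mask] * np.log(P[mask] / Q[mask])))


def kl_gradient(P: np.ndarray, Q: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Analytic gradient of the conditional-SNE objective:

        dC/dy_i = 2 sum_j (p_{j|i} - q_{j|i} + p_{i|j} - q_{i|j}) (y_i - y_j)
    """
    P, Q, Y = (np.asarray(a, float) for a in (P, Q, Y))
    M = (P - Q) + (P - Q).T
    # sum_j M_ij (y_i - y_j) = y_i * rowsum - M @ Y
    return 2.0 * (Y * M.sum(axis=1, keepdims=True) - M @ Y)


def _student_t_q(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    num = 1.0 / (1.0 + _sq_dists(Y))
    np.fill_diagonal(num, 0.0)
    return num / num.sum(), num


def run_embedding(features: np.ndarray, d: int = 3,
                  perplexity: float | None = None,
                  learning_rate: float = 2.0,
                  n_iter: int = 1000,
                  momentum: tuple[float, float] = (0.5, 0.8),
                  momentum_switch: int = 250,
                  variant: str = "gaussian",
                  seed: int = 0) -> EmbeddingResult:
    """Project features to ``d`` dimensions by gradient descent on C.

    Coordinates start from a seeded small-variance Gaussian; the KL
    objective is recorded every iteration.  Default perplexity is
    min(30, (n-1)/3).  Aborts with a diagnostic if the objective diverges.
    """
    X = np.asarray(features, float)
    n = X.shape[0]
    if n < d + 1:
        raise ValueError(f"need at least d+1 = {d + 1} points, got {n}")
    if variant not in ("gaussian", "student-t"):
        raise ValueError(f"unknown variant {variant!r}")
    if perplexity is None:
        perplexity = min(30.0, (n - 1) / 3.0)
    aff = compute_high_dim_affinities(X, perplexity=perplexity)
    P = aff.P
    if variant == "student-t":
        P = (P + P.T) / (2.0 * n)      # symmetrized joint affinities

    def objective_grad(Yc: np.ndarray) -> tuple[float, np.ndarray]:
        if variant == "gaussian":
            Q = compute_low_dim_affinities(Yc)
            return kl_objective(P, np.maximum(Q, _EPS)), kl_gradient(P, Q, Yc)
        Q, num = _student_t_q(Yc)
        Qs = np.maximum(Q, _EPS)
        mask = P > 0
        C = float(np.sum(P[mask] * np.log(P[mask] / Qs[mask])))
        M = (P - Q) * num
        return C, 4.0 * (Yc * M.sum(axis=1, keepdims=True) - M @ Yc)

    rng = np.random.default_rng(seed)
    Y = rng.normal(0.0, 1e-2, (n, d))
    V = np.zeros_like(Y)
    trace = np.empty(n_iter)
    C, G = objective_grad(Y)
    # backtracking safeguard: the Gaussian kernel's repulsion grows with the
    # coordinate scale, so a fixed step can destabilize; steps that would
    # raise C (or underflow Q) are rejected, halving the step scale and
    # resetting momentum
    scale = 1.0
    for it in range(n_iter):
        if not np.isfinite(C):
            raise FloatingPointError(
                f"embedding diverged at iteration {it} (C={C})")
        trace[it] = C
        m = momentum[0] if it < momentum_switch else momentum[1]
        V_cand = m * V - scale * learning_rate * G
        Y_cand = Y + V_cand
        Y_cand = Y_cand - Y_cand.mean(axis=0)
        try:
            C_cand, G_cand = objective_grad(Y_cand)
            accept = np.isfinite(C_cand) and C_cand <= C + 1e-12
        except FloatingPointError:
            accept = False
        if accept:
            Y, V, C, G = Y_cand, V_cand, C_cand, G_cand
            scale = min(scale * 1.1, 10.0)
        else:
            scale = max(scale * 0.5, 1e-9)
            V = np.zeros_like(V)
    return EmbeddingResult(
        coordinates=Y, kl_trace=trace,
        config={"d": d, "perplexity": perplexity, "learning_rate": learning_rate,
                "n_iter": n_iter, "momentum": momentum,
                "momentum_switch": momentum_switch, "variant": variant,
                "seed": seed})
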