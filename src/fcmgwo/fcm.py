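"""Fuzzy c-means (FCM) clustering of vectorized pixel intensities.

FCM assigns every data point a graded membership in each of ``c`` clusters
and alternates two closed-form updates that monotonically decrease the
objective

    J_m = sum_i sum_j u_ij^m * ||x_i - c_j||^2

where ``m > 1`` is the fuzziness exponent, ``u_ij`` the membership of point
``i`` in cluster ``j`` and ``c_j`` the cluster centers.  The alternating
minimizer (optimal memberships for fixed centers, then weighted-mean centers
for fixed memberships) is the classical one; each step is optimal for the
variables it updates, which is what makes the objective trace non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "DegenerateClusterError",
    "FcmConfig",
    "FcmResult",
    "init_membership",
    "fcm_objective",
    "update_memberships",
    "update_centers",
    "run_fcm",
    "memberships_to_csv",
    "memberships_from_csv",
]


class DegenerateClusterError(RuntimeError):
    """A cluster received zero total membership weight and has no center."""


@dataclass(frozen=True)
class FcmConfig:
    """FCM hyper-parameters.

    Defaults follow the segmentation setting this package targets: 3 clusters
    (nucleus / cytoplasm / background), fuzziness 1.5, at most 5 iterations.

    ``init`` selects the initialization: ``"spread"`` places initial centers
    evenly across the per-feature data range (robust on images dominated by
    one intensity population), ``"random"`` draws a random row-stochastic
    membership matrix from ``seed``.
    """

    c: int = 3
    m: float = 1.5
    max_iter: int = 5
    tol: float = 1e-5
    seed: int | None = None
    init: str = "spread"

    def __post_init__(self) -> None:
        if self.c < 1:
            raise ValueError(f"number of clusters must be >= 1, got {self.c}")
        if not self.m > 1:
            raise ValueError(f"fuzziness exponent must be > 1, got {self.m}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")
        if self.tol < 0:
            raise ValueError(f"tol must be >= 0, got {self.tol}")
        if self.init not in ("spread", "random"):
            raise ValueError(f"unknown init {self.init!r}")


@dataclass
class FcmResult:
    centers: np.ndarray          # (c, f)
    memberships: np.ndarray      # (n, c), rows sum to 1
    objective_trace: list[float] = field(default_factory=list)
    iterations_run: int = 0

    @property
    def objective(self) -> float:
        return self.objective_trace[-1]


def as_feature_matrix(data: np.ndarray) -> np.ndarray:
    """Coerce input to a float ``(n, f)`` matrix; 1-D input becomes one feature."""
    X = np.asarray(data, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError(f"expected an (n, f) feature matrix, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    return X


def init_membership(n: int, c: int, seed: int | None = None) -> np.ndarray:
    """Random row-stochastic ``(n, c)`` membership matrix, reproducible by seed."""
    if n < 1 or c < 1:
        raise ValueError(f"n and c must be >= 1, got n={n}, c={c}")
    rng = np.random.default_rng(seed)
    u = rng.random((n, c))
    return u / u.sum(axis=1, keepdims=True)


def _check_membership(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    if u.ndim != 2:
        raise ValueError(f"membership matrix must be 2-D, got shape {u.shape}")
    return u


def fcm_objective(data: np.ndarray, centers: np.ndarray, u: np.ndarray, m: float) -> float:
    """Evaluate J_m = sum_ij u_ij^m ||x_i - c_j||^2."""
    X = as_feature_matrix(data)
    C = as_feature_matrix(centers)
    u = _check_membership(u)
    if u.shape != (X.shape[0], C.shape[0]) or X.shape[1] != C.shape[1]:
        raise ValueError(
            f"inconsistent shapes: data {X.shape}, centers {C.shape}, u {u.shape}"
        )
    d2 = cdist(X, C, "sqeuclidean")
    return float(np.sum(u**m * d2))


def update_memberships(data: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    """Optimal memberships for fixed centers.

    u_ij = 1 / sum_k (d_ij / d_ik)^(2/(m-1)) with Euclidean d.  Computed in
    ratio form on squared distances, which is overflow-safe even for tiny
    distances.  A point coinciding with one or more centers gets its full
    membership split equally among the coincident centers.
    """
    if not m > 1:
        raise ValueError(f"fuzziness exponent must be > 1, got {m}")
    X = as_feature_matrix(data)
    C = as_feature_matrix(centers)
    d2 = cdist(X, C, "sqeuclidean")
    zero = d2 <= 0.0
    hit = zero.any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        # ratios[i, j, k] = (d2_ij / d2_ik)^(1/(m-1)); row-normalized inverse sum
        ratios = (d2[:, :, None] / d2[:, None, :]) ** (1.0 / (m - 1.0))
        u = 1.0 / ratios.sum(axis=2)
    if hit.any():
        u[hit] = zero[hit] / zero[hit].sum(axis=1, keepdims=True)
    return u


def update_centers(data: np.ndarray, u: np.ndarray, m: float) -> np.ndarray:
    """Weighted-mean centers c_j = sum_i u_ij^m x_i / sum_i u_ij^m."""
    X = as_feature_matrix(data)
    u = _check_membership(u)
    if u.shape[0] != X.shape[0]:
        raise ValueError(f"u has {u.shape[0]} rows for {X.shape[0]} points")
    um = u**m
    weights = um.sum(axis=0)
    if np.any(weights <= 0.0):
        dead = np.nonzero(weights <= 0.0)[0].tolist()
        raise DegenerateClusterError(f"cluster(s) {dead} received zero membership weight")
    return (um.T @ X) / weights[:, None]


def _spread_centers(X: np.ndarray, c: int) -> np.ndarray:
    lo, hi = X.min(axis=0), X.max(axis=0)
    if c == 1:
        return ((lo + hi) / 2.0)[None, :]
    return np.linspace(lo, hi, c)


def run_fcm(data: np.ndarray, cfg: FcmConfig) -> FcmResult:
    """Alternate membership and center updates for at most ``cfg.max_iter`` rounds.

    Stops early once the largest center movement between consecutive rounds
    falls below ``cfg.tol``.  The recorded objective trace is non-increasing.
    """
    X = as_feature_matrix(data)
    if cfg.init == "random":
        u = init_membership(X.shape[0], cfg.c, cfg.seed)
        centers = update_centers(X, u, cfg.m)
    else:
        centers = _spread_centers(X, cfg.c)
    trace: list[float] = []
    iterations = 0
    for _ in range(cfg.max_iter):
        u = update_memberships(X, centers, cfg.m)
        new_centers = update_centers(X, u, cfg.m)
        trace.append(fcm_objective(X, new_centers, u, cfg.m))
        iterations += 1
        movement = float(np.max(np.abs(new_centers - centers)))
        centers = new_centers
        if movement < cfg.tol:
            break
    return FcmResult(centers=centers, memberships=u, objective_trace=trace,
                     iterations_run=iterations)


def memberships_to_csv(u: np.ndarray, path) -> None:
    """Write an (n, c) membership matrix as CSV with cluster-id column headers."""
    u = _check_membership(u)
    pd.DataFrame(u, columns=[str(j) for j in range(u.shape[1])]).to_csv(path, index=False)


def memberships_from_csv(path) -> np.ndarray:
    return pd.read_csv(path).to_numpy(dtype=float)
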