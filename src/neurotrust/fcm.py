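"""Fuzzy C-means clustering and scatter-matrix cluster separability.

A standard alternating-optimization fuzzy C-means (fuzzifier m, Euclidean
distances): memberships u_ik ∝ d_ik^(−2/(m−1)) normalized per sample,
centers are membership-weighted means, iterate until the membership change
falls below tolerance. Hard assignments take the maximum membership.

Cluster quality is scored by the scatter-ratio criterion

    J = tr(S_W⁻¹ S_B),

with S_W the pooled within-cluster scatter and S_B the between-cluster
scatter of the hard assignments; larger J means better-separated clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)


def fuzzy_cmeans(
    X: np.ndarray,
    n_clusters: int = 2,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Run fuzzy C-means; returns (centers, memberships).

    Memberships have shape (n_samples, n_clusters) and row-sum to 1.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < n_clusters:
        raise ValueError("fewer samples than clusters")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    rng = np.random.default_rng(seed)
    U = rng.dirichlet(np.ones(n_clusters), size=n)
    for _ in range(max_iter):
        Um = U**m
        centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=-1)
        d2 = np.maximum(d2, 1e-300)
        inv = d2 ** (-1.0 / (m - 1.0))  # d^{-2/(m-1)}
        U_new = inv / inv.sum(axis=1, keepdims=True)
        shift = np.abs(U_new - U).max()
        U = U_new
        if shift < tol:
            break
    Um = U**m
    centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
    return centers, U


def scatter_matrices(X: np.ndarray, assignments: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within-cluster scatter S_W and between-cluster scatter S_B."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    p = X.shape[1]
    S_W = np.zeros((p, p))
    S_B = np.zeros((p, p))
    for c in np.unique(assignments):
        Xc = X[assignments == c]
        mc = Xc.mean(axis=0)
        D = Xc - mc
        S_W += D.T @ D
        dm = (mc - mu)[:, None]
        S_B += len(Xc) * (dm @ dm.T)
    return S_W, S_B


def separability_criterion(X: np.ndarray, assignments: np.ndarray) -> float:
    """J = tr(S_W⁻¹ S_B); ridge-regularizes a singular S_W (logged)."""
    S_W, S_B = scatter_matrices(X, assignments)
    try:
        return float(np.trace(np.linalg.solve(S_W, S_B)))
    except np.linalg.LinAlgError:
        eps = 1e-8 * max(np.trace(S_W) / S_W.shape[0], 1.0)
        logger.warning("singular within-cluster scatter; applying ridge %.3g", eps)
        return float(np.trace(np.linalg.solve(S_W + eps * np.eye(S_W.shape[0]), S_B)))


@dataclass
class ClusterReport:
    """Fuzzy C-means validation of a labelled feature subset."""

    cluster_accuracy: float      # percent, best label matching
    J: float                     # scatter separability criterion
    memberships: np.ndarray      # n_samples × n_clusters, rows sum to 1
    assignments: np.ndarray      # hard cluster index per sample


def fuzzy_cmeans_validate(
    X,
    y,
    features: list[str] | None = None,
    n_clusters: int = 2,
    seed: int = 0,
    m: float = 2.0,
) -> ClusterReport:
    """Cluster a (z-scored) feature subset and score agreement with labels.

    Hard assignments come from the maximum membership; clusters are matched
    to labels by the permutation maximizing accuracy. J is computed from the
    hard assignments on the standardized features.
    """
    if isinstance(X, pd.DataFrame):
        Xv = X[features].to_numpy(dtype=float) if features else X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
    y = np.asarray(y)
    sd = Xv.std(axis=0)
    Xs = (Xv - Xv.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    _, U = fuzzy_cmeans(Xs, n_clusters=n_clusters, m=m, seed=seed)
    hard = U.argmax(axis=1)
    classes = pd.unique(y)
    # optimal cluster-to-class matching (Hungarian; reduces to the best of
    # two permutations when n_clusters = 2)
    conf = np.zeros((n_clusters, len(classes)))
    for ci in range(n_clusters):
        for li, lab in enumerate(classes):
            conf[ci, li] = np.sum((hard == ci) & (y == lab))
    rows, cols = linear_sum_assignment(-conf)
    correct = conf[rows, cols].sum()
    accuracy = 100.0 * correct / len(y)
    J = separability_criterion(Xs, hard)
    return ClusterReport(cluster_accuracy=float(accuracy), J=J, memberships=U, assignments=hard)
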