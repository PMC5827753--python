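"""Kernel-target alignment (KTA) feature weighting and selection.

Features are z-scored and combined into a weighted linear kernel
K(w) = Σ_m w_m x_m x_mᵀ with non-negative weights. The centred alignment
between K(w) and the ideal label kernel y yᵀ,

    A(w) = ⟨K_c(w), Y_c⟩_F / (‖K_c(w)‖_F ‖Y_c‖_F),

is maximized by projected gradient ascent (clip to w ≥ 0, renormalize to
unit L2 norm; A is scale-invariant in w so the norm is a reporting
convention). Because the columns are centred, A has the closed form
(aᵀw)/(‖ỹ‖²√(wᵀGw)) with a_m = (x_mᵀỹ)², G_ml = (x_mᵀx_l)² and
ỹ = y − ȳ, which makes the exact gradient cheap. Backtracking on the step
size guarantees the alignment never decreases across iterations.

Features are ranked by descending weight. Selection applies greedy
correlation suppression: a candidate whose absolute Pearson correlation
with an already selected feature exceeds a threshold is skipped, so only
one of a pair of (near-)duplicated informative features is selected —
alignment itself is exactly indifferent to how weight splits across
duplicates, so the ranking alone cannot break such ties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class KTAResult:
    """Weights, ranking and selection from one KTA optimization."""

    weights: pd.Series          # all features, canonical column order
    ranked: list[str]           # all features by descending weight
    selected: list[str]         # top n_select after correlation suppression
    alignment: float            # final centred alignment value
    history: np.ndarray         # alignment per accepted iteration (non-decreasing)
    n_iter: int
    converged: bool


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score columns; constant columns become all-zero (flagged)."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    constant = sd == 0
    sd_safe = np.where(constant, 1.0, sd)
    return (X - mu) / sd_safe, constant


def kta_rank_features(
    X,
    y,
    n_select: int | None = None,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    corr_threshold: float = 0.95,
) -> KTAResult:
    """Weight features by centred kernel-target alignment and select the top set.

    Parameters
    ----------
    X : DataFrame or array, shape (n, p)
    y : binary labels (any two values)
    n_select : number of features to select (default: all, ranked)
    seed : seeds the tiny symmetric-breaking jitter on the initial weights
    corr_threshold : |r| above which a lower-weighted near-duplicate of an
        already selected feature is skipped during selection
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(Xv.shape[1])]
    if np.isnan(Xv).any():
        raise ValueError("missing values in active feature columns")
    classes = pd.unique(np.asarray(y))
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    if len(classes) > 2:
        raise ValueError("KTA selection expects binary labels")
    yv = np.where(np.asarray(y) == classes[0], 1.0, -1.0)
    n, p = Xv.shape
    if n_select is None:
        n_select = p
    if n_select < 1:
        raise ValueError("n_select must be >= 1")

    Xs, constant = _standardize(Xv)
    y_c = yv - yv.mean()
    a = (Xs.T @ y_c) ** 2                     # per-feature alignment numerators
    G = (Xs.T @ Xs) ** 2                      # kernel Gram of rank-1 terms
    y_norm2 = float(y_c @ y_c)

    def alignment(w: np.ndarray) -> float:
        denom = np.sqrt(w @ G @ w)
        if denom == 0:
            return 0.0
        return float((a @ w) / (y_norm2 * denom))

    rng = np.random.default_rng(seed)
    w = a / np.linalg.norm(a) if np.linalg.norm(a) > 0 else np.full(p, 1 / np.sqrt(p))
    w = w + rng.uniform(0, 1e-3, size=p)
    w[constant] = 0.0
    w = np.clip(w, 0.0, None)
    w /= np.linalg.norm(w)

    history = [alignment(w)]
    step = 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Gw = G @ w
        wGw = float(w @ Gw)
        grad = a / (y_norm2 * np.sqrt(wGw)) - (a @ w) * Gw / (y_norm2 * wGw**1.5)
        grad[constant] = 0.0
        improved = False
        trial_step = step
        for _ in range(40):
            cand = np.clip(w + trial_step * grad, 0.0, None)
            norm = np.linalg.norm(cand)
            if norm == 0:
                trial_step /= 2
                continue
            cand /= norm
            val = alignment(cand)
            if val >= history[-1] - 1e-15:
                improved = True
                break
            trial_step /= 2
        if not improved:
            converged = True
            break
        w = cand
        step = trial_step * 2
        history.append(val)
        if len(history) > 1 and history[-1] - history[-2] < tol:
            converged = True
            break

    weights = pd.Series(w, index=names)
    order = weights.sort_values(ascending=False, kind="stable").index.tolist()
    ranked = [f for f in order if not constant[names.index(f)]] + [
        f for f in order if constant[names.index(f)]
    ]

    # greedy correlation suppression for the selected subset
    selected: list[str] = []
    skipped: list[str] = []
    col = {name: Xs[:, i] for i, name in enumerate(names)}
    for f in ranked:
        if len(selected) >= n_select:
            break
        if constant[names.index(f)]:
            continue
        dup = False
        for g in selected:
            denom = np.linalg.norm(col[f]) * np.linalg.norm(col[g])
            if denom == 0:
                continue
            r = float(col[f] @ col[g] / denom)
            if abs(r) > corr_threshold:
                dup = True
                break
        (skipped if dup else selected).append(f)
    for f in skipped:                       # backfill if suppression exhausted the pool
        if len(selected) >= n_select:
            break
        selected.append(f)

    return KTAResult(
        weights=weights,
        ranked=ranked,
        selected=selected[:n_select],
        alignment=history[-1],
        history=np.asarray(history),
        n_iter=it,
        converged=converged,
    )
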