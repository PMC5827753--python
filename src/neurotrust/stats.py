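"""Group statistics on trust features.

Welch two-sample t-tests with Bonferroni correction across the tested
feature set (group sizes are unequal, 63/24 and 43/40, so pooled-variance
tests are avoided), Pearson correlations between key and probe features at
95% confidence, and a 2-component PCA projection of z-scored features for
plotting the classified groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

#: Corrected-p significance tiers and their star flags.
SIGNIFICANCE_TIERS = ((1e-4, "****"), (1e-3, "***"), (0.05, "*"))


@dataclass
class TTestResult:
    t: float
    p: float
    p_corrected: float
    stars: str

    @property
    def significant(self) -> bool:
        return self.stars != ""


def _stars(p_corrected: float) -> str:
    for threshold, flag in SIGNIFICANCE_TIERS:
        if p_corrected <= threshold:
            return flag
    return ""


def group_ttest(values, labels, n_tests: int = 1) -> TTestResult:
    """Welch two-sample t-test with Bonferroni correction over ``n_tests``.

    Degenerate input (zero variance in both groups with equal means) yields
    t = 0, p = 1 rather than an error.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = pd.unique(labels)
    if len(classes) != 2:
        raise ValueError("exactly two groups required")
    a = values[labels == classes[0]]
    b = values[labels == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two samples")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, p=1.0, p_corrected=1.0, stars="")
        return TTestResult(t=np.inf, p=0.0, p_corrected=0.0, stars="****")
    t, p = sst.ttest_ind(a, b, equal_var=False)
    p_corr = min(1.0, float(p) * n_tests)
    return TTestResult(t=float(t), p=float(p), p_corrected=p_corr, stars=_stars(p_corr))


def ttest_table(X: pd.DataFrame, y, features: list[str] | None = None) -> pd.DataFrame:
    """Per-feature group means ± SE with Welch t and Bonferroni-corrected p.

    Mirrors the published key-feature tables: one row per feature, group
    mean and standard error for each label, t, raw and corrected p, stars.
    """
    features = list(features) if features is not None else list(X.columns)
    y = np.asarray(y)
    classes = list(pd.unique(y))
    rows = []
    for f in features:
        v = X[f].to_numpy(dtype=float)
        res = group_ttest(v, y, n_tests=len(features))
        row: dict[str, object] = {"feature": f}
        for cls in classes:
            grp = v[y == cls]
            row[f"mean_{cls}"] = grp.mean()
            row[f"se_{cls}"] = grp.std(ddof=1) / np.sqrt(len(grp))
        row.update(t=res.t, p=res.p, p_corrected=res.p_corrected, stars=res.stars)
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")


def key_feature_correlations(
    X: pd.DataFrame,
    key_features: list[str],
    probe_features: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson r and p for every (key, probe) pair; keep pairs with p < alpha.

    Constant columns cannot be correlated and are skipped with a log note.
    """
    rows = []
    for key in key_features:
        for probe in probe_features:
            if key == probe:
                continue
            a = X[key].to_numpy(dtype=float)
            b = X[probe].to_numpy(dtype=float)
            if a.std() == 0 or b.std() == 0:
                logger.warning("skipping constant column in pair (%s, %s)", key, probe)
                continue
            r, p = sst.pearsonr(a, b)
            if p < alpha:
                rows.append(
                    {"key_feature": key, "probe_feature": probe, "r": float(r), "p": float(p)}
                )
    return pd.DataFrame(rows, columns=["key_feature", "probe_feature", "r", "p"])


def pca_project(X: pd.DataFrame, features: list[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Project z-scored features onto the top-2 principal components.

    Returns (coordinates (n, 2), explained variance ratios). Rank-1 data
    gets a zeroed second component (logged).
    """
    if isinstance(X, pd.DataFrame):
        Xv = X[list(features)].to_numpy(dtype=float) if features else X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
    if Xv.shape[1] < 2:
        raise ValueError("PCA projection needs at least two features")
    sd = Xv.std(axis=0)
    Xs = (Xv - Xv.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    rank = np.linalg.matrix_rank(Xs)
    if rank < 2:
        logger.warning("data rank < 2; second component zeroed")
        pca = PCA(n_components=1)
        c1 = pca.fit_transform(Xs)
        coords = np.hstack([c1, np.zeros_like(c1)])
        ratios = np.array([float(pca.explained_variance_ratio_[0]), 0.0])
        return coords, ratios
    pca = PCA(n_components=2)
    coords = pca.fit_transform(Xs)
    return coords, pca.explained_variance_ratio_
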