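"""Trust classification model, statsmodels-style.

:class:`TrustModel` wraps a feature table plus labels; :meth:`TrustModel.fit`
runs KTA feature selection, the dimension sweep, cross-validated linear-SVM
evaluation and fuzzy C-means cluster validation, returning a
:class:`TrustResults` that carries the estimates and renders a summary table.

Example
-------
>>> from neurotrust.synthetic import uva_group_spec, generate_feature_dataset
>>> from neurotrust.model import TrustModel
>>> df = generate_feature_dataset(uva_group_spec(), seed=0)
>>> res = TrustModel.from_dataframe(df).fit(seed=0)
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crossval import SweepResult, SVMReport, evaluate_svm, sweep_dimension
from .fcm import ClusterReport, fuzzy_cmeans_validate
from .feature_names import ALL_FEATURE_NAMES
from .kta import KTAResult, kta_rank_features
from .stats import key_feature_correlations, pca_project, ttest_table


class TrustModel:
    """Binary trust classifier over a named feature table.

    Parameters
    ----------
    X : DataFrame, one row per recording, columns named features
    y : binary trust labels aligned with the rows
    task : optional per-row task identifiers (e.g. 'UVA'/'LND') used by the
        complexity-contrast experiment
    """

    def __init__(self, X: pd.DataFrame, y, task=None):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame with named feature columns")
        self.X = X.copy()
        self.y = np.asarray(y)
        if len(self.y) != len(self.X):
            raise ValueError("label length mismatch")
        if len(pd.unique(self.y)) != 2:
            raise ValueError("trust classification requires exactly two label values")
        self.task = None if task is None else np.asarray(task)
        # MW/E slots may be absent; drop all-missing columns from the active set
        missing = [c for c in self.X.columns if self.X[c].isna().all()]
        if missing:
            self.X = self.X.drop(columns=missing)
        if self.X.isna().any().any():
            raise ValueError("feature table has partially missing columns")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_col: str = "label",
        task_col: str | None = "task",
        feature_cols: list[str] | None = None,
    ) -> "TrustModel":
        """Build from a table carrying feature, label (and task) columns."""
        if label_col not in df.columns:
            raise KeyError(f"label column {label_col!r} missing")
        if feature_cols is None:
            feature_cols = [c for c in df.columns if c in ALL_FEATURE_NAMES]
            if not feature_cols:
                feature_cols = [c for c in df.columns if c not in (label_col, task_col)]
        task = df[task_col].to_numpy() if task_col and task_col in df.columns else None
        return cls(df[feature_cols], df[label_col].to_numpy(), task=task)

    def fit(
        self,
        n_select: int | str = "auto",
        cv: str = "loocv",
        max_dim: int = 15,
        seed: int = 0,
        selection_mode: str = "global",
    ) -> "TrustResults":
        """Select features, sweep the dimension and evaluate the classifier.

        ``n_select='auto'`` takes the sweep optimum (smallest dimension at
        maximum accuracy); an integer fixes the key-feature count directly.
        """
        kta = kta_rank_features(self.X, self.y, n_select=min(max_dim, self.X.shape[1]), seed=seed)
        sweep = sweep_dimension(
            self.X, self.y, cv=cv, max_dim=max_dim, seed=seed, selection_mode=selection_mode
        )
        n_key = sweep.optimum if n_select == "auto" else int(n_select)
        selected = sweep.ranked[:n_key]
        loocv = evaluate_svm(self.X, self.y, selected, cv="loocv", seed=seed)
        kfold = evaluate_svm(self.X, self.y, selected, cv="10fold", seed=seed)
        cluster = fuzzy_cmeans_validate(self.X, self.y, selected, seed=seed)
        tstats = ttest_table(self.X, self.y, selected)
        return TrustResults(
            model=self,
            kta=kta,
            sweep=sweep,
            selected_features=selected,
            loocv=loocv,
            kfold=kfold,
            cluster=cluster,
            ttests=tstats,
            seed=seed,
        )

    def complexity_contrast(
        self, features: list[str], cv: str = "loocv", seed: int = 0
    ) -> tuple[SVMReport, SVMReport]:
        """Classify the same feature subset against trust and task labels.

        Returns (trust_report, complexity_report); requires task labels.
        """
        if self.task is None:
            raise ValueError("task labels are required for the complexity contrast")
        trust_rep = evaluate_svm(self.X, self.y, features, cv=cv, seed=seed)
        task_rep = evaluate_svm(self.X, self.task, features, cv=cv, seed=seed)
        return trust_rep, task_rep


@dataclass
class TrustResults:
    """Fitted trust-classification results.

    Attributes mirror the published reporting: ranked key features with KTA
    weights, the accuracy-vs-dimension curve, LOOCV and 10-fold accuracy and
    F-score, fuzzy C-means cluster accuracy with the scatter criterion J,
    and the per-feature group statistics.
    """

    model: TrustModel
    kta: KTAResult
    sweep: SweepResult
    selected_features: list[str]
    loocv: SVMReport
    kfold: SVMReport
    cluster: ClusterReport
    ttests: pd.DataFrame
    seed: int
    extras: dict = field(default_factory=dict)

    @property
    def accuracy_curve(self) -> dict[int, float]:
        return self.sweep.curve

    @property
    def optimum_dimension(self) -> int:
        return self.sweep.optimum

    def feature_weights(self) -> pd.Series:
        """KTA weights of the selected features, descending."""
        return self.kta.weights[self.selected_features]

    def correlations(self, probe_features: list[str]) -> pd.DataFrame:
        """Significant Pearson correlations of key vs probe features."""
        return key_feature_correlations(self.model.X, self.selected_features, probe_features)

    def pca_coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        return pca_project(self.model.X, self.selected_features)

    def summary(self) -> str:
        w = self.feature_weights()
        lines = [
            "Trust classification results",
            "=" * 60,
            f"samples: {len(self.model.y)}   features: {self.model.X.shape[1]}",
            f"optimum dimension (sweep {min(self.sweep.curve)}..{max(self.sweep.curve)}): "
            f"{self.optimum_dimension}",
            f"LOOCV accuracy: {self.loocv.accuracy:6.2f}%   F-score: {self.loocv.f_score:6.2f}%",
            f"{self.kfold.cv_scheme} accuracy: {self.kfold.accuracy:6.2f}%   "
            f"F-score: {self.kfold.f_score:6.2f}%",
            f"fuzzy C-means accuracy: {self.cluster.cluster_accuracy:6.2f}%   "
            f"J = {self.cluster.J:.2f}",
            "-" * 60,
            "selected features (descending KTA weight):",
        ]
        for name in self.selected_features:
            stars = self.ttests.loc[name, "stars"] if name in self.ttests.index else ""
            lines.append(f"  {name:<10s} weight {w[name]:.4f}  p_corr "
                         f"{self.ttests.loc[name, 'p_corrected']:.3g} {stars}")
        return "\n".join(lines)

    # ---- plotting ---------------------------------------------------------

    def plot_accuracy_curve(self, ax=None):
        """Accuracy vs number of selected features."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        d = sorted(self.sweep.curve)
        ax.plot(d, [self.sweep.curve[k] for k in d], marker="o")
        ax.axvline(self.optimum_dimension, ls="--", color="grey")
        ax.set_xlabel("number of selected features")
        ax.set_ylabel(f"{self.sweep.cv_scheme} accuracy (%)")
        return ax

    def plot_pca(self, ax=None):
        """Samples on the first two principal components, coloured by label."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        coords, ratios = self.pca_coordinates()
        for lab in pd.unique(self.model.y):
            sel = self.model.y == lab
            ax.scatter(coords[sel, 0], coords[sel, 1], label=str(lab), alpha=0.7)
        ax.set_xlabel(f"PC1 ({100 * ratios[0]:.0f}%)")
        ax.set_ylabel(f"PC2 ({100 * ratios[1]:.0f}%)")
        ax.legend()
        return ax
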