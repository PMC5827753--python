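"""Reproducible simulation experiments over the calibrated group specs.

These are the study-level analogues run by the acceptance script and the
acceptance tests: generate feature datasets at the published group sizes,
classify with the key features under 10-fold CV and LOOCV, average over a
fixed number of dataset seeds, and (optionally) sweep the feature dimension
to locate the optimum key-feature count. Seeds for the individual datasets
are derived deterministically from the base seed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .crossval import evaluate_svm, sweep_dimension
from .feature_names import KEY_FEATURES_LND
from .model import TrustModel
from .synthetic import (
    GroupSpec,
    combined_trust_complexity_dataset,
    generate_feature_dataset,
    lnd_group_spec,
    uva_group_spec,
)

_SEED_STRIDE = 7919  # prime stride keeps derived seeds distinct and < 2**31


def _derived_seed(base: int, i: int) -> int:
    return int((base + _SEED_STRIDE * (i + 1)) % (2**31))


@dataclass
class TrustExperimentReport:
    """Aggregated classification results for one task's synthetic analogue."""

    task: str
    n_samples: int
    key_features: list[str]
    acc_kfold: float            # mean 10-fold accuracy (%) over seeds
    acc_loocv: float            # mean LOOCV accuracy (%) over seeds
    f_kfold: float
    f_loocv: float
    per_seed_kfold: list[float] = field(default_factory=list)
    per_seed_loocv: list[float] = field(default_factory=list)
    optima: list[int] = field(default_factory=list)
    modal_optimum: int | None = None


def run_trust_experiment(
    task: str = "UVA",
    seed: int = 0,
    n_seeds: int = 10,
    sweep: bool = False,
    max_dim: int = 15,
) -> TrustExperimentReport:
    """Synthetic trust-classification experiment for one task.

    For each of ``n_seeds`` derived dataset seeds, draw the two-group table
    at the published sizes and score a linear SVM on the task's key-feature
    columns under stratified 10-fold CV and LOOCV; report mean accuracies.
    With ``sweep=True`` additionally run the KTA dimension sweep (d = 2..
    ``max_dim``, LOOCV) per seed and report the modal optimum dimension.
    """
    spec: GroupSpec = uva_group_spec() if task.upper() == "UVA" else lnd_group_spec()
    keys = list(spec.key_features)
    accs_k, accs_l, fs_k, fs_l, optima = [], [], [], [], []
    for i in range(n_seeds):
        ds_seed = _derived_seed(seed, i)
        df = generate_feature_dataset(spec, seed=ds_seed)
        model = TrustModel.from_dataframe(df)
        rep_k = evaluate_svm(model.X, model.y, keys, cv="10fold", seed=ds_seed)
        rep_l = evaluate_svm(model.X, model.y, keys, cv="loocv", seed=ds_seed)
        accs_k.append(rep_k.accuracy)
        accs_l.append(rep_l.accuracy)
        fs_k.append(rep_k.f_score)
        fs_l.append(rep_l.f_score)
        if sweep:
            sw = sweep_dimension(model.X, model.y, cv="loocv", max_dim=max_dim, seed=ds_seed)
            optima.append(sw.optimum)
    modal = Counter(optima).most_common(1)[0][0] if optima else None
    return TrustExperimentReport(
        task=spec.task,
        n_samples=spec.n_trustworthy + spec.n_concerning,
        key_features=keys,
        acc_kfold=float(np.mean(accs_k)),
        acc_loocv=float(np.mean(accs_l)),
        f_kfold=float(np.mean(fs_k)),
        f_loocv=float(np.mean(fs_l)),
        per_seed_kfold=accs_k,
        per_seed_loocv=accs_l,
        optima=optima,
        modal_optimum=modal,
    )


@dataclass
class ContrastReport:
    """Trust-vs-complexity classification contrast on the pooled table."""

    trust_accuracy: float
    trust_f_score: float
    complexity_accuracy: float
    complexity_f_score: float
    n_samples: int

    @property
    def gap(self) -> float:
        return self.trust_accuracy - self.complexity_accuracy


def run_complexity_contrast(seed: int = 0, cv: str = "loocv") -> ContrastReport:
    """Classify the pooled two-task table by trust and by task complexity.

    Uses the nine complex-task key features for both classifications, as in
    the published combined-data analysis. On the synthetic table the
    features track trust only, so complexity accuracy sits at chance.
    """
    df = combined_trust_complexity_dataset(seed=seed)
    model = TrustModel.from_dataframe(df)
    trust_rep, task_rep = model.complexity_contrast(list(KEY_FEATURES_LND), cv=cv, seed=seed)
    return ContrastReport(
        trust_accuracy=trust_rep.accuracy,
        trust_f_score=trust_rep.f_score,
        complexity_accuracy=task_rep.accuracy,
        complexity_f_score=task_rep.f_score,
        n_samples=len(df),
    )
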