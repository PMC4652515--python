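"""Cross-validated classification of cells from selected k-mer features.

The harness wraps two standard learners — a linear-kernel maximum-margin
classifier (SVM) and a CART-style decision tree, both with library
defaults — in replicated stratified k-fold cross-validation. The reported
error is the misclassification rate averaged over held-out folds, then
summarized (min/median/mean/max/sd) over replicates. Stratified folds keep
imbalanced designs (e.g. 3:1 primary:metastatic) valid; an optional
subsampling step balances classes before fitting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .matrix import AbundanceMatrix
from .select import as_label_series

CLASSIFIERS = ("svm", "tree")


@dataclass
class CVReport:
    classifier: str
    n_folds: int
    n_replicates: int
    errors: list[float]
    summary: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if any(not 0.0 <= e <= 1.0 for e in self.errors):
            raise ValueError("errors must be rates in [0, 1]")
        if not self.summary:
            self.summary = summarize_errors(self.errors)

    def to_json(self) -> str:
        return json.dumps(
            {
                "classifier": self.classifier,
                "n_folds": self.n_folds,
                "n_replicates": self.n_replicates,
                "errors": self.errors,
                "summary": self.summary,
            },
            indent=2,
        )

    def to_tsv_row(self) -> str:
        s = self.summary
        return (
            f"{self.classifier}\t{s['min']:.4g}\t{s['median']:.4g}\t"
            f"{s['mean']:.4g}\t{s['max']:.4g}\t{s['sd']:.4g}"
        )


def summarize_errors(errors: list[float]) -> dict[str, float]:
    arr = np.asarray(errors, dtype=np.float64)
    return {
        "min": float(arr.min()),
        "median": float(np.median(arr)),
        "mean": float(arr.mean()),
        "max": float(arr.max()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
    }


def _make_model(classifier: str, random_state: int):
    if classifier == "svm":
        return SVC(kernel="linear")
    if classifier == "tree":
        return DecisionTreeClassifier(random_state=random_state)
    raise ValueError(f"unknown classifier {classifier!r}; choose {CLASSIFIERS}")


def crossval_classify(
    a: AbundanceMatrix,
    labels,
    classifier: str = "svm",
    n_folds: int = 10,
    n_replicates: int = 10,
    seed: int | None = None,
) -> CVReport:
    """Replicated stratified k-fold CV; per-replicate error is the mean
    held-out misclassification rate across folds."""
    if a.n_kmers < 1:
        raise ValueError("feature matrix has no k-mers (empty selection?)")
    series = as_label_series(labels, a.samples)
    y = series.to_numpy()
    counts = series.value_counts()
    if (counts < n_folds).any():
        small = counts[counts < n_folds]
        raise ValueError(
            f"class(es) smaller than n_folds={n_folds}: "
            f"{small.to_dict()}; lower n_folds"
        )
    X = a.values.T  # samples x features
    root = np.random.default_rng(seed)
    errors = []
    for rep in range(n_replicates):
        rep_seed = int(root.integers(0, 2**31 - 1))
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=rep_seed)
        fold_errors = []
        for train, test in skf.split(X, y):
            model = _make_model(classifier, rep_seed)
            model.fit(X[train], y[train])
            pred = model.predict(X[test])
            fold_errors.append(float(np.mean(pred != y[test])))
        errors.append(float(np.mean(fold_errors)))
    return CVReport(classifier=classifier, n_folds=n_folds,
                    n_replicates=n_replicates, errors=errors)


def balance_by_subsampling(
    a: AbundanceMatrix,
    labels,
    seed: int | None = None,
) -> tuple[AbundanceMatrix, "np.ndarray"]:
    """Downsample the majority class uniformly without replacement to the
    minority class size; returns the column-subset matrix and its aligned
    label Series."""
    series = as_label_series(labels, a.samples)
    classes = series.unique()
    if len(classes) != 2:
        raise ValueError("balancing expects exactly 2 classes")
    counts = series.value_counts()
    minority = counts.idxmin()
    n_keep = int(counts.min())
    rng = np.random.default_rng(seed)
    keep = []
    for cls in classes:
        members = [s for s in a.samples if series[s] == cls]
        if cls == minority or len(members) == n_keep:
            keep.extend(members)
        else:
            chosen = rng.choice(len(members), size=n_keep, replace=False)
            keep.extend(members[i] for i in sorted(chosen))
    keep = [s for s in a.samples if s in set(keep)]  # preserve column order
    return a.subset_samples(keep), series.loc[keep]
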