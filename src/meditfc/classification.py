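"""Cross-validated group classification on connectivity feature tables.

Six classifier families are compared — decision tree (DT), linear
discriminant analysis (LDA), logistic regression (LR), RBF support
vector machine (SVM), k-nearest neighbors (KNN) and a bagged-tree
ensemble — on the two contrasts LTM vs NM and STM vs NM, with 10-fold
cross-validated accuracy as the headline metric.

The classification sample is one (subject, epoch) row. Because epochs
of one subject are strongly dependent, folds are stratified at the
*subject* level by default: all epochs of a subject share a fold, so no
subject appears in both a training and a test split. An epoch-level
fold mode is available for comparison; it is optimistic because it lets
a classifier memorize subjects. With fewer than ``n_folds`` subjects the
subject-level scheme is impossible and the epoch-level fallback is used
with an explicit leakage warning.

Hyperparameters are fixed and documented rather than tuned: the feature
space is 16-dimensional and small-sample, so defaults of the textbook
form of each family are used throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import BaggingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as sk_confusion
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .preprocessing import DEFAULT_BANDS
from .synthetic import GROUPS

CLASSIFIER_NAMES: tuple[str, ...] = ("DT", "LDA", "LR", "SVM", "KNN", "Ensemble")

#: States entering the state-wise comparison grid (post is recorded but
#: not part of the default classification grid; pass it explicitly to
#: include it).
DEFAULT_STATEWISE_STATES: tuple[str, ...] = ("baseline", "meditation", "transmission")

COMPARISONS: tuple[tuple[str, str], ...] = (("LTM", "NM"), ("STM", "NM"))


def make_classifier(name: str, seed: int):
    """One classifier instance with the package's fixed hyperparameters."""
    if name == "DT":
        return DecisionTreeClassifier(max_depth=5, random_state=seed)
    if name == "LDA":
        return LinearDiscriminantAnalysis()
    if name == "LR":
        return LogisticRegression(max_iter=2000)
    if name == "SVM":
        return SVC(kernel="rbf", C=1.0, gamma="scale")
    if name == "KNN":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "Ensemble":
        return BaggingClassifier(
            DecisionTreeClassifier(max_depth=5),
            n_estimators=100,
            random_state=seed,
        )
    raise ValueError(f"unknown classifier {name!r}")


@dataclass
class CVResult:
    """Cross-validated accuracy for one (comparison, table, classifier) cell."""

    comparison: tuple[str, str]
    layout: str
    fixed_factor: str
    classifier: str
    fold_accuracies: np.ndarray
    mean_accuracy: float
    confusion: np.ndarray  # 2x2 counts, rows = true (first group, second group)
    seed: int
    fold_unit: str = "subject"
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)

    def __post_init__(self) -> None:
        tp, fn = self.confusion[0]
        fp, tn = self.confusion[1]
        self.sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
        self.specificity = tn / (tn + fp) if (tn + fp) else float("nan")


def crossvalidate(
    table: pd.DataFrame,
    comparison: tuple[str, str],
    classifier: str,
    seed: int,
    *,
    layout: str = "statewise",
    fixed_factor: str = "",
    n_folds: int = 10,
    fold_unit: str = "subject",
) -> CVResult:
    """Stratified 10-fold cross-validation of one binary group contrast.

    Features are standardized *within* each training fold and the fitted
    scaling applied to the held-out fold, so no test-set statistics leak
    into training.
    """
    a, b = comparison
    sub = table[table["group"].isin(comparison)]
    feature_cols = [c for c in sub.columns if c != "group"]
    y = (sub["group"] == b).to_numpy().astype(int)  # 0 = first group, 1 = second
    X = sub[feature_cols].to_numpy(dtype=float)
    subjects = sub.index.get_level_values("subject").to_numpy()
    for grp in comparison:
        if int((sub["group"] == grp).sum()) < n_folds:
            raise ValueError(f"need >= {n_folds} samples per class; group {grp} has fewer")

    n_subjects = len(np.unique(subjects))
    if fold_unit == "subject" and n_subjects < n_folds:
        warnings.warn(
            f"only {n_subjects} subjects for {n_folds}-fold subject-level CV; "
            "falling back to epoch-level folds (subject leakage across folds)",
            UserWarning,
            stacklevel=2,
        )
        fold_unit = "epoch"

    if fold_unit == "subject":
        splitter = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = splitter.split(X, y, groups=subjects)
    elif fold_unit == "epoch":
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = splitter.split(X, y)
    else:
        raise ValueError(f"unknown fold_unit {fold_unit!r}")

    accs = []
    conf = np.zeros((2, 2), dtype=int)
    for train, test in splits:
        model = Pipeline(
            [("scale", StandardScaler()), ("clf", make_classifier(classifier, seed))]
        )
        model.fit(X[train], y[train])
        pred = model.predict(X[test])
        accs.append(float(np.mean(pred == y[test])))
        conf += sk_confusion(y[test], pred, labels=[0, 1])
    accs = np.asarray(accs)
    return CVResult(
        comparison=comparison,
        layout=layout,
        fixed_factor=fixed_factor,
        classifier=classifier,
        fold_accuracies=accs,
        mean_accuracy=float(accs.mean()),
        confusion=conf,
        seed=seed,
        fold_unit=fold_unit,
    )


def run_full_comparison(
    features: pd.DataFrame,
    seed: int,
    *,
    statewise_states: tuple[str, ...] = DEFAULT_STATEWISE_STATES,
    bands: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS),
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES,
    comparisons: tuple[tuple[str, str], ...] = COMPARISONS,
    fold_unit: str = "subject",
    n_folds: int = 10,
) -> pd.DataFrame:
    """The full accuracy grid: comparisons x (states + bands) x classifiers.

    Under defaults this is 2 x (3 + 4) x 6 = 84 rows.
    """
    from .features import build_feature_table  # local import avoids cycle

    present = set(features["group"])
    needed = {g for comp in comparisons for g in comp}
    missing = sorted(needed - present)
    if missing:
        raise ValueError(f"cohort lacks group(s): {missing}")
    for g in GROUPS:
        if g in needed and g not in present:
            raise ValueError(f"cohort lacks group {g}")

    cells = [("statewise", s) for s in statewise_states] + [("bandwise", b) for b in bands]
    rows = []
    for layout, fixed in cells:
        table = build_feature_table(features, layout, fixed)
        for comp in comparisons:
            for name in classifiers:
                res = crossvalidate(
                    table, comp, name, seed,
                    layout=layout, fixed_factor=fixed,
                    n_folds=n_folds, fold_unit=fold_unit,
                )
                rows.append(
                    {
                        "comparison": f"{comp[0]} vs {comp[1]}",
                        "layout": layout,
                        "fixed_factor": fixed,
                        "classifier": name,
                        "mean_accuracy": res.mean_accuracy,
                        "sensitivity": res.sensitivity,
                        "specificity": res.specificity,
                        "fold_unit": res.fold_unit,
                        "seed": seed,
                    }
                )
    return pd.DataFrame(rows)
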