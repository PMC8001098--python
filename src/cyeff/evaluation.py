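"""Supervised evaluation harness for feature tables.

Implements the benchmarking protocol used to assess the effort features:
group-aware (patient-exclusive) train/test splitting, grid-searched
hyperparameters for four classifiers (polynomial and RBF SVM, kNN, random
forest), pooled confusion-matrix metrics, and two univariate feature
rankings (two-sample t-test and a rank test).

A feature table is a pandas DataFrame with the reserved columns
``image_id``, ``group_id``, ``label`` (binary, 1 = rough/malignant-like,
the positive class) followed by one column per feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "ID_COLUMNS",
    "CLASSIFIERS",
    "ConfusionMatrix",
    "FitResult",
    "feature_columns",
    "group_split",
    "default_grid",
    "fit_evaluate",
    "rank_features",
]

ID_COLUMNS = ("image_id", "group_id", "label")
CLASSIFIERS = ("svm_poly", "svm_rbf", "knn", "rf")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with the rough/malignant-like class positive."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")


@dataclass(frozen=True)
class FitResult:
    classifier: str
    confusion: ConfusionMatrix
    best_params: dict

    @property
    def accuracy(self) -> float:
        return self.confusion.accuracy

    @property
    def sensitivity(self) -> float:
        return self.confusion.sensitivity

    @property
    def specificity(self) -> float:
        return self.confusion.specificity


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ID_COLUMNS]


def _validate_table(table: pd.DataFrame) -> None:
    missing = [c for c in ID_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks required columns {missing}")
    if table[feature_columns(table)].isna().any().any():
        raise ValueError("feature table contains missing values")
    if not set(np.unique(table["label"])) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    straddle = table.groupby("group_id")["label"].nunique()
    if (straddle > 1).any():
        bad = straddle[straddle > 1].index.tolist()
        raise ValueError(f"groups straddle classes: {bad}")


def group_split(
    table: pd.DataFrame, test_fraction: float = 0.2, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split rows by group so no group appears in both partitions.

    Groups are allocated per class (each class keeps at least one group on
    each side), so both partitions contain both classes and leakage through
    shared groups is impossible by construction.
    """
    _validate_table(table)
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    test_groups: list = []
    for label in (0, 1):
        groups = sorted(table.loc[table["label"] == label, "group_id"].unique())
        if len(groups) < 2:
            raise ValueError(f"class {label} has fewer than 2 groups; cannot split")
        n_test = int(np.clip(round(test_fraction * len(groups)), 1, len(groups) - 1))
        order = rng.permutation(len(groups))
        test_groups.extend(groups[i] for i in order[:n_test])
    in_test = table["group_id"].isin(test_groups)
    train, test = table[~in_test].copy(), table[in_test].copy()
    assert not set(train["group_id"]) & set(test["group_id"])
    return train, test


def default_grid(classifier: str, profile: str = "fast") -> dict:
    """Hyperparameter grids.

    ``full`` spans the canonical search ranges (C and gamma from 1e-3 to
    1e3 in decades, k from 1 to 1000, trees 5..1000 in steps of five, depth
    1..50); ``fast`` truncates them (k <= 50, trees <= 200, coarse depth)
    for desk-scale runs.  Both contain the reference optima C=1,
    gamma=0.01, k=10, depth 7 with 60 trees.
    """
    decades = [10.0**e for e in range(-3, 4)]
    small_decades = [10.0**e for e in range(-2, 3)]
    if profile == "full":
        grids = {
            "svm_poly": {"clf__C": decades},
            "svm_rbf": {"clf__C": decades, "clf__gamma": decades},
            "knn": {"clf__n_neighbors": list(range(1, 1001))},
            "rf": {
                "clf__n_estimators": list(range(5, 1001, 5)),
                "clf__max_depth": list(range(1, 51)),
            },
        }
    elif profile == "fast":
        grids = {
            "svm_poly": {"clf__C": small_decades},
            "svm_rbf": {"clf__C": small_decades, "clf__gamma": small_decades},
            "knn": {"clf__n_neighbors": [1, 3, 5, 10, 20, 50]},
            "rf": {"clf__n_estimators": [20, 60, 120, 200], "clf__max_depth": [3, 7, 15, 50]},
        }
    else:
        raise ValueError(f"unknown grid profile {profile!r}")
    if classifier not in grids:
        raise ValueError(f"unknown classifier {classifier!r}; choose from {CLASSIFIERS}")
    return grids[classifier]


def _make_estimator(classifier: str, seed: int | None) -> Pipeline:
    if classifier == "svm_poly":
        clf = SVC(kernel="poly", degree=3)
    elif classifier == "svm_rbf":
        clf = SVC(kernel="rbf")
    elif classifier == "knn":
        clf = KNeighborsClassifier(metric="euclidean")
    elif classifier == "rf":
        clf = RandomForestClassifier(random_state=seed)
    else:
        raise ValueError(f"unknown classifier {classifier!r}; choose from {CLASSIFIERS}")
    steps = []
    if classifier in ("svm_poly", "svm_rbf", "knn"):
        # distance/margin based: standardize with train statistics
        steps.append(("scale", StandardScaler()))
    steps.append(("clf", clf))
    return Pipeline(steps)


def fit_evaluate(
    train: pd.DataFrame,
    test: pd.DataFrame,
    classifier: str,
    grid: dict | None = None,
    cv: int = 10,
    seed: int | None = None,
) -> FitResult:
    """Grid-search on train (k-fold CV), freeze the best model, score test.

    The held-out rows are evaluated in ``cv`` folds with the frozen model
    and the per-fold confusion matrices are pooled; with a frozen model the
    pooled matrix equals the all-at-once one, but the fold protocol is kept
    explicit so fold-wise metrics can be inspected.
    """
    for t in (train, test):
        _validate_table(t)
    cols = feature_columns(train)
    if cols != feature_columns(test):
        raise ValueError("train and test must share feature columns")
    y_train = train["label"].to_numpy()
    if len(np.unique(y_train)) < 2:
        raise ValueError("training data contains a single class")
    x_train = train[cols].to_numpy(float)
    grid = grid if grid is not None else default_grid(classifier)
    n_cv = min(cv, int(np.bincount(y_train).min()))
    if "clf__n_neighbors" in grid:
        # a fold's fit set has ~ (n_cv-1)/n_cv of the rows; larger k cannot fit
        max_k = max(1, len(train) * (n_cv - 1) // n_cv)
        ks = [k for k in grid["clf__n_neighbors"] if k <= max_k]
        grid = {**grid, "clf__n_neighbors": ks or [max_k]}
    search = GridSearchCV(_make_estimator(classifier, seed), grid, cv=n_cv, scoring="accuracy")
    search.fit(x_train, y_train)
    model = search.best_estimator_

    x_test = test[cols].to_numpy(float)
    y_test = test["label"].to_numpy()
    n_folds = min(cv, len(test))
    folds = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    tp = tn = fp = fn = 0
    for _, idx in folds.split(x_test):
        pred = model.predict(x_test[idx])
        truth = y_test[idx]
        tp += int(np.sum((pred == 1) & (truth == 1)))
        tn += int(np.sum((pred == 0) & (truth == 0)))
        fp += int(np.sum((pred == 1) & (truth == 0)))
        fn += int(np.sum((pred == 0) & (truth == 1)))
    return FitResult(
        classifier=classifier,
        confusion=ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn),
        best_params={k.removeprefix("clf__"): v for k, v in search.best_params_.items()},
    )


def rank_features(
    table: pd.DataFrame, method: str = "t_test", paired: bool = False
) -> pd.DataFrame:
    """Rank features by class separation significance (smallest p first).

    ``t_test`` is the two-sample Student t-test.  ``wilcoxon`` defaults to
    the rank-sum (Mann-Whitney) form, the valid choice for independent
    class groups; ``paired=True`` forces the literal signed-rank test on
    class samples trimmed to equal length.  Features whose statistic is
    undefined (e.g. constant in both classes) are flagged and ranked last.
    Returns a DataFrame with columns feature, statistic, p_value, defined,
    rank.
    """
    _validate_table(table)
    if method not in ("t_test", "wilcoxon"):
        raise ValueError(f"unknown ranking method {method!r}")
    rows = []
    for name in feature_columns(table):
        a = table.loc[table["label"] == 1, name].to_numpy(float)
        b = table.loc[table["label"] == 0, name].to_numpy(float)
        try:
            if method == "t_test":
                stat, p = stats.ttest_ind(a, b)
            elif paired:
                n = min(len(a), len(b))
                stat, p = stats.wilcoxon(a[:n], b[:n])
            else:
                stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            defined = bool(np.isfinite(p))
        except ValueError:
            stat, p, defined = float("nan"), float("nan"), False
        if not defined:
            stat, p = float("nan"), float("nan")
        rows.append({"feature": name, "statistic": float(stat), "p_value": float(p), "defined": defined})
    out = pd.DataFrame(rows)
    # undefined last; ties broken by name for determinism
    out["_p"] = out["p_value"].fillna(np.inf)
    out = out.sort_values(["_p", "feature"], kind="stable").drop(columns="_p")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)
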