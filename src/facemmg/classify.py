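"""Leave-session-out SVM training and evaluation.

Sensors are removed and re-placed between sessions, so whole sessions
are held out: train on two sessions, test on the third, rotating the
held-out session.  In user-dependent mode one subject's events are
used; in user-independent mode all subjects are pooled (subjects appear
in both train and test, sessions never do).

Hyperparameters come from a fixed grid — linear kernel with
C in {0.001, 0.01, 1, 10}; polynomial with C in {7, 8, 9, 10, 12, 15,
20}, degree in {1, 2, 3} and gamma in {4, 16, 1, 1/4, 1/16}/n_features;
plus, in user-independent mode, a Gaussian (RBF) kernel with C in
{3, 5, 6, 7, 8, 9}.  A seeded class-stratified 33% tuning hold-out is
carved from the training split; each grid point is scored by 10-fold
stratified CV macro-recall on the remaining 67% and the winner is
refitted on the full training split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import (StratifiedKFold, cross_val_score,
                                     train_test_split)
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

from .calibration import enumerate_pairs
from .features import FeatureMatrix, build_feature_matrix
from .synth import GESTURES, Dataset, calibration_tables

__all__ = [
    "GridSpec", "SplitSpec", "EvalReport", "ExperimentResult",
    "split", "grid_search", "make_svm", "evaluate", "run_experiment",
    "chance_level",
]


@dataclass(frozen=True)
class GridSpec:
    """The SVM hyperparameter search grid."""

    C_linear: tuple[float, ...] = (0.001, 0.01, 1, 10)
    C_poly: tuple[float, ...] = (7, 8, 9, 10, 12, 15, 20)
    degrees: tuple[int, ...] = (1, 2, 3)
    gamma_factors: tuple[float, ...] = (4.0, 16.0, 1.0, 0.25, 0.0625)
    C_gaussian: tuple[float, ...] = (3, 5, 6, 7, 8, 9)
    include_gaussian: bool = False
    cv_folds: int = 10
    holdout_fraction: float = 0.33
    tuning_metric: str = "recall_macro"

    def points(self, n_features: int) -> Iterator[dict]:
        """Every grid point as an SVC keyword dict (deterministic order)."""
        gammas = [f / n_features for f in self.gamma_factors]
        for C in self.C_linear:
            yield {"kernel": "linear", "C": C}
        for C in self.C_poly:
            for degree in self.degrees:
                for gamma in gammas:
                    yield {"kernel": "poly", "C": C, "degree": degree,
                           "gamma": gamma}
        if self.include_gaussian:
            for C in self.C_gaussian:
                for gamma in gammas:
                    yield {"kernel": "rbf", "C": C, "gamma": gamma}

    def n_points(self, n_features: int = 176) -> int:
        return sum(1 for _ in self.points(n_features))


@dataclass(frozen=True)
class SplitSpec:
    """Leave-session-out split: which session is held out, for whom."""

    mode: str                      # "independent" or "dependent"
    test_session: int
    subject_id: int | None = None  # required in dependent mode

    def __post_init__(self) -> None:
        if self.mode not in ("independent", "dependent"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if self.mode == "dependent" and self.subject_id is None:
            raise ValueError("user-dependent split needs a subject_id")


def split(labels: pd.DataFrame, spec: SplitSpec) -> tuple[pd.Index, pd.Index]:
    """(train index, test index) over a labels frame.

    Train = the two remaining sessions; test = the held-out session.
    In dependent mode both sides are restricted to the named subject.
    """
    sessions = set(labels["session_id"].unique())
    if spec.test_session not in sessions:
        raise ValueError(f"unknown session {spec.test_session}; have {sorted(sessions)}")
    frame = labels
    if spec.mode == "dependent":
        if spec.subject_id not in set(labels["subject_id"].unique()):
            raise ValueError(f"unknown subject {spec.subject_id}")
        frame = labels[labels["subject_id"] == spec.subject_id]
    test = frame.index[frame["session_id"] == spec.test_session]
    train = frame.index[frame["session_id"] != spec.test_session]
    return train, test


def make_svm(params: dict, decomposition: str = "ovo"):
    """SVC from a grid point; optionally wrapped one-vs-rest."""
    clf = SVC(**params)
    if decomposition == "ovr":
        return OneVsRestClassifier(clf)
    if decomposition != "ovo":
        raise ValueError(f"unknown decomposition {decomposition!r}")
    return clf


def grid_search(
    X: np.ndarray,
    y: Sequence[str],
    grid: GridSpec,
    seed: int = 0,
    decomposition: str = "ovo",
    use_holdout: bool = True,
):
    """Grid search with a 33% tuning hold-out and 10-fold CV macro-recall.

    Returns (best_params, fitted_model, cv_table).  The winner is
    refitted on all of (X, y).  Deterministic for a given seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes to train")
    if use_holdout and 0.0 < grid.holdout_fraction < 1.0:
        X_cv, _X_hold, y_cv, _y_hold = train_test_split(
            X, y, test_size=grid.holdout_fraction, stratify=y,
            random_state=seed)
    else:
        X_cv, y_cv = X, y
    _, counts = np.unique(y_cv, return_counts=True)
    if counts.min() < grid.cv_folds:
        raise ValueError(
            f"stratification error: smallest class has {counts.min()} events "
            f"in the tuning split, fewer than cv_folds={grid.cv_folds}")
    skf = StratifiedKFold(n_splits=grid.cv_folds, shuffle=True,
                          random_state=seed)
    rows = []
    best_score, best_params = -np.inf, None
    for params in grid.points(X.shape[1]):
        model = make_svm(params, decomposition)
        scores = cross_val_score(model, X_cv, y_cv, cv=skf,
                                 scoring=grid.tuning_metric)
        mean = float(scores.mean())
        rows.append({**params, "cv_score": mean})
        if mean > best_score:  # ties keep the earlier grid point
            best_score, best_params = mean, params
    model = make_svm(best_params, decomposition).fit(X, y)
    return best_params, model, pd.DataFrame(rows)


@dataclass
class EvalReport:
    """Confusion matrix and per-class / averaged metrics on a test split."""

    confusion: pd.DataFrame          # rows = true class, cols = predicted
    per_class: pd.DataFrame          # precision, recall, f1, support
    macro: dict[str, float]
    weighted: dict[str, float]
    n_test: int

    def to_json_dict(self) -> dict:
        return {
            "n_test": self.n_test,
            "macro": self.macro,
            "weighted": self.weighted,
            "per_class": self.per_class.to_dict(orient="index"),
            "confusion": self.confusion.to_dict(orient="index"),
        }


def evaluate(model, X: np.ndarray, y: Sequence[str],
             classes: Sequence[str] = GESTURES) -> EvalReport:
    """Score a fitted model: confusion matrix, per-class and macro P/R/F1.

    A class that is never predicted has precision (and F1 where
    undefined) reported as 0.
    """
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty test split")
    unknown = set(y) - set(classes)
    if unknown:
        raise ValueError(f"labels outside the class dictionary: {sorted(unknown)}")
    pred = model.predict(np.asarray(X, dtype=float))
    cm = confusion_matrix(y, pred, labels=list(classes))
    prec, rec, f1, support = precision_recall_fscore_support(
        y, pred, labels=list(classes), zero_division=0)
    per_class = pd.DataFrame(
        {"precision": prec, "recall": rec, "f1": f1, "support": support},
        index=list(classes))
    present = per_class["support"] > 0
    macro = {
        "precision": float(prec[present].mean()),
        "recall": float(rec[present].mean()),
        "f1": float(f1[present].mean()),
        "accuracy": float(np.mean(pred == y)),
    }
    w = support[present] / support[present].sum()
    weighted = {
        "precision": float(np.sum(prec[present] * w)),
        "recall": float(np.sum(rec[present] * w)),
        "f1": float(np.sum(f1[present] * w)),
    }
    return EvalReport(
        confusion=pd.DataFrame(cm, index=list(classes), columns=list(classes)),
        per_class=per_class, macro=macro, weighted=weighted,
        n_test=int(y.size))


def chance_level(n_classes: int = len(GESTURES)) -> float:
    """Chance accuracy of a balanced problem (1/11 ~ 0.09 here)."""
    return 1.0 / n_classes


@dataclass
class ExperimentResult:
    """Aggregated leave-session-out outcome over the session rotations."""

    reports: dict[int, EvalReport]          # keyed by held-out session
    best_params: dict[int, dict]
    mean_macro: dict[str, float]
    mean_per_class_f1: pd.Series
    n_feature_columns: int
    dma_set: str
    mode: str

    def weakest_classes(self, k: int = 3) -> list[str]:
        return list(self.mean_per_class_f1.nsmallest(k).index)


def run_experiment(
    dataset: Dataset,
    dma_set: str = "all",
    mode: str = "independent",
    subject_id: int | None = None,
    seed: int = 0,
    grid: GridSpec | None = None,
    policy: str = "max",
    decomposition: str = "ovo",
    feature_matrix: FeatureMatrix | None = None,
    test_sessions: Sequence[int] | None = None,
    use_holdout: bool = False,
) -> ExperimentResult:
    """Full pipeline over all session rotations.

    Enumerates the DMA set, builds per-session calibration tables from
    synthetic sweeps, featurizes every event, then per held-out session:
    standardize on train (imputation + scaling from training rows only),
    grid-search the SVM on train, and evaluate on the held-out session.
    The Gaussian kernel is enabled only in user-independent mode unless
    an explicit grid is given.
    """
    if grid is None:
        grid = GridSpec(include_gaussian=(mode == "independent"))
    pairs = enumerate_pairs(dma_set)
    if feature_matrix is None:
        tables = calibration_tables(dataset)
        feature_matrix = build_feature_matrix(dataset, pairs, tables,
                                              policy=policy)
    fm = feature_matrix
    if test_sessions is None:
        test_sessions = sorted(fm.labels["session_id"].unique())

    reports: dict[int, EvalReport] = {}
    best_params: dict[int, dict] = {}
    for sess in test_sessions:
        spec = SplitSpec(mode=mode, test_session=int(sess),
                         subject_id=subject_id)
        train_idx, test_idx = split(fm.labels, spec)
        X_train, X_all, _ = fm.standardized(train_idx)
        y_train = fm.labels.loc[train_idx, "gesture"].to_numpy()
        params, model, _cv = grid_search(
            X_train, y_train, grid, seed=seed, decomposition=decomposition,
            use_holdout=use_holdout)
        pos = fm.values.index.get_indexer(test_idx)
        X_test = X_all[pos]
        y_test = fm.labels.loc[test_idx, "gesture"].to_numpy()
        reports[int(sess)] = evaluate(model, X_test, y_test)
        best_params[int(sess)] = params

    macro_keys = ("precision", "recall", "f1", "accuracy")
    mean_macro = {k: float(np.mean([r.macro[k] for r in reports.values()]))
                  for k in macro_keys}
    mean_f1 = pd.concat(
        [r.per_class["f1"] for r in reports.values()], axis=1).mean(axis=1)
    return ExperimentResult(
        reports=reports, best_params=best_params, mean_macro=mean_macro,
        mean_per_class_f1=mean_f1, n_feature_columns=fm.n_columns,
        dma_set=dma_set, mode=mode)
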