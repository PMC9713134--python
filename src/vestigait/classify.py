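"""Random-Forest classification with subject-wise repeated splits.

Models are evaluated the way small-cohort wearable studies should be: every
trial of a participant stays on one side of the train/test split, 50
repeated splits each hold out three participants per class, and performance
is the AUROC of the *merged* pool of held-out prediction probabilities
across repeats, with a percentile-bootstrap confidence interval.
Hyperparameters are tuned on the training split alone with participant-
grouped k-fold cross-validation, and feature standardization is fit on the
training split only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import itertools
import logging

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupKFold

from .features import TaskDataset

log = logging.getLogger(__name__)


class InvalidCohortError(ValueError):
    """Fewer than three participants in a class; the split is impossible."""


class UndefinedAUROCError(ValueError):
    """Pooled predictions contain a single class."""


@dataclass(frozen=True)
class SplitPlan:
    """Repeated subject-wise 80/20 splits: 24 train / 6 test participants."""

    repeats: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)

    def validate(self) -> None:
        for train, test in self.repeats:
            assert not set(train) & set(test), "participant leaked across the split"


def make_split_plan(participants, labels, n_repeats: int = 50,
                    seed: int = 0, n_test_per_class: int = 3) -> SplitPlan:
    """Independent repeated draws of a 3+3-participant test set.

    Each repeat samples ``n_test_per_class`` participants per class without
    replacement for the test side; the rest train. Across repeats the draws
    are independent, so participants recur in different test sets.
    """
    participants = np.asarray(participants)
    labels = np.asarray(labels)
    by_class = {c: participants[labels == c] for c in (0, 1)}
    for c, members in by_class.items():
        if len(members) < n_test_per_class:
            raise InvalidCohortError(
                f"class {c} has {len(members)} participants; "
                f"need at least {n_test_per_class}")
    rng = np.random.default_rng(seed)
    repeats = []
    for _ in range(n_repeats):
        test = np.concatenate([
            rng.choice(by_class[c], size=n_test_per_class, replace=False)
            for c in (0, 1)])
        test_set = set(test.tolist())
        train = tuple(sorted(p for p in participants.tolist() if p not in test_set))
        repeats.append((train, tuple(sorted(test.tolist()))))
    plan = SplitPlan(tuple(repeats))
    plan.validate()
    return plan


@dataclass
class Scaler:
    mean: np.ndarray
    std: np.ndarray
    zero_variance: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        out = (X - self.mean) / self.std
        out[:, self.zero_variance] = 0.0
        return out


def standardize(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray, Scaler]:
    """Per-feature z-scoring fit on the training matrix only.

    Zero-variance training features map to 0 in both matrices.
    """
    train = np.asarray(train, dtype=float)
    test = np.asarray(test, dtype=float)
    if train.size == 0:
        raise ValueError("training matrix is empty")
    mean = train.mean(axis=0)
    std = train.std(axis=0)
    zero = std == 0
    std_safe = np.where(zero, 1.0, std)
    scaler = Scaler(mean=mean, std=std_safe, zero_variance=zero)
    return scaler.transform(train), scaler.transform(test), scaler


@dataclass(frozen=True)
class ModelConfig:
    """Random-Forest hyperparameter grid and inner-CV settings.

    The default grid spans the four tuned hyperparameters; grid points are
    ordered as listed and ties in inner-CV AUROC break toward the earlier
    point. A singleton grid skips the inner CV entirely.
    """

    param_grid: dict = field(default_factory=lambda: {
        "n_estimators": (100, 300, 500),
        "max_features": ("sqrt", 0.1, 0.3),
        "max_depth": (None, 5, 10),
        "min_samples_leaf": (1, 2, 5),
    })
    inner_cv_folds: int = 5
    n_bootstrap: int = 1000
    seed: int = 0

    def grid_points(self) -> list[dict]:
        keys = list(self.param_grid)
        combos = itertools.product(*(self.param_grid[k] for k in keys))
        points = [dict(zip(keys, combo)) for combo in combos]
        if not points:
            raise ValueError("hyperparameter grid is empty")
        return points

    @classmethod
    def singleton(cls, n_estimators: int = 200, max_features="sqrt",
                  max_depth=None, min_samples_leaf: int = 1, **kw) -> "ModelConfig":
        """A grid of one point, for quick evaluations without inner CV."""
        return cls(param_grid={
            "n_estimators": (n_estimators,), "max_features": (max_features,),
            "max_depth": (max_depth,), "min_samples_leaf": (min_samples_leaf,)}, **kw)


def _fit_forest(params: dict, X: np.ndarray, y: np.ndarray, seed: int):
    model = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    model.fit(X, y)
    return model


def tune_and_train(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                   config: ModelConfig) -> tuple[RandomForestClassifier, dict, float]:
    """Grid search with participant-grouped k-fold CV, then refit on all rows.

    Inner folds that end up single-class are skipped with a warning (their
    AUROC is undefined). Returns (model, best_params, best mean inner AUROC);
    the score is NaN when the grid is a singleton and no CV ran.
    """
    points = config.grid_points()
    if len(points) == 1:
        return _fit_forest(points[0], X, y, config.seed), points[0], float("nan")
    n_groups = len(np.unique(groups))
    k = min(config.inner_cv_folds, n_groups)
    splitter = GroupKFold(n_splits=k)
    folds = list(splitter.split(X, y, groups))
    scores = []
    for params in points:
        fold_aucs = []
        for tr, va in folds:
            if len(np.unique(y[va])) < 2:
                log.warning("inner fold has one class; skipping its AUROC")
                continue
            model = _fit_forest(params, X[tr], y[tr], config.seed)
            fold_aucs.append(roc_auc_score(y[va], model.predict_proba(X[va])[:, 1]))
        scores.append(np.mean(fold_aucs) if fold_aucs else -np.inf)
    best = int(np.argmax(scores))  # first max wins: ties break by grid order
    return _fit_forest(points[best], X, y, config.seed), points[best], float(scores[best])


@dataclass
class EvalResult:
    """Merged-prediction evaluation of one (placement, task) model."""

    predictions: pd.DataFrame  # repeat, participant_id, trial_index, label, prob
    auroc: float
    auroc_ci: tuple[float, float]
    accuracy: float
    f1: float
    sensitivity: float
    specificity: float
    confusion: np.ndarray  # [[tn, fp], [fn, tp]]
    models: list | None = None

    def __post_init__(self) -> None:
        assert 0.0 <= self.auroc <= 1.0
        lo, hi = self.auroc_ci
        assert lo <= self.auroc <= hi or np.isnan(lo)
        assert int(self.confusion.sum()) == len(self.predictions)


def _threshold_metrics(y: np.ndarray, prob: np.ndarray, threshold: float = 0.5):
    pred = (prob >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    accuracy = (tp + tn) / len(y)
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan")
    return accuracy, f1, sensitivity, specificity, np.array([[tn, fp], [fn, tp]])


def bootstrap_auroc_ci(y: np.ndarray, prob: np.ndarray, n_boot: int = 1000,
                       seed: int = 0, level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUROC of a prediction pool."""
    rng = np.random.default_rng(seed)
    n = len(y)
    stats_ = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(y[idx])) < 2:
            continue
        stats_.append(roc_auc_score(y[idx], prob[idx]))
    if not stats_:
        return (float("nan"), float("nan"))
    alpha = (1.0 - level) / 2.0
    return (float(np.quantile(stats_, alpha)), float(np.quantile(stats_, 1 - alpha)))


def evaluate(plan: SplitPlan, dataset: TaskDataset, config: ModelConfig,
             return_models: bool = False) -> EvalResult:
    """Run every repeat of the plan and score the merged prediction pool.

    Per repeat: standardize on the training split, tune/fit the forest, and
    predict probabilities for the held-out participants' trials. All
    (label, probability) pairs are pooled over repeats; the merged AUROC,
    its bootstrap CI, and threshold-0.5 metrics are computed on the pool.
    """
    plan.validate()
    X = dataset.X.to_numpy(dtype=float)
    known = set(dataset.groups.tolist())
    rows = []
    models = []
    for repeat, (train_ids, test_ids) in enumerate(plan.repeats):
        if not (set(train_ids) | set(test_ids)) <= known:
            raise ValueError("split plan references unknown participants")
        tr = np.isin(dataset.groups, train_ids)
        te = np.isin(dataset.groups, test_ids)
        X_tr, X_te, _scaler = standardize(X[tr], X[te])
        model, params, _score = tune_and_train(
            X_tr, dataset.y[tr], dataset.groups[tr], config)
        prob = model.predict_proba(X_te)[:, 1]
        for (pid, trial_index), label, p in zip(
                dataset.X.index[te], dataset.y[te], prob):
            rows.append((repeat, pid, trial_index, int(label), float(p)))
        if return_models:
            models.append((model, params, test_ids))
    pool = pd.DataFrame(rows, columns=["repeat", "participant_id", "trial_index",
                                       "label", "prob"])
    y = pool["label"].to_numpy()
    prob = pool["prob"].to_numpy()
    if len(np.unique(y)) < 2:
        raise UndefinedAUROCError("pooled predictions contain one class")
    auroc = float(roc_auc_score(y, prob))
    ci = bootstrap_auroc_ci(y, prob, n_boot=config.n_bootstrap, seed=config.seed + 101)
    accuracy, f1, sens, spec, confusion = _threshold_metrics(y, prob)
    return EvalResult(predictions=pool, auroc=auroc, auroc_ci=ci,
                      accuracy=accuracy, f1=f1, sensitivity=sens,
                      specificity=spec, confusion=confusion,
                      models=models if return_models else None)


def placement_task_grid(task_datasets: dict[str, TaskDataset],
                        placements, config: ModelConfig,
                        n_repeats: int = 50, split_seed: int = 0,
                        ) -> tuple[pd.DataFrame, dict]:
    """One model per (placement, task); AUROC matrix with row/column means.

    ``task_datasets`` maps task id to a (possibly multi-placement) feature
    dataset; each cell restricts the columns to one placement. Returns the
    AUROC matrix (placements x tasks, margins appended as ``mean``) and the
    dict of full :class:`EvalResult` objects keyed ``(placement, task)``.
    """
    results: dict[tuple[str, str], EvalResult] = {}
    tasks = list(task_datasets)
    matrix = pd.DataFrame(index=list(placements), columns=tasks, dtype=float)
    for task, dataset in task_datasets.items():
        participants = dataset.participants
        labels = np.array([dataset.participant_labels()[p] for p in participants])
        plan = make_split_plan(participants, labels, n_repeats=n_repeats,
                               seed=split_seed)
        for placement in placements:
            sub = dataset.select_placements([placement])
            res = evaluate(plan, sub, config)
            results[(placement, task)] = res
            matrix.loc[placement, task] = res.auroc
    matrix["mean"] = matrix[tasks].mean(axis=1)
    matrix.loc["mean"] = matrix.mean(axis=0)
    return matrix, results
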