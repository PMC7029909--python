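"""Within-activity lameness classifiers under stratified 10-fold CV.

Five algorithms are benchmarked with fixed hyperparameters: random
forest (250 trees, minimum leaf 1, √p features per split), a one-hidden-
layer neural network (100 rectified-linear units, learning rate 1e-4),
an RBF-kernel support vector machine, AdaBoost over 100 depth-1 trees
(learning rate 1) and 5-nearest-neighbours with Euclidean distance and
no normalization.  Cross-validation is 10-fold, stratified on the
lameness class only — deliberately *not* grouped by sheep, reproducing
the sheep-level leakage of the original protocol; a grouped-by-sheep
mode is available for the leakage-free variant.

No class rebalancing is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from ovinesense.evaluate import ConfusionCounts, MetricSet, compute_metrics
from ovinesense.features import FEATURE_NAMES
from ovinesense.relieff import RankedFeatures, top_k

ALGORITHMS = ("RF", "NN", "SVM", "AdaBoost", "KNN")


@dataclass(frozen=True)
class ClassifierSpec:
    """One of the five benchmarked algorithms with its fixed settings.

    Settings not pinned above (SVM regularization/width, NN optimizer)
    follow scikit-learn conventional defaults and are recorded in the run
    manifest.  The NN trains by stochastic gradient (adam) for at most
    ``nn_max_iter`` epochs with early stop on a training-loss plateau.
    """

    algorithm: str
    seed: int = 0
    nn_max_iter: int = 300

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}")

    def build(self):
        if self.algorithm == "RF":
            return RandomForestClassifier(
                n_estimators=250,
                min_samples_leaf=1,
                max_features="sqrt",
                random_state=self.seed,
                n_jobs=1,
            )
        if self.algorithm == "NN":
            return MLPClassifier(
                hidden_layer_sizes=(100,),
                activation="relu",
                learning_rate_init=0.0001,
                max_iter=self.nn_max_iter,
                n_iter_no_change=10,
                random_state=self.seed,
            )
        if self.algorithm == "SVM":
            return SVC(kernel="rbf", random_state=self.seed)
        if self.algorithm == "AdaBoost":
            return AdaBoostClassifier(
                estimator=DecisionTreeClassifier(max_depth=1),
                n_estimators=100,
                learning_rate=1.0,
                random_state=self.seed,
            )
        return KNeighborsClassifier(n_neighbors=5, metric="euclidean")

    @property
    def hyperparameters(self) -> dict:
        return self.build().get_params()


@dataclass
class CVResult:
    """Cross-validated performance for one (activity, algorithm, n_features)."""

    activity: str
    algorithm: str
    n_features_used: int
    fold_counts: list[ConfusionCounts]
    fold_metrics: list[MetricSet]
    mean_metrics: MetricSet
    predictions: pd.DataFrame  # sheep_id, window_index, lame, predicted_lame, fold

    @property
    def mean_accuracy(self) -> float:
        return self.mean_metrics.overall_accuracy


def stratified_kfold(
    labels: np.ndarray | pd.Series, k: int = 10, seed: int = 0
) -> np.ndarray:
    """Fold index per instance, stratified on the binary lameness class.

    Every instance lands in exactly one fold and per-fold class
    proportions match the global proportion to within one instance.
    """
    y = np.asarray(labels).astype(int)
    _, counts = np.unique(y, return_counts=True)
    if len(counts) < 2 or counts.min() < k:
        raise ValueError(
            f"each class needs >= k={k} members for stratified {k}-fold; "
            f"class counts are {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        assignment[test_idx] = fold
    return assignment


def grouped_kfold(
    labels: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
    k: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Leakage-free alternative: folds never split a sheep across train
    and test, while keeping the lameness classes balanced across folds
    (class-imbalanced folds would bias every fold's majority prior)."""
    y = np.asarray(labels).astype(int)
    groups = np.asarray(groups)
    if len(np.unique(groups)) < k:
        raise ValueError(f"need >= k={k} distinct sheep for grouped {k}-fold")
    sgkf = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(groups), dtype=int)
    X_dummy = np.zeros((len(groups), 1))
    for fold, (_, test_idx) in enumerate(sgkf.split(X_dummy, y, groups=groups)):
        assignment[test_idx] = fold
    return assignment


def run_cv(
    feature_table: pd.DataFrame,
    ranking: RankedFeatures | None,
    spec: ClassifierSpec,
    n_features: int = len(FEATURE_NAMES),
    k_folds: int = 10,
    fold_assignment: np.ndarray | None = None,
    fold_seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation on one activity's windows.

    ``feature_table`` is the extraction contract table (metadata +
    feature columns) restricted to a single activity; only the top
    ``n_features`` columns of ``ranking`` are used (``ranking=None``
    uses the canonical column order).  Per-fold confusion counts, per-
    fold metrics, their across-fold mean, and every window's single
    out-of-fold prediction are returned.
    """
    feature_names = ranking.feature_names if ranking is not None else list(FEATURE_NAMES)
    unknown = set(feature_names) - set(feature_table.columns)
    if unknown:
        raise ValueError(f"ranking names features absent from the table: {sorted(unknown)}")
    if not (1 <= n_features <= len(feature_names)):
        raise ValueError(f"n_features must be in [1, {len(feature_names)}]")
    activities = feature_table["activity"].unique()
    if len(activities) > 1:
        raise ValueError(
            f"feature table must be restricted to one activity, got {sorted(activities)}"
        )
    columns = (
        top_k(ranking, n_features) if ranking is not None else feature_names[:n_features]
    )
    X = feature_table[columns].to_numpy(dtype=float)
    y = feature_table["lame"].to_numpy(dtype=bool)
    if fold_assignment is None:
        fold_assignment = stratified_kfold(y, k=k_folds, seed=fold_seed)

    fold_counts: list[ConfusionCounts] = []
    fold_metrics: list[MetricSet] = []
    pred = np.zeros(len(y), dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for fold in range(int(fold_assignment.max()) + 1):
            test = fold_assignment == fold
            model = spec.build()
            model.fit(X[~test], y[~test])
            y_hat = model.predict(X[test]).astype(bool)
            pred[test] = y_hat
            counts = ConfusionCounts(
                tp=int(np.sum(y_hat & y[test])),
                tn=int(np.sum(~y_hat & ~y[test])),
                fp=int(np.sum(y_hat & ~y[test])),
                fn=int(np.sum(~y_hat & y[test])),
            )
            fold_counts.append(counts)
            fold_metrics.append(compute_metrics(counts))

    mean_metrics = MetricSet(
        overall_accuracy=float(np.mean([m.overall_accuracy for m in fold_metrics])),
        precision=float(np.mean([m.precision for m in fold_metrics])),
        recall=float(np.mean([m.recall for m in fold_metrics])),
        f_score=float(np.mean([m.f_score for m in fold_metrics])),
        specificity=float(np.mean([m.specificity for m in fold_metrics])),
    )
    predictions = pd.DataFrame(
        {
            "sheep_id": feature_table["sheep_id"].to_numpy(),
            "window_index": feature_table["window_index"].to_numpy(),
            "lame": y,
            "predicted_lame": pred,
            "fold": fold_assignment,
        }
    )
    return CVResult(
        activity=str(activities[0]) if len(activities) else "",
        algorithm=spec.algorithm,
        n_features_used=n_features,
        fold_counts=fold_counts,
        fold_metrics=fold_metrics,
        mean_metrics=mean_metrics,
        predictions=predictions,
    )


def feature_sweep(
    feature_table: pd.DataFrame,
    ranking: RankedFeatures,
    spec: ClassifierSpec,
    n_features_grid: list[int] | None = None,
    k_folds: int = 10,
    fold_seed: int = 0,
) -> list[CVResult]:
    """Accuracy curve over the number of top-ranked features.

    One fold assignment is drawn and reused across every feature count,
    so curve differences reflect the feature set, not fold noise.
    """
    if n_features_grid is None:
        n_features_grid = list(range(1, len(ranking.feature_names) + 1))
    y = feature_table["lame"].to_numpy(dtype=bool)
    fold_assignment = stratified_kfold(y, k=k_folds, seed=fold_seed)
    return [
        run_cv(
            feature_table,
            ranking,
            spec,
            n_features=n,
            k_folds=k_folds,
            fold_assignment=fold_assignment,
        )
        for n in n_features_grid
    ]


class TwoPhasePredictor:
    """The two-phase prediction path: activity first, then lameness.

    Phase 1 classifies the window's activity from the same 32 features;
    phase 2 routes the window to the lameness model trained for that
    activity.  ``oracle_activity`` bypasses phase 1 with ground truth.
    """

    def __init__(self, activity_model, lameness_models: dict[str, object], feature_names: list[str]):
        self.activity_model = activity_model
        self.lameness_models = dict(lameness_models)
        self.feature_names = list(feature_names)

    def predict(
        self, feature_rows: pd.DataFrame, oracle_activity: np.ndarray | None = None
    ) -> pd.DataFrame:
        X = feature_rows[self.feature_names].to_numpy(dtype=float)
        if oracle_activity is not None:
            activities = np.asarray(oracle_activity)
        else:
            activities = self.activity_model.predict(X)
        lame = np.zeros(len(X), dtype=bool)
        for activity in np.unique(activities):
            if activity not in self.lameness_models:
                raise ValueError(f"no lameness model for predicted activity {activity!r}")
            mask = activities == activity
            lame[mask] = self.lameness_models[activity].predict(X[mask]).astype(bool)
        return pd.DataFrame({"activity": activities, "predicted_lame": lame})


def fit_two_phase(
    feature_table: pd.DataFrame,
    spec: ClassifierSpec | None = None,
    feature_names: list[str] | None = None,
) -> TwoPhasePredictor:
    """Train the phase-1 activity model and one lameness model per activity."""
    if spec is None:
        spec = ClassifierSpec("RF")
    if feature_names is None:
        feature_names = list(FEATURE_NAMES)
    X = feature_table[feature_names].to_numpy(dtype=float)
    activity_model = spec.build()
    activity_model.fit(X, feature_table["activity"].to_numpy())
    lameness_models = {}
    for activity, sub in feature_table.groupby("activity"):
        model = spec.build()
        model.fit(sub[feature_names].to_numpy(dtype=float), sub["lame"].to_numpy(dtype=bool))
        lameness_models[str(activity)] = model
    return TwoPhasePredictor(activity_model, lameness_models, feature_names)


def two_phase_predict(
    feature_rows: pd.DataFrame,
    predictor: TwoPhasePredictor,
    oracle_activity: np.ndarray | None = None,
) -> pd.DataFrame:
    """Functional wrapper over :meth:`TwoPhasePredictor.predict`."""
    return predictor.predict(feature_rows, oracle_activity=oracle_activity)
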