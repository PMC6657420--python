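"""Per-event binary classification harness.

For each alteration event, a classifier is trained on expression (or
aggregated) features to predict carrier status: one stratified 75/25
train/test split per repetition, gradient-boosted trees by default, and
held-out-test AUROC as the performance metric.  Repeated splits (or
bootstrap resampling of the training samples) give an AUROC distribution
whose mean and SD summarize the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .containers import ConfigError
from .evaluation import auroc
from .perturb import sweep_seed

logger = logging.getLogger(__name__)

ALGORITHMS = (
    "gradient_boosting",
    "logistic_regression",
    "random_forest",
    "knn",
    "linear_svm",
    "lda",
)

#: Canonical gradient-boosting defaults: 100 trees, depth 3, learning rate
#: 0.1, no subsampling.
GB_DEFAULTS = {"max_iter": 100, "max_depth": 3, "learning_rate": 0.1}


@dataclass
class ModelSpec:
    """Algorithm choice, fixed hyperparameters, and split policy.

    ``hyperparameters`` entries whose values are lists are treated as a
    tuning grid and resolved by ``cv_folds``-fold cross-validation on the
    training partition; scalar entries are passed through as-is.  With the
    fixed defaults nothing is tuned and the model is fit once.
    """

    algorithm: str = "gradient_boosting"
    hyperparameters: dict = field(default_factory=dict)
    cv_folds: int = 10
    train_frac: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ConfigError(
                f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}"
            )
        if not (0 < self.train_frac < 1):
            raise ConfigError(f"train_frac must be in (0,1), got {self.train_frac}")
        if self.cv_folds < 2:
            raise ConfigError(f"cv_folds must be >= 2, got {self.cv_folds}")


@dataclass
class ModelResult:
    event_id: str
    algorithm: str
    test_scores: np.ndarray
    test_labels: np.ndarray
    auroc: float
    rep_index: int
    n_train: int
    n_test: int


@dataclass
class AurocDistribution:
    """AUROCs over repeated splits or bootstraps, with failures counted."""

    event_id: str
    algorithm: str
    aurocs: np.ndarray
    n_failed: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.aurocs))

    @property
    def sd(self) -> float:
        return float(np.std(self.aurocs, ddof=1)) if self.aurocs.size > 1 else 0.0


def _make_estimator(spec: ModelSpec, seed: int):
    hp = {k: v for k, v in spec.hyperparameters.items() if not isinstance(v, list)}
    grid = {k: v for k, v in spec.hyperparameters.items() if isinstance(v, list)}
    if spec.algorithm == "gradient_boosting":
        est = HistGradientBoostingClassifier(**{**GB_DEFAULTS, **hp}, random_state=seed)
    elif spec.algorithm == "logistic_regression":
        est = LogisticRegression(max_iter=2000, **hp)
    elif spec.algorithm == "random_forest":
        est = RandomForestClassifier(n_estimators=hp.pop("n_estimators", 500),
                                     random_state=seed, **hp)
    elif spec.algorithm == "knn":
        est = KNeighborsClassifier(**hp)
    elif spec.algorithm == "linear_svm":
        est = SVC(kernel="linear", random_state=seed, **hp)
    elif spec.algorithm == "lda":
        est = LinearDiscriminantAnalysis(**hp)
    else:  # pragma: no cover - guarded by ModelSpec
        raise ConfigError(f"unknown algorithm {spec.algorithm!r}")
    if grid:
        est = GridSearchCV(est, grid, cv=spec.cv_folds, scoring="roc_auc")
    return est


def _scores(est, X) -> np.ndarray:
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    return est.decision_function(X)


def split_data(
    samples, labels, train_frac: float = 0.75, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test split of sample identifiers.

    |train| = round(train_frac * n); class balance is preserved within one
    sample.  Classes with < 2 members cannot be stratified and raise.
    """
    samples = np.asarray(samples)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ConfigError("both classes must be present to split")
    if counts.min() < 2:
        raise ConfigError(
            f"class {classes[np.argmin(counts)]!r} has < 2 members; cannot stratify"
        )
    n_train = int(round(train_frac * samples.size))
    train, test = train_test_split(
        samples, train_size=n_train, stratify=y, random_state=seed % (2**31)
    )
    return train, test


def train_event_model(
    features: pd.DataFrame,
    labels: pd.Series,
    spec: ModelSpec,
    event_id: str = "event",
    rep_index: int = 0,
) -> ModelResult:
    """Fit one split: train on 75%, score the held-out 25%, report AUROC.

    ``features`` is variables x samples; ``labels`` is a binary Series
    aligned to the feature columns.
    """
    X = features.to_numpy(dtype=np.float64).T  # samples x variables
    if not np.isfinite(X).all():
        raise ValueError("features contain non-finite values")
    y = labels.reindex(features.columns).to_numpy()
    if np.any(pd.isna(y)):
        raise ConfigError("labels missing for some samples")
    y = y.astype(int)
    idx = np.arange(len(y))
    train_idx, test_idx = split_data(idx, y, spec.train_frac, spec.seed)
    if np.unique(y[train_idx]).size < 2:
        raise ConfigError("training partition contains a single class")
    est = _make_estimator(spec, spec.seed)
    est.fit(X[train_idx], y[train_idx])
    scores = _scores(est, X[test_idx])
    return ModelResult(
        event_id=event_id,
        algorithm=spec.algorithm,
        test_scores=scores,
        test_labels=y[test_idx],
        auroc=auroc(scores, y[test_idx]),
        rep_index=rep_index,
        n_train=train_idx.size,
        n_test=test_idx.size,
    )


def repeated_evaluation(
    features: pd.DataFrame,
    labels: pd.Series,
    spec: ModelSpec,
    reps: int = 100,
    event_id: str = "event",
) -> AurocDistribution:
    """AUROC distribution over ``reps`` independent train/test splits.

    Per-rep seeds derive deterministically from ``spec.seed``; degenerate
    repetitions (e.g. a single-class partition) are skipped and counted.
    """
    aurocs, failed = [], 0
    for rep in range(reps):
        rep_spec = ModelSpec(
            algorithm=spec.algorithm,
            hyperparameters=spec.hyperparameters,
            cv_folds=spec.cv_folds,
            train_frac=spec.train_frac,
            seed=sweep_seed(spec.seed, 0, rep),
        )
        try:
            aurocs.append(
                train_event_model(features, labels, rep_spec, event_id, rep).auroc
            )
        except (ConfigError, ValueError) as exc:
            failed += 1
            logger.warning("rep %d failed: %s", rep, exc)
    if not aurocs:
        raise ConfigError("every repetition failed")
    return AurocDistribution(event_id, spec.algorithm, np.array(aurocs), failed)


def bootstrap_evaluation(
    features: pd.DataFrame,
    labels: pd.Series,
    spec: ModelSpec,
    n_boot: int = 100,
    event_id: str = "event",
) -> AurocDistribution:
    """AUROC distribution over bootstrap resamples of the training samples.

    The test partition is fixed by ``spec.seed``; each bootstrap resamples
    the training samples with replacement, refits, and scores the fixed
    test partition.
    """
    X = features.to_numpy(dtype=np.float64).T
    if not np.isfinite(X).all():
        raise ValueError("features contain non-finite values")
    y = labels.reindex(features.columns).to_numpy().astype(int)
    idx = np.arange(len(y))
    train_idx, test_idx = split_data(idx, y, spec.train_frac, spec.seed)
    rng = np.random.default_rng(spec.seed)
    aurocs, failed = [], 0
    for bi in range(n_boot):
        boot = rng.choice(train_idx, size=train_idx.size, replace=True)
        if np.unique(y[boot]).size < 2:
            failed += 1
            continue
        est = _make_estimator(spec, sweep_seed(spec.seed, 1, bi))
        est.fit(X[boot], y[boot])
        aurocs.append(auroc(_scores(est, X[test_idx]), y[test_idx]))
    if not aurocs:
        raise ConfigError("every bootstrap failed (single-class resamples)")
    return AurocDistribution(event_id, spec.algorithm, np.array(aurocs), failed)
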