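"""Univariate feature selection and ensemble-classifier training.

Features are scored by the one-way ANOVA F statistic across activity labels
(between-group over within-group mean squares, computed from its definition),
the top-k (default 20) are retained, and a random-forest, gradient-boosting
or XGBoost classifier is tuned by stratified 10-fold cross-validation over a
strided (n_estimators, max_depth) grid and refitted on the full training
partition. Selection is always fitted on the training partition only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from xgboost import XGBClassifier

logger = logging.getLogger(__name__)

FAMILIES = ("random_forest", "gradient_boosting", "extreme_gradient_boosting")

#: strided sub-grids of the tuning ranges 1-100 x 1-30 (RF), 1-50 x 1-14
#: (GBoost) and 1-100 x 1-30 (XGBoost), each containing the reported optimum
#: of its family: RF (98, 21), GBoost (50, 8), XGBoost (83, 10).
DEFAULT_GRIDS: dict[str, list[tuple[int, int]]] = {
    "random_forest": [
        (n, d) for n in (14, 28, 42, 56, 70, 84, 98) for d in (1, 6, 11, 16, 21, 26)
    ],
    "gradient_boosting": [
        (n, d) for n in (10, 20, 30, 40, 50) for d in (2, 4, 6, 8, 10, 12, 14)
    ],
    "extreme_gradient_boosting": [
        (n, d) for n in (21, 41, 62, 83) for d in (2, 6, 10, 14, 18, 22, 26, 30)
    ],
}


@dataclass
class SelectionResult:
    scores: dict[str, float]
    selected: list[str]
    k: int


@dataclass(frozen=True)
class ModelSpec:
    family: str
    n_estimators: int
    max_depth: int
    seed: int = 0

    def validate(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.n_estimators < 1 or self.max_depth < 1:
            raise ValueError("n_estimators and max_depth must be >= 1")


@dataclass
class TrainedModel:
    spec: ModelSpec
    feature_names: list[str]
    estimator: object
    classes: list[str]
    metadata: dict = field(default_factory=dict)

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        """Class probabilities, columns ordered as ``self.classes``."""
        X = table[self.feature_names].to_numpy()
        proba = self.estimator.predict_proba(X)
        order = [list(self.estimator.classes_).index(self._enc(c)) for c in self.classes]
        return proba[:, order]

    def predict(self, table: pd.DataFrame) -> list[str]:
        proba = self.predict_proba(table)
        return [self.classes[i] for i in proba.argmax(axis=1)]

    def _enc(self, label: str):
        # XGBoost needs integer-encoded labels; others take strings
        return self.classes.index(label) if self.spec.family == "extreme_gradient_boosting" else label


def _split_xy(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    if "label" not in table.columns:
        raise ValueError("feature table must have a 'label' column")
    return table.drop(columns="label"), table["label"]


def anova_f_scores(X: pd.DataFrame, y: pd.Series) -> dict[str, float]:
    """One-way ANOVA F per feature, from its definition.

    F = between-group mean square / within-group mean square, with g-1 and
    n-g degrees of freedom. Constant features score 0; a perfect separator
    (zero within-group variance, positive between) scores +inf.
    """
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValueError("need at least two classes to score features")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 rows")
    n, g = len(y), len(classes)
    scores: dict[str, float] = {}
    vals = X.to_numpy(dtype=float)
    grand = vals.mean(axis=0)
    ss_between = np.zeros(vals.shape[1])
    ss_within = np.zeros(vals.shape[1])
    for c in classes:
        m = (y == c).to_numpy()
        gm = vals[m].mean(axis=0)
        ss_between += m.sum() * (gm - grand) ** 2
        ss_within += ((vals[m] - gm) ** 2).sum(axis=0)
    ms_between = ss_between / (g - 1)
    ms_within = ss_within / (n - g)
    for j, name in enumerate(X.columns):
        if ms_between[j] <= 0:
            scores[name] = 0.0
        elif ms_within[j] <= 0:
            scores[name] = float("inf")
        else:
            scores[name] = float(ms_between[j] / ms_within[j])
    return scores


def score_features(table: pd.DataFrame, k: int = 20) -> SelectionResult:
    X, y = _split_xy(table)
    scores = anova_f_scores(X, y)
    finite_or_inf = [f for f in X.columns if not np.isnan(scores[f])]
    order = {f: i for i, f in enumerate(X.columns)}
    ranked = sorted(finite_or_inf, key=lambda f: (-scores[f], order[f]))
    selected = ranked[: min(k, len(ranked))]
    return SelectionResult(scores=scores, selected=selected, k=k)


def select_top_k(
    table: pd.DataFrame, k: int = 20, result: SelectionResult | None = None
) -> pd.DataFrame:
    """Restrict the table to the k best-scoring features plus the label.

    Ties break by original column order for reproducibility. ``k`` larger
    than the feature count keeps everything with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X, _ = _split_xy(table)
    if k > X.shape[1]:
        logger.warning("k=%d exceeds feature count %d; keeping all", k, X.shape[1])
        k = X.shape[1]
    if result is None or result.k != k:
        result = score_features(table, k)
    return table[result.selected[:k] + ["label"]].copy()


def split_train_test(
    table: pd.DataFrame, test_fraction: float = 0.2, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test split, deterministic under seed."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    _, y = _split_xy(table)
    train, test = train_test_split(
        table, test_size=test_fraction, stratify=y, random_state=seed
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)


def build_estimator(spec: ModelSpec):
    spec.validate()
    if spec.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=spec.n_estimators, max_depth=spec.max_depth,
            random_state=spec.seed, n_jobs=1,
        )
    if spec.family == "gradient_boosting":
        return GradientBoostingClassifier(
            n_estimators=spec.n_estimators, max_depth=spec.max_depth,
            random_state=spec.seed,
        )
    return XGBClassifier(
        n_estimators=spec.n_estimators, max_depth=spec.max_depth,
        random_state=spec.seed, n_jobs=1, verbosity=0,
    )


def cross_val_accuracy(
    table: pd.DataFrame, spec: ModelSpec, folds: int = 10, seed: int = 0
) -> float:
    """Mean stratified k-fold CV accuracy of ``spec`` on ``table``."""
    X, y = _split_xy(table)
    counts = y.value_counts()
    if folds > counts.min():
        raise ValueError(
            f"folds={folds} exceeds the smallest class size ({counts.min()})"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    classes = sorted(y.unique())
    y_enc = y.map(classes.index) if spec.family == "extreme_gradient_boosting" else y
    accs = []
    Xv, yv = X.to_numpy(), y_enc.to_numpy()
    for tr, te in skf.split(Xv, yv):
        est = build_estimator(spec)
        est.fit(Xv[tr], yv[tr])
        accs.append(float(np.mean(est.predict(Xv[te]) == yv[te])))
    return float(np.mean(accs))


def tune_hyperparameters(
    train: pd.DataFrame,
    family: str = "random_forest",
    grid: list[tuple[int, int]] | None = None,
    folds: int = 10,
    seed: int = 0,
) -> ModelSpec:
    """Spec maximizing mean CV accuracy; ties go to the smaller model
    (fewer estimators, then shallower trees)."""
    if family not in FAMILIES:
        raise ValueError(f"unknown model family {family!r}")
    grid = grid if grid is not None else DEFAULT_GRIDS[family]
    if not grid:
        raise ValueError("empty hyperparameter grid")
    results = []
    for n, d in grid:
        spec = ModelSpec(family, n, d, seed)
        acc = cross_val_accuracy(train, spec, folds, seed)
        results.append((acc, n, d))
    results.sort(key=lambda t: (-t[0], t[1], t[2]))
    best_acc, n, d = results[0]
    logger.info("tuned %s: n_estimators=%d max_depth=%d (CV acc %.4f over %d specs)",
                family, n, d, best_acc, len(grid))
    return ModelSpec(family, n, d, seed)


def train(train_table: pd.DataFrame, spec: ModelSpec, folds: int = 10) -> TrainedModel:
    """Fit a four-class probabilistic classifier; deterministic under seed."""
    spec.validate()
    X, y = _split_xy(train_table)
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValueError("training data has a single class")
    y_fit = y.map(classes.index) if spec.family == "extreme_gradient_boosting" else y
    est = build_estimator(spec)
    est.fit(X.to_numpy(), y_fit.to_numpy())
    return TrainedModel(
        spec=spec, feature_names=list(X.columns), estimator=est, classes=classes,
        metadata={"n_train": len(train_table), "cv_folds": folds, "seed": spec.seed},
    )


def cross_val_proba(
    table: pd.DataFrame, spec: ModelSpec, folds: int = 10, seed: int = 0
) -> tuple[list[str], np.ndarray]:
    """Pooled out-of-fold class probabilities (for cross-validated ROC)."""
    X, y = _split_xy(table)
    classes = sorted(y.unique())
    y_enc = y.map(classes.index) if spec.family == "extreme_gradient_boosting" else y
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    proba = np.zeros((len(table), len(classes)))
    Xv, yv = X.to_numpy(), y_enc.to_numpy()
    for tr, te in skf.split(Xv, yv):
        est = build_estimator(spec)
        est.fit(Xv[tr], yv[tr])
        p = est.predict_proba(Xv[te])
        order = [
            list(est.classes_).index(c if spec.family != "extreme_gradient_boosting" else i)
            for i, c in enumerate(classes)
        ]
        proba[te] = p[:, order]
    return list(y), proba
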