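"""Gradient-boosted slide triage on the four aggregation features.

Model selection follows the screening pipeline's protocol: a small
hyperparameter grid is scored by stratified fivefold cross-validated
accuracy, the best combination (ties broken towards the smallest ensemble)
is refitted on the full training set, and slides are called high-risk when
the predicted probability reaches a configurable decision threshold
(default 0.7; the threshold trades sensitivity against specificity and is
meant to be tuned to the deployment's screening needs).

Fitted models serialize to a versioned JSON document (trees as nested
split records) so predictions are reproducible across platforms without
pickles.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigError, InputError
from .types import FEATURE_COLUMNS, RiskLabel

MODEL_FORMAT_VERSION = 1


def _default_grid() -> dict[str, list]:
    return {
        "n_estimators": [50, 200],
        "max_depth": [2, 3],
        "learning_rate": [0.1, 0.3],
        "min_samples_leaf": [1, 5],
    }


@dataclass
class ClassifierConfig:
    """Cross-validation and decision settings for the slide classifier."""

    n_folds: int = 5
    grid: dict[str, list] = field(default_factory=_default_grid)
    decision_threshold: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ConfigError("hyperparameter grid must be non-empty")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ConfigError("decision_threshold must lie in (0, 1)")


def _as_xy(
    features: pd.DataFrame, labels: pd.Series | dict | None
) -> tuple[np.ndarray, np.ndarray | None, list[str]]:
    x = features.loc[:, list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise InputError("feature matrix contains non-finite values")
    y = None
    if labels is not None:
        if isinstance(labels, dict):
            labels = pd.Series(labels)
        aligned = labels.reindex(features["slide_id"])
        if aligned.isna().any():
            missing = aligned[aligned.isna()].index.tolist()
            raise InputError(f"labels missing for slides: {missing}")
        y = np.array([1 if RiskLabel(v) is RiskLabel.HIGH else 0 for v in aligned])
    return x, y, list(features["slide_id"])


def _check_classes(y: np.ndarray, n_folds: int) -> None:
    counts = np.bincount(y, minlength=2)
    if counts[0] == 0 or counts[1] == 0:
        raise InputError("both risk classes must be present in the labels")
    if counts.min() < n_folds:
        raise InputError(
            f"need >= {n_folds} slides per class for {n_folds}-fold "
            f"stratification, got {counts.tolist()}"
        )


def cross_validate_select(
    features: pd.DataFrame,
    labels: pd.Series | dict,
    config: ClassifierConfig | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Grid-search hyperparameters by stratified k-fold CV accuracy.

    Returns the winning hyperparameters and a report with one row per grid
    point (mean accuracy plus per-fold accuracies). The argmax tie-break
    prefers fewer trees, then shallower trees, then grid order.
    Deterministic given ``config.seed``.
    """
    config = config or ClassifierConfig()
    x, y, _ = _as_xy(features, labels)
    _check_classes(y, config.n_folds)
    cv = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    folds = list(cv.split(x, y))
    keys = list(config.grid.keys())
    rows = []
    for combo in itertools.product(*(config.grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        fold_acc = []
        for train_idx, test_idx in folds:
            clf = GradientBoostingClassifier(random_state=config.seed, **params)
            clf.fit(x[train_idx], y[train_idx])
            fold_acc.append(float((clf.predict(x[test_idx]) == y[test_idx]).mean()))
        rows.append({**params, "mean_accuracy": float(np.mean(fold_acc)),
                     "fold_accuracies": fold_acc})
    report = pd.DataFrame(rows)
    best = report.sort_values(
        ["mean_accuracy", "n_estimators", "max_depth"],
        ascending=[False, True, True],
        kind="stable",
    ).iloc[0]
    chosen = {k: best[k] for k in keys}
    # numpy scalars -> plain python for JSON round-trips
    chosen = {k: (v.item() if hasattr(v, "item") else v) for k, v in chosen.items()}
    return chosen, report


@dataclass
class TrainedSlideClassifier:
    """A finalized boosted-tree ensemble over the four slide features."""

    model: GradientBoostingClassifier
    hyperparameters: dict
    cv_accuracies: list[float] | None = None
    training_set_id: str = ""
    feature_names: tuple[str, ...] = FEATURE_COLUMNS

    def predict_proba_high(self, features: pd.DataFrame) -> np.ndarray:
        x, _, _ = _as_xy(features, None)
        return self.model.predict_proba(x)[:, 1]


def fit_final(
    features: pd.DataFrame,
    labels: pd.Series | dict,
    hyperparameters: dict,
    seed: int = 0,
    training_set_id: str = "",
) -> TrainedSlideClassifier:
    """Refit the selected model on the entire training set."""
    x, y, _ = _as_xy(features, labels)
    counts = np.bincount(y, minlength=2)
    if counts[0] == 0 or counts[1] == 0:
        raise InputError("cannot fit a classifier on single-class labels")
    clf = GradientBoostingClassifier(random_state=seed, **hyperparameters)
    clf.fit(x, y)
    return TrainedSlideClassifier(
        model=clf, hyperparameters=dict(hyperparameters), training_set_id=training_set_id
    )


def predict_risk(
    clf: "TrainedSlideClassifier | JsonBoostedModel",
    features: pd.DataFrame,
    threshold: float = 0.7,
) -> pd.DataFrame:
    """Per-slide probability of high risk and the thresholded label.

    A slide is called high-risk iff ``probability_high >= threshold``
    (boundary inclusive), so lowering the threshold can only enlarge the
    predicted high-risk set.
    """
    if not 0.0 < threshold < 1.0:
        raise InputError("threshold must lie in (0, 1)")
    proba = clf.predict_proba_high(features)
    labels = [
        RiskLabel.HIGH.value if p >= threshold else RiskLabel.LOW.value for p in proba
    ]
    return pd.DataFrame(
        {
            "slide_id": list(features["slide_id"]),
            "probability_high": proba,
            "label": labels,
        }
    )


# ----------------------------------------------------------- persistence ---

def _export_tree(tree) -> dict:
    t = tree.tree_
    return {
        "children_left": t.children_left.tolist(),
        "children_right": t.children_right.tolist(),
        "feature": t.feature.tolist(),
        "threshold": t.threshold.tolist(),
        "value": t.value[:, 0, 0].tolist(),
    }


def save_model(clf: TrainedSlideClassifier, path: str | Path) -> None:
    """Persist the ensemble as a versioned JSON document."""
    model = clf.model
    init_raw = float(model._raw_predict_init(np.zeros((1, len(clf.feature_names))))[0, 0])
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "feature_names": list(clf.feature_names),
        "hyperparameters": clf.hyperparameters,
        "learning_rate": float(model.learning_rate),
        "init_raw": init_raw,
        "trees": [_export_tree(est[0]) for est in model.estimators_],
        "training_set_id": clf.training_set_id,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True) + "\n")


class JsonBoostedModel:
    """Pure-numpy predictor for a JSON-serialized boosted-tree ensemble."""

    def __init__(self, doc: dict) -> None:
        if doc.get("format_version") != MODEL_FORMAT_VERSION:
            raise InputError(
                f"unsupported model format version {doc.get('format_version')!r}"
            )
        self.feature_names = tuple(doc["feature_names"])
        self.hyperparameters = doc["hyperparameters"]
        self.learning_rate = float(doc["learning_rate"])
        self.init_raw = float(doc["init_raw"])
        self.trees = doc["trees"]

    def _tree_predict(self, tree: dict, x: np.ndarray) -> np.ndarray:
        left = tree["children_left"]
        right = tree["children_right"]
        feat = tree["feature"]
        thr = tree["threshold"]
        value = tree["value"]
        out = np.empty(x.shape[0])
        for i in range(x.shape[0]):
            node = 0
            while left[node] != -1:
                node = left[node] if x[i, feat[node]] <= thr[node] else right[node]
            out[i] = value[node]
        return out

    def predict_proba_high(self, features: pd.DataFrame) -> np.ndarray:
        x, _, _ = _as_xy(features, None)
        raw = np.full(x.shape[0], self.init_raw)
        for tree in self.trees:
            raw += self.learning_rate * self._tree_predict(tree, x)
        return expit(raw)


def load_model(path: str | Path) -> JsonBoostedModel:
    return JsonBoostedModel(json.loads(Path(path).read_text()))
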