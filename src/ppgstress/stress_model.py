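"""Three-level stress classification from HRV features.

A CART decision tree maps a 34-feature HRV vector to a stress state in
{0: none, 1: moderate, 2: severe}. The tree is chosen for interpretability
and negligible inference cost, which suits a 30-s recompute cycle.
Hyperparameters follow the reference configuration: maximum depth 10,
minimum 10 samples to split, minimum 5 samples per leaf, Gini impurity.

The estimator wraps scikit-learn's ``DecisionTreeClassifier`` for growth but
predicts by an explicit root-to-leaf descent over the exported node arrays,
so that a freshly fitted model and one loaded from its JSON archive share
the same code path, and leaf ties resolve deterministically toward the
lower class index.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .errors import SchemaError
from .hrv_features import FEATURE_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "TreeHyperparams",
    "StressTreeClassifier",
    "EvalReport",
    "train",
    "predict",
    "evaluate",
    "split_train_test",
]

_ARCHIVE_FORMAT = "ppgstress-tree"
_ARCHIVE_VERSION = 1


@dataclass(frozen=True)
class TreeHyperparams:
    """CART growth constraints (reference defaults)."""

    max_depth: int = 10
    min_samples_split: int = 10
    min_samples_leaf: int = 5
    split_criterion: str = "gini"
    seed: int = 0

    def __post_init__(self):
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.min_samples_split < 2:
            raise ValueError("min_samples_split must be >= 2")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")


@dataclass
class EvalReport:
    """Held-out classification metrics over the three stress classes."""

    accuracy: float
    precision: np.ndarray  # per class 0, 1, 2
    recall: np.ndarray
    f1: np.ndarray
    confusion: np.ndarray  # 3x3, rows = true class
    flags: tuple[str, ...] = ()


def _as_matrix(X) -> np.ndarray:
    """Validate feature input: canonical columns if a DataFrame, 34 columns."""
    if isinstance(X, pd.DataFrame):
        cols = list(X.columns)
        if cols != list(FEATURE_NAMES):
            missing = sorted(set(FEATURE_NAMES) - set(cols))
            extra = sorted(set(cols) - set(FEATURE_NAMES))
            raise SchemaError(
                f"feature columns must be the canonical 34 names in order; "
                f"missing={missing}, unexpected={extra}"
            )
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.shape[1] != len(FEATURE_NAMES):
        raise ValueError(f"expected {len(FEATURE_NAMES)} features, got {X.shape[1]}")
    bad = ~np.isfinite(X).all(axis=1)
    if bad.any():
        rows = np.flatnonzero(bad).tolist()
        raise ValueError(f"non-finite feature values in rows {rows}")
    return X


class StressTreeClassifier(ClassifierMixin, BaseEstimator):
    """scikit-learn style CART classifier for the 3 stress states.

    Parameters mirror :class:`TreeHyperparams`; ``random_state`` makes the
    grown tree deterministic given identical training data and row order.

    Fitted attributes
    -----------------
    classes_ : ndarray
        Sorted class labels seen in training (subset of {0, 1, 2}).
    tree_nodes_ : dict of ndarray
        Exported node arrays (feature, threshold, children, leaf counts)
        used for prediction and persistence.
    """

    def __init__(
        self,
        max_depth: int = 10,
        min_samples_split: int = 10,
        min_samples_leaf: int = 5,
        criterion: str = "gini",
        random_state: int = 0,
    ):
        self.max_depth = max_depth
        self.min_samples_split = min_samples_split
        self.min_samples_leaf = min_samples_leaf
        self.criterion = criterion
        self.random_state = random_state

    def fit(self, X, y):
        Xm = _as_matrix(X)
        y = np.asarray(y)
        if Xm.shape[0] != y.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        labels = np.unique(y)
        if not np.isin(labels, [0, 1, 2]).all():
            raise ValueError(f"labels must be in {{0, 1, 2}}, got {labels.tolist()}")
        if labels.size < 3:
            warnings.warn(
                f"training data contains only classes {labels.tolist()}; "
                "the model cannot predict absent classes",
                stacklevel=2,
            )
        tree = DecisionTreeClassifier(
            criterion=self.criterion,
            max_depth=self.max_depth,
            min_samples_split=self.min_samples_split,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.random_state,
        ).fit(Xm, y.astype(int))
        t = tree.tree_
        self.classes_ = tree.classes_.astype(int)
        self.n_features_in_ = Xm.shape[1]
        self.feature_names_in_ = np.asarray(FEATURE_NAMES, dtype=object)
        self.tree_nodes_ = {
            "feature": t.feature.copy(),
            "threshold": t.threshold.copy(),
            "left": t.children_left.copy(),
            "right": t.children_right.copy(),
            "value": t.value[:, 0, :].copy() * t.n_node_samples[:, None],
        }
        self.depth_ = int(tree.get_depth())
        self.n_leaves_ = int(tree.get_n_leaves())
        if self.n_leaves_ == 1:
            warnings.warn(
                "growth constraints allowed no split; model is a single-leaf "
                "majority predictor",
                stacklevel=2,
            )
        return self

    def _descend(self, Xm: np.ndarray) -> np.ndarray:
        nodes = self.tree_nodes_
        out = np.empty(Xm.shape[0], dtype=int)
        for i, row in enumerate(Xm):
            node = 0
            while nodes["left"][node] != -1:
                if row[nodes["feature"][node]] <= nodes["threshold"][node]:
                    node = nodes["left"][node]
                else:
                    node = nodes["right"][node]
            counts = nodes["value"][node]
            out[i] = self.classes_[int(np.argmax(counts))]  # ties -> lower class
        return out

    def predict(self, X):
        check_is_fitted(self, "tree_nodes_")
        return self._descend(_as_matrix(X))

    def save(self, path: str | Path) -> None:
        """Persist as a self-describing JSON archive.

        The archive stores node arrays, the canonical feature order, the
        hyperparameters, and a hash of feature order + hyperparameters so a
        feature-order mismatch at predict time is detected, not silent.
        """
        check_is_fitted(self, "tree_nodes_")
        hp = self.get_params()
        payload = {
            "format": _ARCHIVE_FORMAT,
            "version": _ARCHIVE_VERSION,
            "feature_order": list(FEATURE_NAMES),
            "hyperparams": hp,
            "classes": self.classes_.tolist(),
            "nodes": {k: np.asarray(v).tolist() for k, v in self.tree_nodes_.items()},
        }
        payload["config_hash"] = hashlib.sha256(
            json.dumps([payload["feature_order"], hp], sort_keys=True).encode()
        ).hexdigest()
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "StressTreeClassifier":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != _ARCHIVE_FORMAT:
            raise SchemaError(f"{path}: not a {_ARCHIVE_FORMAT} archive")
        if payload["feature_order"] != list(FEATURE_NAMES):
            raise SchemaError(
                f"{path}: archive feature order does not match the canonical "
                "34-name order"
            )
        expect = hashlib.sha256(
            json.dumps(
                [payload["feature_order"], payload["hyperparams"]], sort_keys=True
            ).encode()
        ).hexdigest()
        if payload.get("config_hash") != expect:
            raise SchemaError(f"{path}: archive hash mismatch; file corrupted")
        model = cls(**payload["hyperparams"])
        model.classes_ = np.asarray(payload["classes"], dtype=int)
        model.n_features_in_ = len(FEATURE_NAMES)
        model.feature_names_in_ = np.asarray(FEATURE_NAMES, dtype=object)
        nodes = payload["nodes"]
        model.tree_nodes_ = {
            "feature": np.asarray(nodes["feature"], dtype=int),
            "threshold": np.asarray(nodes["threshold"], dtype=float),
            "left": np.asarray(nodes["left"], dtype=int),
            "right": np.asarray(nodes["right"], dtype=int),
            "value": np.asarray(nodes["value"], dtype=float),
        }
        model.n_leaves_ = int(np.sum(model.tree_nodes_["left"] == -1))
        return model


def _split_table(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    if "label" not in table.columns:
        raise ValueError("feature table has no 'label' column; cannot train/evaluate")
    X = table[list(FEATURE_NAMES)]
    y = table["label"].to_numpy(dtype=int)
    return X, y


def train(
    table: pd.DataFrame, hp: TreeHyperparams | None = None
) -> StressTreeClassifier:
    """Train a stress tree on a labeled canonical feature table."""
    hp = hp or TreeHyperparams()
    X, y = _split_table(table)
    model = StressTreeClassifier(
        max_depth=hp.max_depth,
        min_samples_split=hp.min_samples_split,
        min_samples_leaf=hp.min_samples_leaf,
        criterion=hp.split_criterion,
        random_state=hp.seed,
    )
    return model.fit(X, y)


def predict(model: StressTreeClassifier, x) -> int | np.ndarray:
    """Predict the stress label for one feature vector (or a batch).

    A vector with non-finite entries raises; features are never imputed.
    """
    single = (
        isinstance(x, (pd.Series, dict))
        or (np.asarray(x, dtype=object).ndim == 1 and not isinstance(x, pd.DataFrame))
    )
    if isinstance(x, dict):
        x = np.array([x[name] for name in FEATURE_NAMES], dtype=float)
    elif isinstance(x, pd.Series):
        x = x.reindex(list(FEATURE_NAMES)).to_numpy(dtype=float)
    preds = model.predict(x)
    return int(preds[0]) if single else preds


def evaluate(model: StressTreeClassifier, test: pd.DataFrame) -> EvalReport:
    """Accuracy, per-class precision/recall/F1 and the 3x3 confusion matrix."""
    X, y = _split_table(test)
    if len(test) == 0:
        raise ValueError("test table is empty")
    preds = model.predict(X)
    cm = confusion_matrix(y, preds, labels=[0, 1, 2])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prec, rec, f1, support = precision_recall_fscore_support(
            y, preds, labels=[0, 1, 2], zero_division=0
        )
    flags = tuple(
        f"class_{c}_zero_support" for c, s in zip((0, 1, 2), support) if s == 0
    )
    return EvalReport(
        accuracy=float(np.trace(cm) / np.sum(cm)),
        precision=prec,
        recall=rec,
        f1=f1,
        confusion=cm,
        flags=flags,
    )


def split_train_test(
    table: pd.DataFrame, test_fraction: float, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified, seed-reproducible train/test partition of a labeled table."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    _, y = _split_table(table)
    counts = pd.Series(y).value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(
            f"classes with fewer than 2 rows cannot be stratified: "
            f"{small.index.tolist()}"
        )
    train_df, test_df = train_test_split(
        table, test_size=test_fraction, random_state=seed, stratify=y
    )
    return train_df, test_df
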