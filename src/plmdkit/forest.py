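"""Random forest for sleep-posture classification, written from scratch.

The ensemble follows the classical recipe, decomposed exactly the way the
streaming datapath realises it: per tree, (1) a bootstrap resample of the
training set, (2) a random feature subset of size ``m`` drawn without
replacement from the ``M`` features, (3) a CART-style tree grown fully with
no pruning on that resample restricted to that subset, and (4) a majority
vote across the ``T`` trees at prediction time.

Determinism is a contract, not an accident: one seeded generator drives the
whole training run (per tree: bootstrap indices first, then the feature
subset), split ties break toward the lowest feature index and then the lowest
threshold, and vote ties break toward the lowest class in the fixed class
order — so equal inputs reproduce bit-identical forests and predictions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Dataset", "ForestConfig", "DecisionTree", "Forest", "VoteTally",
    "bootstrap_sample", "select_features", "grow_tree", "train_forest",
    "forest_predict",
]


@dataclass
class Dataset:
    """Feature matrix X (n, M), integer class labels y, fixed class order."""

    X: np.ndarray
    y: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (instances x features)")
        if len(self.X) != len(self.y):
            raise ValueError("X and y length mismatch")
        if len(self.X) < 1:
            raise ValueError("dataset must hold at least one instance")
        if self.y.min(initial=0) < 0 or self.y.max(initial=0) >= len(self.classes):
            raise ValueError("labels must index into classes")

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @classmethod
    def from_labelled(cls, X: np.ndarray, labels: list[str],
                      classes: tuple[str, ...] | None = None) -> "Dataset":
        if classes is None:
            classes = tuple(sorted(set(labels)))
        index = {c: i for i, c in enumerate(classes)}
        y = np.array([index[l] for l in labels], dtype=np.int64)
        return cls(X=X, y=y, classes=tuple(classes))


@dataclass(frozen=True)
class ForestConfig:
    """T trees, m features per tree (default ceil(sqrt(M))), one seed."""

    n_trees: int = 10
    n_features: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.n_features is not None and self.n_features < 1:
            raise ValueError("n_features must be >= 1")

    def resolve_m(self, M: int) -> int:
        m = self.n_features if self.n_features is not None else math.ceil(math.sqrt(M))
        if m > M:
            raise ValueError(f"n_features ({m}) exceeds feature count ({M})")
        return m


class DecisionTree:
    """Binary CART tree stored as parallel node arrays.

    Internal nodes test ``x[feature] <= threshold`` (left on true); leaves
    carry a class label.  Grown fully: recursion stops only when a node is
    pure or no non-trivial split exists among the assigned features.
    """

    def __init__(self) -> None:
        self.feature: list[int] = []
        self.threshold: list[float] = []
        self.left: list[int] = []
        self.right: list[int] = []
        self.label: list[int] = []

    def _add_node(self) -> int:
        self.feature.append(-1)
        self.threshold.append(0.0)
        self.left.append(-1)
        self.right.append(-1)
        self.label.append(-1)
        return len(self.feature) - 1

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    def predict_one(self, x: np.ndarray) -> int:
        node = 0
        while self.feature[node] >= 0:
            if x[self.feature[node]] <= self.threshold[node]:
                node = self.left[node]
            else:
                node = self.right[node]
        return self.label[node]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.array([self.predict_one(x) for x in X], dtype=np.int64)

    def used_features(self) -> set[int]:
        return {f for f in self.feature if f >= 0}

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "threshold": self.threshold,
            "left": self.left,
            "right": self.right,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionTree":
        t = cls()
        t.feature = [int(v) for v in d["feature"]]
        t.threshold = [float(v) for v in d["threshold"]]
        t.left = [int(v) for v in d["left"]]
        t.right = [int(v) for v in d["right"]]
        t.label = [int(v) for v in d["label"]]
        return t


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p * p).sum())


def _majority(y: np.ndarray, n_classes: int) -> int:
    # np.argmax returns the first maximum -> lowest class wins ties.
    return int(np.argmax(np.bincount(y, minlength=n_classes)))


def _best_split(X: np.ndarray, y: np.ndarray, features: np.ndarray,
                n_classes: int) -> tuple[int, float] | None:
    """Best (feature, threshold) by Gini gain over candidate midpoints.

    Candidates are midpoints between consecutive distinct sorted values.
    Ties break toward the lowest feature index, then the lowest threshold
    (features are scanned ascending, thresholds ascending, and only a
    strictly better gain replaces the incumbent).  Returns None when no
    feature admits a non-trivial split.
    """
    n = len(y)
    parent = _gini(np.bincount(y, minlength=n_classes))
    best: tuple[float, int, float] | None = None  # (gain, feature, threshold)
    for f in np.sort(features):
        xs = X[:, f]
        order = np.argsort(xs, kind="stable")
        xs_s = xs[order]
        ys_s = y[order]
        distinct = np.nonzero(xs_s[1:] > xs_s[:-1])[0]  # split after index i
        if distinct.size == 0:
            continue
        onehot = np.zeros((n, n_classes), dtype=np.int64)
        onehot[np.arange(n), ys_s] = 1
        cum = np.cumsum(onehot, axis=0)
        total = cum[-1]
        for i in distinct:
            left_counts = cum[i]
            right_counts = total - left_counts
            nl = i + 1
            nr = n - nl
            weighted = (nl * _gini(left_counts) + nr * _gini(right_counts)) / n
            gain = parent - weighted
            thr = (xs_s[i] + xs_s[i + 1]) / 2.0
            if best is None or gain > best[0] + 1e-12:
                best = (gain, int(f), thr)
    if best is None:
        return None
    return best[1], best[2]


def grow_tree(X: np.ndarray, y: np.ndarray, features: np.ndarray | None = None,
              n_classes: int | None = None) -> DecisionTree:
    """Grow a fully-grown, unpruned CART tree on the given feature subset.

    Splitting criterion is Gini impurity; a node is split as long as it is
    impure and some assigned feature still varies within it (the best-gain
    split is taken even when the gain is zero), so every leaf is either pure
    or holds only conflicting duplicates.  Deterministic given its inputs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    if X.ndim != 2 or len(X) != len(y) or len(y) == 0:
        raise ValueError("grow_tree needs a non-empty (X, y) sample")
    if features is None:
        features = np.arange(X.shape[1])
    features = np.asarray(features, dtype=np.int64)
    if n_classes is None:
        n_classes = int(y.max()) + 1

    tree = DecisionTree()

    def build(idx: np.ndarray) -> int:
        node = tree._add_node()
        ys = y[idx]
        counts = np.bincount(ys, minlength=n_classes)
        if np.count_nonzero(counts) <= 1:
            tree.label[node] = _majority(ys, n_classes)
            return node
        split = _best_split(X[idx], ys, features, n_classes)
        if split is None:  # conflicting duplicates: all features constant
            tree.label[node] = _majority(ys, n_classes)
            return node
        f, thr = split
        mask = X[idx, f] <= thr
        tree.feature[node] = f
        tree.threshold[node] = thr
        tree.left[node] = build(idx[mask])
        tree.right[node] = build(idx[~mask])
        return node

    build(np.arange(len(y)))
    return tree


def bootstrap_sample(data: Dataset, rng: np.random.Generator) -> tuple[Dataset, np.ndarray]:
    """n draws with replacement from the dataset; returns (resample, indices)."""
    if data.n < 1:
        raise ValueError("cannot bootstrap an empty dataset")
    idx = rng.integers(0, data.n, size=data.n)
    return Dataset(X=data.X[idx], y=data.y[idx], classes=data.classes), idx


def select_features(M: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """m distinct feature indices drawn uniformly without replacement,
    returned in ascending order."""
    if not 1 <= m <= M:
        raise ValueError("need 1 <= m <= M")
    return np.sort(rng.choice(M, size=m, replace=False))


@dataclass(frozen=True)
class VoteTally:
    """Per-class vote counts and the majority winner (ties -> lowest class)."""

    counts: tuple[int, ...]
    winner: int
    classes: tuple[str, ...]

    @property
    def winner_label(self) -> str:
        return self.classes[self.winner]

    def as_dict(self) -> dict[str, int]:
        return {c: n for c, n in zip(self.classes, self.counts) if n > 0}


@dataclass
class Forest:
    """T (tree, feature subset) pairs plus the class order they vote over."""

    trees: list[DecisionTree]
    subsets: list[np.ndarray]
    classes: tuple[str, ...]
    config: ForestConfig = field(default_factory=ForestConfig)
    n_features: int = 0

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def predict(self, x: np.ndarray) -> tuple[str, VoteTally]:
        return forest_predict(self, x)

    def predict_batch(self, X: np.ndarray) -> list[str]:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        votes = np.stack([t.predict(X) for t in self.trees])  # (T, n)
        out = []
        for col in votes.T:
            counts = np.bincount(col, minlength=len(self.classes))
            out.append(self.classes[int(np.argmax(counts))])
        return out

    def to_json(self) -> str:
        doc = {
            "format": "plmdkit-forest",
            "version": 1,
            "n_features": self.n_features,
            "classes": list(self.classes),
            "config": {
                "n_trees": self.config.n_trees,
                "n_features": self.config.n_features,
                "seed": self.config.seed,
            },
            "trees": [
                {"subset": [int(i) for i in s], **t.to_dict()}
                for t, s in zip(self.trees, self.subsets)
            ],
        }
        return json.dumps(doc, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "Forest":
        doc = json.loads(text)
        if doc.get("format") != "plmdkit-forest":
            raise ValueError("not a plmdkit forest document")
        cfg = ForestConfig(
            n_trees=doc["config"]["n_trees"],
            n_features=doc["config"]["n_features"],
            seed=doc["config"]["seed"],
        )
        trees = [DecisionTree.from_dict(t) for t in doc["trees"]]
        subsets = [np.array(t["subset"], dtype=np.int64) for t in doc["trees"]]
        return cls(trees=trees, subsets=subsets,
                   classes=tuple(doc["classes"]), config=cfg,
                   n_features=int(doc.get("n_features", 0)))


def train_forest(data: Dataset, config: ForestConfig | None = None,
                 bootstrap: bool = True) -> Forest:
    """Train T trees from one seeded stream.

    Per tree the generator is consumed in a documented order — bootstrap
    indices first, then the feature subset — so equal (data, config) pairs
    yield bit-identical forests.  ``bootstrap=False`` is a test hook that
    trains every tree on the full sample (a T = 1, m = M forest then equals a
    single CART tree).
    """
    if config is None:
        config = ForestConfig()
    m = config.resolve_m(data.n_features)
    rng = np.random.default_rng(config.seed)
    trees: list[DecisionTree] = []
    subsets: list[np.ndarray] = []
    for _ in range(config.n_trees):
        if bootstrap:
            sample, _idx = bootstrap_sample(data, rng)
        else:
            sample = data
        subset = select_features(data.n_features, m, rng)
        tree = grow_tree(sample.X, sample.y, features=subset,
                         n_classes=len(data.classes))
        trees.append(tree)
        subsets.append(subset)
    return Forest(trees=trees, subsets=subsets, classes=data.classes,
                  config=config, n_features=data.n_features)


def forest_predict(forest: Forest, x: np.ndarray) -> tuple[str, VoteTally]:
    """Majority vote across the ensemble; counts always sum to T."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("forest_predict takes a single feature vector")
    if forest.n_features and x.shape[0] != forest.n_features:
        raise ValueError(
            f"feature vector has length {x.shape[0]}, expected {forest.n_features}"
        )
    votes = [t.predict_one(x) for t in forest.trees]
    counts = np.bincount(np.array(votes), minlength=len(forest.classes))
    winner = int(np.argmax(counts))  # first maximum -> lowest class on ties
    tally = VoteTally(counts=tuple(int(c) for c in counts), winner=winner,
                      classes=forest.classes)
    return forest.classes[winner], tally
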