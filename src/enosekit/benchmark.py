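"""Classification benchmark harness.

Reproduces the experimental designs used for e-nose odor recognition:
stratified 80/20 train/test splits, balanced one-vs-rest two-class tasks
(e.g. Kona vs non-Kona) and multi-class tasks, scored by plain accuracy
across a family of classifier backends behind a uniform fit/predict
contract. Classifier internals are not re-derived: classical backends
delegate to scikit-learn and xgboost with fixed default hyperparameters.
The deep backends (a 1-D CNN and a CNN feeding a recurrent layer) require
PyTorch and report as unavailable when it is not installed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Any, Callable, Sequence

import numpy as np

from .core import FeatureVector
from .exceptions import BackendUnavailableError, ValidationError

__all__ = [
    "SplitSpec",
    "BenchmarkResult",
    "BinaryTask",
    "split_dataset",
    "make_one_vs_rest_task",
    "make_backend",
    "available_backends",
    "run_benchmark",
    "report_accuracy_grid",
    "DEFAULT_BACKENDS",
]

#: Backends run when none are specified. The deep backends are opt-in.
DEFAULT_BACKENDS = ("decision_tree", "random_forest", "xgboost", "svm")


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split protocol: stratified 80/20 by default."""

    train_fraction: float = 0.8
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValidationError("train_fraction must be in (0, 1)")


@dataclass
class BenchmarkResult:
    """Accuracy of one backend on one task, with reproducibility context."""

    task: str
    backend: str
    n_train: int
    n_test: int
    accuracy: float | None
    seed: int
    config_hash: str = ""
    error: str | None = None

    def __post_init__(self) -> None:
        if self.accuracy is not None and not 0 <= self.accuracy <= 1:
            raise ValidationError("accuracy must be in [0, 1]")


@dataclass
class BinaryTask:
    """A balanced one-vs-rest task: positives vs an equal-size negative draw."""

    features: list[FeatureVector]
    target_label: str
    n_positive: int
    n_negative: int


def _n_train(n: int, fraction: float) -> int:
    # round to nearest, ties up: 180*0.8 -> 144, 20*0.8 -> 16
    return int(np.floor(n * fraction + 0.5))


def split_dataset(
    features: Sequence[FeatureVector], spec: SplitSpec = SplitSpec()
) -> tuple[list[FeatureVector], list[FeatureVector]]:
    """Deterministic (seeded) stratified split into train and test sets.

    Per class, round(n·train_fraction) samples go to train (ties round up);
    the split is a pure function of the spec's seed; no sample lands in
    both sets.
    """
    features = list(features)
    if not features:
        raise ValidationError("empty dataset")
    rng = np.random.default_rng(spec.seed)
    train: list[FeatureVector] = []
    test: list[FeatureVector] = []
    if spec.stratified:
        groups: dict[str, list[int]] = {}
        for i, f in enumerate(features):
            groups.setdefault(f.label, []).append(i)
        for label in sorted(groups):  # sorted for seed-determinism
            idxs = np.array(groups[label])
            if len(idxs) < 2:
                raise ValidationError(
                    f"class {label!r} has {len(idxs)} sample(s); "
                    "stratified split needs >= 2"
                )
            perm = rng.permutation(len(idxs))
            k = _n_train(len(idxs), spec.train_fraction)
            train.extend(features[i] for i in idxs[perm[:k]])
            test.extend(features[i] for i in idxs[perm[k:]])
    else:
        perm = rng.permutation(len(features))
        k = _n_train(len(features), spec.train_fraction)
        train = [features[i] for i in perm[:k]]
        test = [features[i] for i in perm[k:]]
    return train, test


def make_one_vs_rest_task(
    features: Sequence[FeatureVector], target_label: str, seed: int = 0
) -> BinaryTask:
    """Build a balanced two-class task: target vs an equal-size random rest.

    Negatives are drawn uniformly (seeded) from all non-target samples and
    relabeled ``"not_<target>"``; the composition of the negative class is
    a design choice, recorded in the returned counts.
    """
    features = list(features)
    pos = [f for f in features if f.label == target_label]
    rest = [f for f in features if f.label != target_label]
    if not pos:
        raise ValidationError(f"label {target_label!r} not present")
    if not rest:
        raise ValidationError("dataset contains only the target label")
    rng = np.random.default_rng(seed)
    n_neg = min(len(pos), len(rest))
    neg_idx = rng.choice(len(rest), size=n_neg, replace=False)
    neg_label = f"not_{target_label}"
    neg = [
        FeatureVector(values=rest[i].values, label=neg_label, source_id=rest[i].source_id)
        for i in sorted(neg_idx)
    ]
    return BinaryTask(
        features=pos + neg,
        target_label=target_label,
        n_positive=len(pos),
        n_negative=len(neg),
    )


class _SklearnStyleBackend:
    """Uniform fit/predict wrapper; encodes string labels for estimators
    (xgboost) that need integer classes."""

    def __init__(self, name: str, estimator: Any):
        self.name = name
        self._est = estimator
        self._classes: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: Sequence[str]) -> "_SklearnStyleBackend":
        y = np.asarray(y)
        self._classes, y_enc = np.unique(y, return_inverse=True)
        self._est.fit(np.asarray(X, dtype=float), y_enc)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._classes is None:
            raise ValidationError("backend not fitted")
        pred = np.asarray(self._est.predict(np.asarray(X, dtype=float)))
        return self._classes[pred.astype(int)]


def _unavailable_deep_backend(name: str) -> Callable[[int], Any]:
    def factory(seed: int) -> Any:
        raise BackendUnavailableError(
            f"backend {name!r} requires PyTorch, which is not installed"
        )

    return factory


def _backend_factories() -> dict[str, Callable[[int], Any]]:
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier
    from xgboost import XGBClassifier

    factories: dict[str, Callable[[int], Any]] = {
        "decision_tree": lambda seed: _SklearnStyleBackend(
            "decision_tree", DecisionTreeClassifier(random_state=seed)
        ),
        "random_forest": lambda seed: _SklearnStyleBackend(
            "random_forest",
            RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1),
        ),
        "xgboost": lambda seed: _SklearnStyleBackend(
            "xgboost",
            XGBClassifier(
                n_estimators=100,
                max_depth=4,
                learning_rate=0.3,
                random_state=seed,
                n_jobs=1,
                verbosity=0,
            ),
        ),
        "svm": lambda seed: _SklearnStyleBackend(
            "svm", SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
        ),
        "cnn": _unavailable_deep_backend("cnn"),
        "cnn_lstm": _unavailable_deep_backend("cnn_lstm"),
    }
    return factories


def available_backends() -> tuple[str, ...]:
    """Names accepted by :func:`make_backend`."""
    return tuple(_backend_factories())


def make_backend(name: str, seed: int = 0) -> Any:
    """Instantiate a classifier backend with fixed default hyperparameters."""
    factories = _backend_factories()
    if name not in factories:
        raise ValidationError(
            f"unknown backend {name!r}; choose from {sorted(factories)}"
        )
    return factories[name](seed)


def _stack(features: Sequence[FeatureVector]) -> tuple[np.ndarray, np.ndarray]:
    X = np.vstack([f.values for f in features])
    y = np.array([f.label for f in features])
    return X, y


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_benchmark(
    train: Sequence[FeatureVector],
    test: Sequence[FeatureVector],
    backends: Sequence[str] = DEFAULT_BACKENDS,
    task: str = "multiclass",
    seed: int = 0,
) -> list[BenchmarkResult]:
    """Fit each backend on train, score accuracy on test.

    Accuracy is the fraction of correct predictions on the test set. A
    backend that fails (including an unavailable deep backend) is recorded
    as a failed result with its error message, and the run continues.
    """
    train, test = list(train), list(test)
    if not train or not test:
        raise ValidationError("train and test must be non-empty")
    train_ids = {id(f) for f in train}
    if any(id(f) in train_ids for f in test):
        raise ValidationError("train and test sets overlap")
    Xtr, ytr = _stack(train)
    Xte, yte = _stack(test)
    chash = _config_hash(
        {
            "task": task,
            "seed": seed,
            "backends": list(backends),
            "n_train": len(train),
            "n_test": len(test),
        }
    )
    results = []
    for name in backends:
        try:
            model = make_backend(name, seed=seed)
            model.fit(Xtr, ytr)
            acc = float(np.mean(model.predict(Xte) == yte))
            err = None
        except Exception as exc:  # failure is a result, not an abort
            acc, err = None, f"{type(exc).__name__}: {exc}"
        results.append(
            BenchmarkResult(
                task=task,
                backend=name,
                n_train=len(train),
                n_test=len(test),
                accuracy=acc,
                seed=seed,
                config_hash=chash,
                error=err,
            )
        )
    return results


def report_accuracy_grid(results: Sequence[BenchmarkResult]):
    """Task × backend accuracy grid (3 decimals; missing cells NA).

    Rows follow task submission order; columns follow backend submission
    order. Returns a pandas DataFrame; use ``.to_csv`` / ``.to_string``
    for the file and text renderings.
    """
    import pandas as pd

    results = list(results)
    if not results:
        raise ValidationError("no results to report")
    tasks: list[str] = []
    backends: list[str] = []
    for r in results:
        if r.task not in tasks:
            tasks.append(r.task)
        if r.backend not in backends:
            backends.append(r.backend)
    grid = pd.DataFrame(index=tasks, columns=backends, dtype=float)
    for r in results:
        grid.loc[r.task, r.backend] = (
            round(r.accuracy, 3) if r.accuracy is not None else np.nan
        )
    grid.index.name = "task"
    return grid
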