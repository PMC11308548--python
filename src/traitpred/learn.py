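"""Per-function binary classifiers: tuning, selection, persistence.

One binary classifier is trained per functional class.  The protocol per
class: stratified 80/20 train/test split; feature standardization fit on
the training split only; per-algorithm hyperparameter tuning by nested
stratified 3-fold cross-validation (grid search in the inner loop, an
unbiased score from the outer loop); the per-algorithm finalists are refit
on the full training split and the one with the highest Matthews
correlation coefficient (MCC) on the held-out test split is kept.

The public surface is both functional (``compute_mcc``,
``nested_cv_grid_search``, ``train_registry`` ...) and estimator-shaped:
:class:`FunctionClassifier` is a scikit-learn compatible classifier that
runs the whole per-class protocol in ``fit``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_array, check_X_y

from .dataset import TraitDataset

logger = logging.getLogger(__name__)

REGISTRY_FORMAT_VERSION = 1

ALGORITHMS = ("LR", "RF", "SVM", "NN")
#: tie-break preference when held-out MCC is equal (interpretability first)
ALGORITHM_PREFERENCE = ("LR", "SVM", "RF", "NN")

DEFAULT_GRIDS: dict[str, list[dict]] = {
    "LR": [{"C": c, "penalty": p}
           for c in (0.01, 0.1, 1.0, 10.0, 100.0) for p in ("l1", "l2")],
    "RF": [{"n_trees": n, "max_features_rule": m}
           for n in (100, 300, 500) for m in ("sqrt", "log2")],
    "SVM": [{"kernel": k, "C": c}
            for k in ("linear", "rbf") for c in (0.1, 1.0, 10.0)],
    "NN": [{"dense_units": u, "dropout_rate": d}
           for u in (64, 256, 1024) for d in (0.1, 0.3, 0.5)],
}


def _lr_uses_l1_ratio() -> bool:
    # sklearn >= 1.8 deprecates LogisticRegression(penalty=...) in favour
    # of l1_ratio; pick the spelling the installed version wants
    import sklearn

    major, minor = (int(x) for x in sklearn.__version__.split(".")[:2])
    return (major, minor) >= (1, 8)


_LR_USES_L1_RATIO = _lr_uses_l1_ratio()


class UnstratifiableClassError(ValueError):
    """A class cannot be stratified (too few positives or negatives)."""


class RegistryError(RuntimeError):
    """Registry artifact missing, corrupted, or of the wrong version."""


# ---------------------------------------------------------------------------
# Matthews correlation coefficient


def compute_mcc(tp: int, fp: int, fn: int, tn: int) -> float:
    """MCC from confusion counts.

    ``(tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn))``, with the
    conventional value 0 when any denominator factor is 0.
    """
    for name, v in (("tp", tp), ("fp", fp), ("fn", fn), ("tn", tn)):
        if v < 0:
            raise ValueError(f"negative confusion count {name}={v}")
    if tp + fp + fn + tn == 0:
        raise ValueError("empty confusion matrix")
    denom = (
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    if denom == 0.0:
        return 0.0
    return (float(tp) * tn - float(fp) * fn) / math.sqrt(denom)


def confusion_counts(y_true, y_pred) -> tuple[int, int, int, int]:
    """(tp, fp, fn, tn) for binary vectors."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    return tp, fp, fn, tn


def mcc_score(y_true, y_pred) -> float:
    return compute_mcc(*confusion_counts(y_true, y_pred))


# ---------------------------------------------------------------------------
# Splitting and scaling


def stratified_split(features, labels, train_fraction: float = 0.8,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test index split.

    The positive proportion in each partition differs from the overall one
    by at most one genome; partitions are disjoint and exhaustive and
    deterministic per seed.
    """
    y = np.asarray(labels).astype(int)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos < 2 or n_neg < 2:
        raise UnstratifiableClassError(
            f"unstratifiable class: {n_pos} positives / {n_neg} negatives"
        )
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, train_size=train_fraction, stratify=y, random_state=seed
    )
    return np.sort(train_idx), np.sort(test_idx)


@dataclass
class ScalerParams:
    """Per-feature mean and standard deviation for z-scoring.

    Constant columns store sd 1, so scaling maps them to 0 (no-op).
    """

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def from_standard_scaler(cls, scaler: StandardScaler) -> "ScalerParams":
        return cls(mean=np.asarray(scaler.mean_, dtype=float),
                   sd=np.asarray(scaler.scale_, dtype=float))

    def apply(self, features) -> np.ndarray:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != self.mean.shape[0]:
            raise ValueError(
                f"feature count mismatch: scaler has {self.mean.shape[0]}, "
                f"input has {X.shape[1]}"
            )
        return (X - self.mean) / self.sd


def fit_scaler(train_features) -> ScalerParams:
    """Fit a z-score scaler on the training partition only."""
    scaler = StandardScaler().fit(np.asarray(train_features, dtype=float))
    return ScalerParams.from_standard_scaler(scaler)


def apply_scaler(params: ScalerParams, features) -> np.ndarray:
    return params.apply(features)


# ---------------------------------------------------------------------------
# Model construction


def _nn_backend():
    try:
        from tensorflow import keras  # type: ignore
    except Exception as exc:  # pragma: no cover - backend optional
        raise RuntimeError(
            "neural-network backend missing: the NN algorithm needs the "
            "optional tensorflow/keras extra (pip install traitpred[nn])"
        ) from exc
    return keras


class _KerasBinaryClassifier:  # pragma: no cover - needs optional backend
    """Single-hidden-layer dense network with dropout and sigmoid output."""

    def __init__(self, dense_units: int, dropout_rate: float, seed: int = 0,
                 epochs: int = 50):
        self.dense_units = dense_units
        self.dropout_rate = dropout_rate
        self.seed = seed
        self.epochs = epochs
        self.model_ = None

    def fit(self, X, y):
        keras = _nn_backend()
        import tensorflow as tf  # type: ignore

        tf.keras.utils.set_random_seed(self.seed)
        model = keras.Sequential([
            keras.layers.Input(shape=(X.shape[1],)),
            keras.layers.Dense(self.dense_units, activation="relu"),
            keras.layers.Dropout(self.dropout_rate),
            keras.layers.Dense(1, activation="sigmoid"),
        ])
        model.compile(optimizer="adam", loss="binary_crossentropy")
        stop = keras.callbacks.EarlyStopping(patience=5,
                                             restore_best_weights=True)
        model.fit(X, y, epochs=self.epochs, verbose=0,
                  validation_split=0.2, callbacks=[stop])
        self.model_ = model
        return self

    def predict_proba(self, X):
        p = self.model_.predict(X, verbose=0).ravel()
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def train_class_model(features, labels, algorithm: str, hp: dict,
                      seed: int = 0):
    """Fit one model of the given algorithm on (already scaled) features."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if algorithm == "LR":
        kwargs = dict(C=hp["C"], solver="liblinear", max_iter=5000,
                      random_state=seed)
        if _LR_USES_L1_RATIO:
            kwargs["l1_ratio"] = 1.0 if hp["penalty"] == "l1" else 0.0
        else:  # pragma: no cover - older sklearn
            kwargs["penalty"] = hp["penalty"]
        model = LogisticRegression(**kwargs)
    elif algorithm == "RF":
        model = RandomForestClassifier(
            n_estimators=hp["n_trees"], max_features=hp["max_features_rule"],
            random_state=seed, n_jobs=1,
        )
    elif algorithm == "SVM":
        model = SVC(kernel=hp["kernel"], C=hp["C"], random_state=seed)
    elif algorithm == "NN":
        model = _KerasBinaryClassifier(
            dense_units=hp["dense_units"], dropout_rate=hp["dropout_rate"],
            seed=seed,
        )
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return model.fit(X, y)


# ---------------------------------------------------------------------------
# Nested cross-validation grid search


@dataclass
class CVResult:
    """One outer fold's winner: the tuned combination and its scores."""

    hp: dict
    inner_mean_mcc: float
    outer_mcc: float
    grid_index: int


def nested_cv_grid_search(features, labels, algorithm: str,
                          grid: list[dict] | None = None, k: int = 3,
                          seed: int = 0) -> list[CVResult]:
    """Nested stratified k-fold grid search.

    For each of the ``k`` outer folds an inner k-fold grid search selects
    the hyperparameter combination with the highest inner mean MCC (ties
    resolved by grid order); the winner is refit on the outer-train
    portion and scored on the outer-test fold.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    grid = list(grid if grid is not None else DEFAULT_GRIDS[algorithm])
    if not grid:
        raise ValueError("empty hyperparameter grid")
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos < k or n_neg < k:
        raise UnstratifiableClassError(
            f"class has {n_pos} positives / {n_neg} negatives; cannot form "
            f"{k} stratified folds with a positive in each — use a smaller "
            f"k or exclude the class"
        )
    outer = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    results: list[CVResult] = []
    for fold, (tr, te) in enumerate(outer.split(X, y)):
        inner = StratifiedKFold(n_splits=k, shuffle=True,
                                random_state=seed + 1 + fold)
        best_idx, best_mean = 0, -np.inf
        for gi, hp in enumerate(grid):
            scores = []
            for itr, ite in inner.split(X[tr], y[tr]):
                model = train_class_model(X[tr][itr], y[tr][itr],
                                          algorithm, hp, seed=seed)
                scores.append(mcc_score(y[tr][ite],
                                        model.predict(X[tr][ite])))
            mean = float(np.mean(scores))
            if mean > best_mean:  # strict: ties keep earlier grid entry
                best_idx, best_mean = gi, mean
        winner = grid[best_idx]
        refit = train_class_model(X[tr], y[tr], algorithm, winner, seed=seed)
        outer_mcc = mcc_score(y[te], refit.predict(X[te]))
        results.append(CVResult(hp=winner, inner_mean_mcc=best_mean,
                                outer_mcc=outer_mcc, grid_index=best_idx))
    return results


def choose_final_hp(results: list[CVResult]) -> dict:
    """Final combination from the k outer winners.

    Highest outer MCC; ties by highest inner mean; remaining ties by grid
    order.
    """
    best = min(results,
               key=lambda r: (-r.outer_mcc, -r.inner_mean_mcc, r.grid_index))
    return best.hp


# ---------------------------------------------------------------------------
# The per-class estimator


class FunctionClassifier(BaseEstimator, ClassifierMixin):
    """Binary trait classifier with built-in tuning and model selection.

    ``fit`` runs the full per-class protocol: stratified 80/20 split,
    train-split standardization, per-algorithm nested CV tuning, refit of
    each finalist on the training split, and selection of the algorithm
    with the highest held-out MCC (ties broken LR > SVM > RF > NN).

    Parameters
    ----------
    algorithms : tuple of str
        Candidate algorithms; the NN entry needs the optional keras
        backend. Defaults to the three classical algorithms.
    grids : dict or None
        Per-algorithm hyperparameter grids; ``None`` uses
        :data:`DEFAULT_GRIDS`.
    cv_folds : int
        k for both nested CV loops.
    train_fraction : float
        Share of genomes in the training split.
    seed : int
        Drives the split, the CV folds and stochastic learners.
    nn_repeats : int
        How many times NN tuning is repeated (best repeat kept).
    decision_threshold : float
        Probability cut-off for probabilistic models.
    """

    def __init__(self, algorithms=("LR", "SVM", "RF"), grids=None,
                 cv_folds: int = 3, train_fraction: float = 0.8,
                 seed: int = 0, nn_repeats: int = 5,
                 decision_threshold: float = 0.5):
        self.algorithms = algorithms
        self.grids = grids
        self.cv_folds = cv_folds
        self.train_fraction = train_fraction
        self.seed = seed
        self.nn_repeats = nn_repeats
        self.decision_threshold = decision_threshold

    # -- protocol pieces -------------------------------------------------

    def _grid(self, algorithm: str) -> list[dict]:
        if self.grids and algorithm in self.grids:
            return list(self.grids[algorithm])
        return list(DEFAULT_GRIDS[algorithm])

    def _tune_algorithm(self, algorithm, X_train, y_train):
        if algorithm == "NN":
            # NN tuning is repeated; keep the repeat with the best outer MCC
            best_results, best_score = None, -np.inf
            for rep in range(self.nn_repeats):
                results = nested_cv_grid_search(
                    X_train, y_train, algorithm, self._grid(algorithm),
                    k=self.cv_folds, seed=self.seed + 101 * rep,
                )
                top = max(r.outer_mcc for r in results)
                if top > best_score:
                    best_results, best_score = results, top
            return best_results
        return nested_cv_grid_search(
            X_train, y_train, algorithm, self._grid(algorithm),
            k=self.cv_folds, seed=self.seed,
        )

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        y = y.astype(int)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]

        train_idx, test_idx = stratified_split(
            X, y, train_fraction=self.train_fraction, seed=self.seed
        )
        self.train_indices_, self.test_indices_ = train_idx, test_idx
        self.scaler_ = fit_scaler(X[train_idx])
        Xs = self.scaler_.apply(X)
        X_train, y_train = Xs[train_idx], y[train_idx]
        X_test, y_test = Xs[test_idx], y[test_idx]

        self.nested_results_ = {}
        candidates = []  # (algorithm, model, hp, test_mcc)
        for algorithm in self.algorithms:
            results = self._tune_algorithm(algorithm, X_train, y_train)
            self.nested_results_[algorithm] = results
            hp = choose_final_hp(results)
            model = train_class_model(X_train, y_train, algorithm, hp,
                                      seed=self.seed)
            test_mcc = mcc_score(
                y_test, self._decide(model, X_test)
            )
            candidates.append((algorithm, model, hp, test_mcc))

        self.candidate_scores_ = {a: s for a, _, _, s in candidates}
        self.candidate_hps_ = {a: hp for a, _, hp, _ in candidates}
        alg, model, hp, test_mcc = _argmax_candidate(candidates)
        self.algorithm_ = alg
        self.model_ = model
        self.hyperparameters_ = hp
        self.test_mcc_ = test_mcc
        return self

    def _decide(self, model, X_scaled) -> np.ndarray:
        if hasattr(model, "predict_proba"):
            proba = model.predict_proba(X_scaled)[:, 1]
            return (proba >= self.decision_threshold).astype(int)
        return np.asarray(model.predict(X_scaled)).astype(int)

    def predict(self, X):
        check_array(X)
        Xs = self.scaler_.apply(X)
        return self._decide(self.model_, Xs)


def _argmax_candidate(candidates):
    """Highest held-out MCC; exact ties broken by ALGORITHM_PREFERENCE."""
    pref = {a: i for i, a in enumerate(ALGORITHM_PREFERENCE)}
    return min(candidates,
               key=lambda c: (-c[3], pref.get(c[0], len(pref))))


def select_best(candidates, test_features, test_labels,
                decision_threshold: float = 0.5):
    """Score refit per-algorithm candidates on the test split; keep argmax.

    ``candidates`` is a list of (algorithm, fitted model, hp) tuples on the
    scaled feature space.  Returns (algorithm, model, hp, test_mcc,
    per-candidate scores).
    """
    y = np.asarray(test_labels).astype(int)
    scored = []
    for algorithm, model, hp in candidates:
        if hasattr(model, "predict_proba"):
            pred = (model.predict_proba(test_features)[:, 1]
                    >= decision_threshold).astype(int)
        else:
            pred = np.asarray(model.predict(test_features)).astype(int)
        scored.append((algorithm, model, hp, mcc_score(y, pred)))
    best = _argmax_candidate(scored)
    return (*best, {a: s for a, _, _, s in scored})


# ---------------------------------------------------------------------------
# Registry of per-class bundles


@dataclass
class ClassifierBundle:
    """One functional class's fitted scaler + model + metadata."""

    class_name: str
    algorithm: str
    hyperparameters: dict
    scaler: ScalerParams
    model: object
    feature_order: list[str]
    test_mcc: float
    decision_threshold: float = 0.5
    candidate_scores: dict = field(default_factory=dict)
    candidate_hps: dict = field(default_factory=dict)
    seed: int = 0
    train_fraction: float = 0.8

    def predict(self, features) -> np.ndarray:
        """Binary calls for rows already aligned to ``feature_order``."""
        Xs = self.scaler.apply(features)
        if hasattr(self.model, "predict_proba"):
            proba = self.model.predict_proba(Xs)[:, 1]
            return (proba >= self.decision_threshold).astype(int)
        return np.asarray(self.model.predict(Xs)).astype(int)


@dataclass
class ModelRegistry:
    """All per-class bundles plus the training manifest."""

    bundles: dict[str, ClassifierBundle]
    manifest: dict = field(default_factory=dict)

    @property
    def feature_order(self) -> list[str]:
        first = next(iter(self.bundles.values()))
        return first.feature_order

    @property
    def class_names(self) -> list[str]:
        return list(self.bundles)

    def test_mccs(self) -> pd.Series:
        return pd.Series({c: b.test_mcc for c, b in self.bundles.items()})


@dataclass
class TrainConfig:
    """Knobs of the training protocol (all config-file overridable)."""

    algorithms: tuple = ("LR", "SVM", "RF")
    grids: dict | None = None
    cv_folds: int = 3
    train_fraction: float = 0.8
    seed: int = 0
    min_positives: int = 3
    mcc_success_threshold: float = 0.7
    nn_repeats: int = 5

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        cfg = cls(**{k: v for k, v in payload.items() if k in known})
        if isinstance(cfg.algorithms, list):
            cfg.algorithms = tuple(cfg.algorithms)
        return cfg


def dataset_hash(dataset: TraitDataset) -> str:
    h = hashlib.sha256()
    h.update(dataset.features.to_csv(sep="\t").encode())
    h.update(dataset.labels.to_csv(sep="\t").encode())
    return h.hexdigest()


def train_registry(dataset: TraitDataset,
                   config: TrainConfig | None = None) -> ModelRegistry:
    """Train one :class:`ClassifierBundle` per surviving class.

    Classes that cannot be stratified are skipped with a logged reason;
    producing zero bundles is an error.
    """
    config = config or TrainConfig()
    X = dataset.features.values.astype(float)
    bundles: dict[str, ClassifierBundle] = {}
    skipped: dict[str, str] = {}
    for class_name in dataset.class_names:
        y = dataset.labels[class_name].values.astype(int)
        clf = FunctionClassifier(
            algorithms=config.algorithms, grids=config.grids,
            cv_folds=config.cv_folds, train_fraction=config.train_fraction,
            seed=config.seed, nn_repeats=config.nn_repeats,
        )
        try:
            clf.fit(X, y)
        except UnstratifiableClassError as exc:
            logger.warning("skipping class %r: %s", class_name, exc)
            skipped[class_name] = str(exc)
            continue
        bundles[class_name] = ClassifierBundle(
            class_name=class_name,
            algorithm=clf.algorithm_,
            hyperparameters=clf.hyperparameters_,
            scaler=clf.scaler_,
            model=clf.model_,
            feature_order=dataset.feature_order,
            test_mcc=clf.test_mcc_,
            decision_threshold=clf.decision_threshold,
            candidate_scores=clf.candidate_scores_,
            candidate_hps=clf.candidate_hps_,
            seed=config.seed,
            train_fraction=config.train_fraction,
        )
        if clf.test_mcc_ < config.mcc_success_threshold:
            logger.info("class %r below success threshold: MCC %.3f",
                        class_name, clf.test_mcc_)
    if not bundles:
        raise RuntimeError("no classes could be trained")
    manifest = {
        "format_version": REGISTRY_FORMAT_VERSION,
        "dataset_sha256": dataset_hash(dataset),
        "seed": config.seed,
        "n_genomes": dataset.n_genomes,
        "skipped_classes": skipped,
        "mcc_success_threshold": config.mcc_success_threshold,
        "flagged_below_threshold": sorted(
            c for c, b in bundles.items()
            if b.test_mcc < config.mcc_success_threshold
        ),
    }
    return ModelRegistry(bundles=bundles, manifest=manifest)


def _safe_name(class_name: str) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "_"
                   for c in class_name)


def persist_registry(registry: ModelRegistry, path) -> None:
    """Write the registry: one artifact per bundle plus a JSON manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    files = {}
    for class_name, bundle in registry.bundles.items():
        fname = f"{_safe_name(class_name)}.joblib"
        joblib.dump(bundle, path / fname)
        files[class_name] = fname
    manifest = dict(registry.manifest)
    manifest["format_version"] = REGISTRY_FORMAT_VERSION
    manifest["bundle_files"] = files
    manifest["feature_order"] = registry.feature_order
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_registry(path) -> ModelRegistry:
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise RegistryError(f"no registry manifest at {manifest_path}")
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise RegistryError(f"corrupted registry manifest: {exc}") from exc
    version = manifest.get("format_version")
    if version != REGISTRY_FORMAT_VERSION:
        raise RegistryError(
            f"registry format version {version!r} does not match this "
            f"code's version {REGISTRY_FORMAT_VERSION}"
        )
    bundles: dict[str, ClassifierBundle] = {}
    for class_name, fname in manifest.get("bundle_files", {}).items():
        try:
            bundle = joblib.load(path / fname)
        except Exception as exc:
            raise RegistryError(
                f"cannot load bundle for class {class_name!r}: {exc}"
            ) from exc
        if not isinstance(bundle, ClassifierBundle):
            raise RegistryError(
                f"artifact for class {class_name!r} is not a bundle"
            )
        bundles[class_name] = bundle
    if not bundles:
        raise RegistryError(f"registry at {path} holds no bundles")
    return ModelRegistry(bundles=bundles, manifest=manifest)
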