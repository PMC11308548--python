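"""Apply a trained registry to query genomes.

Aligns query KO vectors to the training feature space, produces binary
function calls per genome, evaluates them against known labels (confusion
matrix + MCC per class), pools classes into functional superclasses, and
extracts per-function gene (KO) importance from the fitted models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import KOVector, TraitDataset
from .learn import (
    ALGORITHM_PREFERENCE,
    ClassifierBundle,
    ModelRegistry,
    compute_mcc,
    stratified_split,
    train_class_model,
)

logger = logging.getLogger(__name__)

#: superclass names used to pool related functions for coarse evaluation
DEFAULT_SUPERCLASS_NAMES = (
    "carbon metabolism",
    "nitrogen metabolism",
    "sulfur metabolism",
    "parasites or symbionts",
    "phototrophy",
    "arsenic ions metabolism",
    "metals metabolisms",
)

UNGROUPED = "ungrouped"


@dataclass
class PredictionReport:
    """Binary genome×class calls, optionally with per-class evaluation."""

    calls: pd.DataFrame
    per_class: pd.DataFrame | None = None


@dataclass
class ImportanceTable:
    """Ranked KO importance scores for one functional class."""

    class_name: str
    source_algorithm: str
    table: pd.DataFrame  # columns: ko, score, rank

    def __len__(self) -> int:
        return len(self.table)


def align_features(query: KOVector | dict, feature_order: list[str]
                   ) -> np.ndarray:
    """Project a query KO vector onto the training feature order.

    KOs absent from the query become 0; query KOs outside the training
    space are dropped (logged as a count); output order follows
    ``feature_order`` regardless of the input's key order.
    """
    counts = query.counts if isinstance(query, KOVector) else dict(query)
    novel = len(set(counts) - set(feature_order))
    if novel:
        logger.info("query has %d KOs outside the training feature space; "
                    "dropped", novel)
    return np.array([counts.get(ko, 0) for ko in feature_order], dtype=float)


def predict_functions(registry: ModelRegistry,
                      queries: list[KOVector]) -> PredictionReport:
    """Binary function calls for each query genome.

    Per class: align to the registry feature order, apply that class's
    scaler, and take the model decision at its threshold.  A genome may be
    positive for any number of classes.
    """
    if not registry.bundles:
        raise ValueError("empty registry")
    feature_order = registry.feature_order
    X = np.vstack([align_features(q, feature_order) for q in queries]) \
        if queries else np.empty((0, len(feature_order)))
    calls = pd.DataFrame(
        0, index=[q.genome_id for q in queries],
        columns=registry.class_names, dtype="int8",
    )
    calls.index.name = "genome"
    for class_name, bundle in registry.bundles.items():
        if len(X):
            calls[class_name] = bundle.predict(X)
    return PredictionReport(calls=calls)


def evaluate_predictions(report: PredictionReport, truth: pd.DataFrame,
                         zero_positive_mcc_as_zero: bool = False
                         ) -> pd.DataFrame:
    """Per-class confusion counts and MCC against known labels.

    Classes are intersected between calls and truth; genomes must match
    exactly.  For classes with zero truth positives the MCC is
    uninformative and reported as NaN (set ``zero_positive_mcc_as_zero``
    for the strict convention of reporting 0 instead).
    """
    calls = report.calls
    missing = sorted(set(calls.index) ^ set(truth.index))
    if missing:
        raise ValueError(f"genome id mismatch between calls and truth: "
                         f"{missing}")
    truth = truth.loc[calls.index]
    classes = [c for c in calls.columns if c in truth.columns]
    rows = {}
    for c in classes:
        y_true = truth[c].astype(int).values
        y_pred = calls[c].astype(int).values
        tp = int(((y_true == 1) & (y_pred == 1)).sum())
        fp = int(((y_true == 0) & (y_pred == 1)).sum())
        fn = int(((y_true == 1) & (y_pred == 0)).sum())
        tn = int(((y_true == 0) & (y_pred == 0)).sum())
        if y_true.sum() == 0 and not zero_positive_mcc_as_zero:
            mcc = float("nan")
        else:
            mcc = compute_mcc(tp, fp, fn, tn)
        rows[c] = {"tp": tp, "fp": fp, "fn": fn, "tn": tn, "mcc": mcc}
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "class"
    report.per_class = table
    return table


def aggregate_superclasses(report: PredictionReport, truth: pd.DataFrame,
                           superclass_map: dict[str, str]) -> pd.DataFrame:
    """Pooled confusion and MCC per superclass.

    Member-class confusion counts are summed and one MCC is computed on
    the pooled confusion; functions absent from the map are left out.
    """
    per_class = evaluate_predictions(report, truth,
                                     zero_positive_mcc_as_zero=True)
    groups: dict[str, list[str]] = {}
    for fn, sc in superclass_map.items():
        if sc == UNGROUPED:
            continue
        groups.setdefault(sc, []).append(fn)
    rows = {}
    for sc, members in groups.items():
        present = [m for m in members if m in per_class.index]
        if not present:
            logger.warning("superclass %r has no member class present; "
                           "skipped", sc)
            continue
        pooled = per_class.loc[present, ["tp", "fp", "fn", "tn"]].sum()
        rows[sc] = {
            **pooled.astype(int).to_dict(),
            "n_members": len(present),
            "mcc": compute_mcc(int(pooled["tp"]), int(pooled["fp"]),
                               int(pooled["fn"]), int(pooled["tn"])),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "superclass"
    return table


def read_superclass_map(path) -> dict[str, str]:
    """2-column TSV (function, superclass) -> mapping."""
    table = pd.read_csv(path, sep="\t", header=None,
                        names=["function", "superclass"], comment="#")
    return dict(zip(table["function"], table["superclass"]))


# ---------------------------------------------------------------------------
# Feature importance


def _second_best_classical(bundle: ClassifierBundle) -> str:
    classical = {a: s for a, s in bundle.candidate_scores.items()
                 if a != "NN"}
    if not classical:
        raise ValueError(
            f"class {bundle.class_name!r}: no classical model available "
            f"for the NN importance fallback"
        )
    pref = {a: i for i, a in enumerate(ALGORITHM_PREFERENCE)}
    return min(classical, key=lambda a: (-classical[a], pref.get(a, 99)))


def _training_split_scaled(bundle: ClassifierBundle, dataset: TraitDataset):
    X = dataset.features[bundle.feature_order].values.astype(float)
    y = dataset.labels[bundle.class_name].values.astype(int)
    train_idx, _ = stratified_split(X, y,
                                    train_fraction=bundle.train_fraction,
                                    seed=bundle.seed)
    return bundle.scaler.apply(X[train_idx]), y[train_idx]


def _scores_from_model(model, algorithm: str) -> np.ndarray:
    if algorithm == "LR":
        return np.asarray(model.coef_).ravel()
    if algorithm == "RF":
        return np.asarray(model.feature_importances_).ravel()
    if algorithm == "SVM":
        return np.asarray(model.coef_).ravel()
    raise ValueError(f"no direct importance for algorithm {algorithm!r}")


def extract_importance(bundle: ClassifierBundle,
                       dataset: TraitDataset | None = None,
                       max_rows: int = 1000,
                       tail_fraction: float = 0.10) -> ImportanceTable:
    """KO importance scores for one class's model.

    LR keeps its nonzero coefficients; RF its positive impurity
    importances; an rbf-kernel SVM gets a linear-kernel surrogate SVM
    retrained on the same training split solely for importance; an NN
    bundle falls back to the class's second-best classical algorithm,
    retrained likewise.  ``source_algorithm`` records any surrogate.  Zero
    scores are filtered; when more than ``max_rows`` rows remain, only the
    top and bottom ``tail_fraction`` by signed score are kept.
    """
    algorithm = bundle.algorithm
    source = algorithm
    score_alg = algorithm
    model = bundle.model

    if algorithm == "NN":
        source = score_alg = _second_best_classical(bundle)
        if dataset is None:
            raise ValueError("dataset required to retrain the NN fallback")
        Xs, y = _training_split_scaled(bundle, dataset)
        hp = bundle.candidate_hps[source]
        if source == "SVM" and hp.get("kernel") != "linear":
            hp = {**hp, "kernel": "linear"}
        model = train_class_model(Xs, y, source, hp, seed=bundle.seed)
        source = f"{source} (NN fallback)"
    elif algorithm == "SVM" and bundle.hyperparameters.get("kernel") != "linear":
        if dataset is None:
            raise ValueError(
                "dataset required to retrain a linear surrogate for an "
                "rbf-kernel SVM"
            )
        Xs, y = _training_split_scaled(bundle, dataset)
        hp = {**bundle.hyperparameters, "kernel": "linear"}
        model = train_class_model(Xs, y, "SVM", hp, seed=bundle.seed)
        source = "SVM (linear surrogate)"
        score_alg = "SVM"
    scores = _scores_from_model(model, score_alg)

    kos = np.asarray(bundle.feature_order)
    nonzero = scores != 0
    table = pd.DataFrame({"ko": kos[nonzero], "score": scores[nonzero]})
    if len(table) > max_rows:
        n_tail = int(len(table) * tail_fraction)
        by_signed = table.sort_values("score", ascending=False,
                                      kind="mergesort")
        table = pd.concat([by_signed.head(n_tail), by_signed.tail(n_tail)])
        table = table.drop_duplicates(subset="ko")
    table = table.reindex(
        table["score"].abs().sort_values(ascending=False,
                                         kind="mergesort").index
    )
    table = table.reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return ImportanceTable(class_name=bundle.class_name,
                           source_algorithm=source, table=table)
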