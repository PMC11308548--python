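"""User-curated refinement of functional classes.

Builds a modified training dataset in which a functional class's positive
genomes are replaced by user-supplied annotated genomes, with
conflict-removal semantics: a user genome already present in the base
dataset is removed from the base rows and re-enters only as a positive of
the refined class, so no genome is ever simultaneously a positive and a
negative example of it.  Held-out genome ids can be excluded from
training entirely (e.g. reserved for validation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import (
    DEFAULT_MIN_POSITIVES,
    KOVector,
    TraitDataset,
    parse_annotation_table,
)
from .learn import ClassifierBundle, ModelRegistry, TrainConfig, train_registry

logger = logging.getLogger(__name__)


@dataclass
class RefinementRequest:
    """Inputs to one class refinement."""

    class_name: str
    new_positive_genomes: list  # annotation files/texts or KOVectors
    base_dataset: TraitDataset
    holdout_genome_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.new_positive_genomes:
            raise ValueError("new_positive_genomes must be non-empty")


def _to_vectors(sources: list) -> list[KOVector]:
    vectors = []
    for src in sources:
        vectors.append(src if isinstance(src, KOVector)
                       else parse_annotation_table(src))
    return vectors


def build_refined_dataset(request: RefinementRequest,
                          min_positives: int = DEFAULT_MIN_POSITIVES
                          ) -> TraitDataset:
    """Apply the refinement semantics to the base dataset.

    1. If the class already exists, all its previous positives become
       negatives for it (they stay in the dataset for other classes).
    2. User genomes already present in the base are removed from the base
       rows and re-enter only as positives of the refined class.
    3. Holdout ids are removed from every row.
    4. KOs of the new genomes outside the base feature space are appended
       as new columns (zeros elsewhere); the new genomes' labels for every
       other class default to 0, with a log line so users can override.
    """
    vectors = _to_vectors(request.new_positive_genomes)
    new_ids = [v.genome_id for v in vectors]
    if len(set(new_ids)) != len(new_ids):
        raise ValueError("duplicate genome ids among provided positives")
    overlap_holdout = set(new_ids) & set(request.holdout_genome_ids)
    if overlap_holdout:
        raise ValueError(f"genomes cannot be both new positives and "
                         f"holdouts: {sorted(overlap_holdout)}")

    features = request.base_dataset.features.copy()
    labels = request.base_dataset.labels.copy()
    class_name = request.class_name

    if class_name in labels.columns:
        n_prev = int(labels[class_name].sum())
        labels[class_name] = 0
        logger.info("class %r: %d previous positives replaced", class_name,
                    n_prev)
    else:
        labels[class_name] = 0

    drop = [g for g in features.index
            if g in set(new_ids) | set(request.holdout_genome_ids)]
    if drop:
        features = features.drop(index=drop)
        labels = labels.drop(index=drop)

    new_counts = pd.DataFrame(
        {v.genome_id: pd.Series(v.counts, dtype=float) for v in vectors}
    ).T.fillna(0)
    novel_kos = sorted(set(new_counts.columns) - set(features.columns))
    if novel_kos:
        logger.info("appending %d new KO columns from provided genomes",
                    len(novel_kos))
        features = features.reindex(
            columns=list(features.columns) + novel_kos, fill_value=0
        )
    new_rows = new_counts.reindex(columns=features.columns,
                                  fill_value=0).astype(np.int64)

    features = pd.concat([features, new_rows])
    new_labels = pd.DataFrame(0, index=new_ids, columns=labels.columns,
                              dtype="int8")
    new_labels[class_name] = 1
    labels = pd.concat([labels, new_labels])
    logger.info("new genomes default to label 0 for the %d other classes; "
                "supply a label override table if they carry known "
                "functions", labels.shape[1] - 1)

    n_pos = int(labels[class_name].sum())
    if n_pos < min_positives:
        raise ValueError(
            f"refined class {class_name!r} ends with {n_pos} positives "
            f"(< {min_positives})"
        )
    features.index.name = "genome"
    labels.index.name = "genome"
    return TraitDataset(features=features, labels=labels)


def train_refined_classifier(refined: TraitDataset, class_name: str,
                             config: TrainConfig | None = None
                             ) -> ClassifierBundle:
    """Train the refined class's bundle along the standard training path."""
    subset = TraitDataset(features=refined.features,
                          labels=refined.labels[[class_name]])
    registry: ModelRegistry = train_registry(subset, config)
    return registry.bundles[class_name]
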