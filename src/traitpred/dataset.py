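"""Build the KO copy-number feature matrix and binary trait-label matrix.

Ingests per-genome functional annotation tables in the eggNOG-mapper
output layout (tab-delimited, one row per gene, a ``KEGG_ko`` column that
may hold ``-``, one K-number, or a comma-separated list prefixed ``ko:``),
derives genome labels from resolved taxon→function memberships by lineage
propagation, and applies the small-class exclusion rule.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .taxonomy import TaxonomyIndex

logger = logging.getLogger(__name__)

KO_PATTERN = re.compile(r"^K\d{5}$")
_KO_TOKEN = re.compile(r"(?:ko:)?(K\d{5})")

#: classes with fewer positive genomes than this are dropped
DEFAULT_MIN_POSITIVES = 3


class AnnotationError(ValueError):
    pass


@dataclass
class KOVector:
    """KO copy numbers of one genome."""

    genome_id: str
    counts: dict[str, int] = field(default_factory=dict)

    def increment(self, ko: str, by: int = 1) -> None:
        if not KO_PATTERN.match(ko):
            raise ValueError(f"not a KO identifier: {ko!r}")
        self.counts[ko] = self.counts.get(ko, 0) + by


@dataclass
class TraitDataset:
    """Paired feature (genome×KO) and label (genome×function) matrices.

    Both matrices share one genome row order; labels are binary.
    """

    features: pd.DataFrame
    labels: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.labels.index):
            raise ValueError("features and labels must share genome order")

    @property
    def feature_order(self) -> list[str]:
        return list(self.features.columns)

    @property
    def class_names(self) -> list[str]:
        return list(self.labels.columns)

    @property
    def n_genomes(self) -> int:
        return len(self.features)

    def class_sizes(self) -> pd.Series:
        return self.labels.sum(axis=0)


def _detect_ko_column(header_fields: list[str]) -> int | None:
    for i, name in enumerate(header_fields):
        if name.strip().lstrip("#").strip().lower() == "kegg_ko":
            return i
    return None


def parse_annotation_table(source, genome_id: str | None = None) -> KOVector:
    """Parse one eggNOG-mapper annotation table into a :class:`KOVector`.

    ``source`` is a path or raw table text.  Every K-number listed for a
    gene increments that KO's copy number by one (a gene with *n* listed
    KOs contributes one copy to each of the *n*); ``-`` entries and
    comment/header lines (leading ``#``) contribute nothing.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        path = Path(source)
        try:
            text = path.read_text()
        except OSError as exc:
            raise AnnotationError(f"cannot read annotation file "
                                  f"{path}: {exc}") from exc
        if genome_id is None:
            genome_id = path.name.split(".")[0]
    else:
        text = str(source)
        if genome_id is None:
            genome_id = "query"

    ko_col: int | None = None
    vector = KOVector(genome_id=genome_id)
    saw_data = False
    for line in text.splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            maybe = _detect_ko_column(line.split("\t"))
            if maybe is not None:
                ko_col = maybe
            continue
        fields = line.split("\t")
        saw_data = True
        if ko_col is None:
            # fall back: first column whose value carries a ko: token
            for i, value in enumerate(fields):
                if _KO_TOKEN.search(value):
                    ko_col = i
                    break
            if ko_col is None:
                continue
        if ko_col >= len(fields):
            continue
        cell = fields[ko_col].strip()
        if not cell or cell == "-":
            continue
        for ko in _KO_TOKEN.findall(cell):
            vector.increment(ko)
    if saw_data and ko_col is None:
        raise AnnotationError(
            f"no KO column detected in annotation table for {genome_id!r}"
        )
    return vector


def build_feature_matrix(
    vectors: list[KOVector],
) -> tuple[pd.DataFrame, list[str]]:
    """Genome×KO copy-number matrix over the union of observed KOs.

    Columns are the lexicographically sorted union of every observed KO;
    a KO absent from a genome is 0.  Values are raw copy numbers —
    standardization happens at training time.
    """
    if not vectors:
        raise ValueError("need at least one KO vector")
    ids = [v.genome_id for v in vectors]
    if len(set(ids)) != len(ids):
        dupes = sorted({g for g in ids if ids.count(g) > 1})
        raise ValueError(f"duplicate genome ids: {dupes}")
    kos = sorted(set().union(*(v.counts.keys() for v in vectors)))
    matrix = pd.DataFrame(0, index=ids, columns=kos, dtype=np.int64)
    for v in vectors:
        if v.counts:
            matrix.loc[v.genome_id, list(v.counts)] = list(v.counts.values())
    matrix.index.name = "genome"
    return matrix, kos


def assign_labels(
    genomes: list[tuple[str, int]],
    matrix: pd.DataFrame,
    matches: dict[str, int],
    index: TaxonomyIndex,
) -> pd.DataFrame:
    """Binary genome×function labels by downward lineage propagation.

    A genome is positive for a function iff any taxid on its lineage (its
    own taxid or an ancestor) equals the matched taxid of a member taxon
    of that function.  ``matrix`` is the binary taxon×function matrix and
    ``matches`` maps its taxon-path rows to taxids (unmatched rows simply
    absent).
    """
    function_taxids: dict[str, set[int]] = {}
    for fn in matrix.columns:
        members = matrix.index[matrix[fn] == 1]
        taxids = {matches[t] for t in members if t in matches}
        function_taxids[fn] = taxids

    labels = pd.DataFrame(0, index=[g for g, _ in genomes],
                          columns=list(matrix.columns), dtype="int8")
    labels.index.name = "genome"
    for genome_id, taxid in genomes:
        if taxid not in index:
            raise ValueError(
                f"genome {genome_id!r}: taxid {taxid} absent from taxonomy"
            )
        lineage = set(index.lineage(taxid))
        for fn, taxids in function_taxids.items():
            if lineage & taxids:
                labels.loc[genome_id, fn] = 1
    return labels


def filter_classes(dataset: TraitDataset,
                   min_positives: int = DEFAULT_MIN_POSITIVES) -> TraitDataset:
    """Drop label classes with fewer than ``min_positives`` positive genomes.

    Genomes are never dropped; surviving columns are unchanged.
    """
    sizes = dataset.class_sizes()
    keep = sizes.index[sizes >= min_positives]
    dropped = sorted(set(dataset.class_names) - set(keep))
    if dropped:
        logger.info("dropping %d classes below %d positives: %s",
                    len(dropped), min_positives, ", ".join(dropped))
    if len(keep) == 0:
        raise ValueError(
            f"every class has fewer than {min_positives} positive genomes"
        )
    return TraitDataset(features=dataset.features,
                        labels=dataset.labels[list(keep)])


def save_dataset(dataset: TraitDataset, outdir) -> None:
    """Write features/labels as TSV plus a JSON manifest."""
    import hashlib
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.features.to_csv(outdir / "features.tsv", sep="\t")
    dataset.labels.to_csv(outdir / "labels.tsv", sep="\t")
    digest = hashlib.sha256(
        dataset.features.to_csv(sep="\t").encode()
        + dataset.labels.to_csv(sep="\t").encode()
    ).hexdigest()
    manifest = {
        "n_genomes": dataset.n_genomes,
        "feature_order": dataset.feature_order,
        "class_names": dataset.class_names,
        "sha256": digest,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_dataset(indir) -> TraitDataset:
    indir = Path(indir)
    features = pd.read_csv(indir / "features.tsv", sep="\t", index_col=0)
    labels = pd.read_csv(indir / "labels.tsv", sep="\t", index_col=0)
    return TraitDataset(features=features, labels=labels)
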