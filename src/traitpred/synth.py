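"""Synthetic inputs with known ground truth.

Every other module is testable offline through these generators: a
miniature taxon→function database file with set-operation directives, a
miniature NCBI-style taxonomy dump, annotation tables with planted
KO→function associations plus Poisson noise, and multi-contig FASTA
genomes (optionally with gene coordinates recorded, so fragmentation can
be propagated back to KO content).  All generators are pure functions of
their parameters and seed, and each returns its own ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import TraitDataset, build_feature_matrix, parse_annotation_table
from .faprotax import FunctionalGroup, FunctionalGroupSet
from .fragsim import FragmentationResult

_CONSONANTS = "bcdfglmnprstv"
_VOWELS = "aeiou"


def _word(rng: np.random.Generator, n_syllables: int = 3) -> str:
    return "".join(
        rng.choice(list(_CONSONANTS)) + rng.choice(list(_VOWELS))
        for _ in range(n_syllables)
    )


# ---------------------------------------------------------------------------
# Taxon→function database fixture


def synth_faprotax(
    n_groups: int,
    taxa_per_group: int,
    n_set_ops: int,
    seed: int = 0,
    taxon_pool: list[str] | None = None,
) -> tuple[str, FunctionalGroupSet]:
    """A database-format fixture file plus its ground-truth parse.

    Directives only ever reference earlier groups, so the directive graph
    is acyclic by construction.  ``taxon_pool`` can inject taxon paths
    whose leaves exist in a taxonomy fixture.
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    rng = np.random.default_rng(seed)
    if taxon_pool is None:
        taxon_pool = [
            f"Bacteria*{_word(rng, 2).capitalize()}ota*"
            f"{_word(rng, 3).capitalize()} {_word(rng, 2)}"
            for _ in range(max(3 * n_groups * taxa_per_group // 2, 4))
        ]
    fgs = FunctionalGroupSet(source_version=f"synthetic-{seed}")
    for gi in range(n_groups):
        group = FunctionalGroup(
            name=f"fn_{_word(rng, 2)}_{gi}",
            annotation=f"synthetic functional group {gi}",
        )
        picks = rng.choice(len(taxon_pool),
                           size=min(taxa_per_group, len(taxon_pool)),
                           replace=False)
        for p in sorted(picks):
            group.add_member(taxon_pool[p])
        fgs.groups[group.name] = group
    names = list(fgs.groups)
    ops_placed = 0
    while ops_placed < n_set_ops and n_groups > 1:
        gi = int(rng.integers(1, n_groups))
        target = names[int(rng.integers(0, gi))]
        op = str(rng.choice(["add", "subtract", "intersect"]))
        fgs.groups[names[gi]].directives.append((op, target))
        ops_placed += 1
    return fgs.to_text(), fgs


# ---------------------------------------------------------------------------
# Taxonomy dump fixture


@dataclass
class TaxonomyTruth:
    """Ground truth of a generated taxonomy dump."""

    root: int
    phyla: dict[str, int]
    genera: dict[str, int]
    species: dict[str, int]
    strains: dict[str, int]
    parent: dict[int, int]
    merged: dict[int, int]
    synonyms: dict[str, int]


def synth_taxonomy(
    n_species: int, strains_per_species: int, seed: int = 0
) -> tuple[str, str, str, TaxonomyTruth]:
    """names/nodes/merged dump content plus the fixture tree.

    Layout: root → 2 phyla → one genus per species → species → strains
    (lineage depth 5 when strains exist).  Includes one merged-id
    redirect and one synonym row per run.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    rng = np.random.default_rng(seed)
    next_id = 1
    nodes: list[tuple[int, int, str]] = []  # (taxid, parent, rank)
    names: list[tuple[int, str, str]] = []  # (taxid, name, name class)

    root = next_id
    next_id += 1
    nodes.append((root, root, "no rank"))
    names.append((root, "root", "scientific name"))

    n_phyla = min(2, n_species)
    phyla: dict[str, int] = {}
    for _ in range(n_phyla):
        name = f"{_word(rng, 3).capitalize()}ota"
        phyla[name] = next_id
        nodes.append((next_id, root, "phylum"))
        names.append((next_id, name, "scientific name"))
        next_id += 1
    phylum_ids = list(phyla.values())

    genera: dict[str, int] = {}
    species: dict[str, int] = {}
    strains: dict[str, int] = {}
    for si in range(n_species):
        genus_name = _word(rng, 3).capitalize()
        genera[genus_name] = next_id
        nodes.append((next_id, phylum_ids[si % n_phyla], "genus"))
        names.append((next_id, genus_name, "scientific name"))
        genus_id = next_id
        next_id += 1
        sp_name = f"{genus_name} {_word(rng, 2)}"
        species[sp_name] = next_id
        nodes.append((next_id, genus_id, "species"))
        names.append((next_id, sp_name, "scientific name"))
        sp_id = next_id
        next_id += 1
        for ti in range(strains_per_species):
            strain_name = f"{sp_name} strain {ti + 1}"
            strains[strain_name] = next_id
            nodes.append((next_id, sp_id, "strain"))
            names.append((next_id, strain_name, "scientific name"))
            next_id += 1

    first_species_name = next(iter(species))
    first_species_id = species[first_species_name]
    merged = {next_id: first_species_id}  # retired id redirect
    next_id += 1
    synonym_name = f"{_word(rng, 3).capitalize()} {_word(rng, 2)}"
    synonyms = {synonym_name: first_species_id}
    names.append((first_species_id, synonym_name, "synonym"))

    nodes_text = "\n".join(
        f"{t}\t|\t{p}\t|\t{r}\t|" for t, p, r in nodes
    )
    names_text = "\n".join(
        f"{t}\t|\t{n}\t|\t\t|\t{c}\t|" for t, n, c in names
    )
    merged_text = "\n".join(
        f"{old}\t|\t{new}\t|" for old, new in merged.items()
    )
    parent = {t: p for t, p, _ in nodes}
    truth = TaxonomyTruth(root=root, phyla=phyla, genera=genera,
                          species=species, strains=strains, parent=parent,
                          merged=merged, synonyms=synonyms)
    return names_text, nodes_text, merged_text, truth


# ---------------------------------------------------------------------------
# Planted-signal trait dataset fixture


@dataclass
class SyntheticTruth:
    """Planted ground truth of a generated trait dataset.

    ``planted_associations`` maps class name → {KO id: effect}, where the
    effect is the expected copy number of that KO in positive genomes
    (negatives draw from a low background rate).  ``class_sizes`` gives
    positives per class; ``noise_rate`` is the probability that any count
    cell is perturbed (resampled from Poisson(1)).
    """

    planted_associations: dict[str, dict[str, float]]
    class_sizes: dict[str, int]
    noise_rate: float = 0.05
    seed: int = 0
    negative_rate: float = 0.1
    background_rate: float = 0.5
    taxonomy: TaxonomyTruth | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.noise_rate < 0.5:
            raise ValueError("noise_rate must be in [0, 0.5)")


def make_default_truth(
    n_classes: int = 5,
    kos_per_class: int = 20,
    effect: float = 5.0,
    positives_per_class: int = 30,
    noise_rate: float = 0.05,
    seed: int = 0,
) -> SyntheticTruth:
    """The standard planted-signal fixture configuration.

    Five classes with 20 disjoint informative KOs each (expected copy
    number 5 in positives), 30 positive genomes per class, and a 5% cell
    perturbation rate.
    """
    planted: dict[str, dict[str, float]] = {}
    ko_counter = 1
    for ci in range(n_classes):
        kos = {f"K{ko_counter + j:05d}": effect for j in range(kos_per_class)}
        ko_counter += kos_per_class
        planted[f"class_{ci}"] = kos
    sizes = {c: positives_per_class for c in planted}
    return SyntheticTruth(planted_associations=planted, class_sizes=sizes,
                          noise_rate=noise_rate, seed=seed)


_EGGNOG_COLUMNS = (
    "#query\tseed_ortholog\tevalue\tscore\teggNOG_OGs\tmax_annot_lvl\t"
    "COG_category\tDescription\tPreferred_name\tGOs\tEC\tKEGG_ko\t"
    "KEGG_Pathway\tKEGG_Module"
)


def _annotation_text(genome_id: str, counts: dict[str, int],
                     n_unannotated: int = 2) -> str:
    """Emit one genome's annotation table in the eggNOG-mapper layout."""
    lines = [
        f"## synthetic annotation for {genome_id}",
        _EGGNOG_COLUMNS,
    ]
    gene_no = 0
    for ko in sorted(counts):
        for _ in range(counts[ko]):
            gene_no += 1
            lines.append(
                f"{genome_id}_{gene_no:05d}\tseed\t1e-50\t200.0\tOG@1\t"
                f"2|Bacteria\tC\tsynthetic gene\t-\t-\t-\tko:{ko}\t-\t-"
            )
    for _ in range(n_unannotated):
        gene_no += 1
        lines.append(
            f"{genome_id}_{gene_no:05d}\tseed\t1e-10\t60.0\tOG@1\t"
            f"2|Bacteria\tS\thypothetical\t-\t-\t-\t-\t-\t-"
        )
    return "\n".join(lines) + "\n"


def synth_dataset(
    truth: SyntheticTruth,
    n_genomes: int = 200,
    n_background_kos: int = 400,
) -> tuple[dict[str, str], pd.DataFrame, TraitDataset]:
    """Annotation tables + label matrix + the assembled dataset.

    Positive genomes of a class draw its informative KO counts from
    Poisson(effect); negatives from Poisson(0.1); background KOs from
    Poisson(0.5) for everyone.  Each cell is perturbed with probability
    ``noise_rate``.  Positive blocks are disjoint across classes and laid
    out genome-block by genome-block.
    """
    if sum(truth.class_sizes.values()) > n_genomes:
        raise ValueError("class_sizes sum exceeds n_genomes")
    rng = np.random.default_rng(truth.seed)
    classes = list(truth.planted_associations)
    informative = sorted(
        {ko for kos in truth.planted_associations.values() for ko in kos}
    )
    max_planted = max(
        (int(ko[1:]) for ko in informative), default=0
    )
    background = [f"K{max_planted + 1 + j:05d}"
                  for j in range(n_background_kos)]
    all_kos = informative + background
    genome_ids = [f"G{gi + 1:04d}" for gi in range(n_genomes)]

    labels = pd.DataFrame(0, index=genome_ids, columns=classes,
                          dtype="int8")
    labels.index.name = "genome"
    start = 0
    for c in classes:
        size = truth.class_sizes.get(c, 0)
        labels.iloc[start:start + size,
                    labels.columns.get_loc(c)] = 1
        start += size

    counts = pd.DataFrame(0, index=genome_ids, columns=all_kos,
                          dtype=np.int64)
    for ko in background:
        counts[ko] = rng.poisson(truth.background_rate, size=n_genomes)
    seen_informative: set[str] = set()
    for c in classes:
        pos_mask = labels[c].values == 1
        for ko, effect in truth.planted_associations[c].items():
            col = rng.poisson(truth.negative_rate, size=n_genomes)
            col[pos_mask] = rng.poisson(effect, size=int(pos_mask.sum()))
            if ko in seen_informative:  # KO shared across classes
                counts[ko] = np.maximum(counts[ko].values, col)
            else:
                counts[ko] = col
                seen_informative.add(ko)
    if truth.noise_rate > 0:
        flip = rng.random(counts.shape) < truth.noise_rate
        noise = rng.poisson(1.0, size=counts.shape)
        counts = counts.where(~flip, noise)

    # union semantics: KOs observed nowhere cannot appear as features
    observed = counts.columns[counts.sum(axis=0) > 0]
    features = counts[sorted(observed)].astype(np.int64)
    features.index.name = "genome"

    annotations = {
        g: _annotation_text(
            g, {ko: int(v) for ko, v in counts.loc[g].items() if v > 0}
        )
        for g in genome_ids
    }
    dataset = TraitDataset(features=features, labels=labels)
    return annotations, labels.copy(), dataset


def rebuild_from_annotations(annotations: dict[str, str]) -> pd.DataFrame:
    """Re-ingest generated annotation tables through the standard parser."""
    vectors = [parse_annotation_table(text, genome_id=g)
               for g, text in annotations.items()]
    matrix, _ = build_feature_matrix(vectors)
    return matrix


# ---------------------------------------------------------------------------
# Genome sequence fixtures


def synth_genome_fasta(
    n_contigs: int, total_length: int, gc: float = 0.5, seed: int = 0
) -> str:
    """Random multi-contig FASTA with the requested GC content (±2%)."""
    if total_length < n_contigs:
        raise ValueError("total_length must be >= n_contigs")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    base_len = total_length // n_contigs
    lines = []
    for ci in range(n_contigs):
        length = base_len + (total_length - base_len * n_contigs
                             if ci == n_contigs - 1 else 0)
        seq = "".join(rng.choice(list("ACGT"), size=length, p=probs))
        lines.append(f">contig_{ci + 1}")
        for i in range(0, length, 80):
            lines.append(seq[i:i + 80])
    return "\n".join(lines) + "\n"


@dataclass
class GeneMap:
    """Coordinates of planted gene copies inside a synthetic genome."""

    genome_id: str
    fasta: str
    genes: pd.DataFrame  # columns: contig, start, end, ko (0-based, half-open)


def synth_genome_with_genes(
    genome_id: str,
    ko_counts: dict[str, int],
    gene_length: int = 300,
    spacer_length: int = 200,
    gc: float = 0.5,
    seed: int = 0,
) -> GeneMap:
    """A single-contig genome carrying one interval per KO gene copy.

    Gene order is shuffled; spacers separate consecutive genes.  The
    returned coordinate table lets fragmentation be translated back into
    surviving KO copy numbers.
    """
    rng = np.random.default_rng(seed)
    gene_list = [ko for ko in sorted(ko_counts)
                 for _ in range(ko_counts[ko])]
    rng.shuffle(gene_list)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]

    def _seq(n: int) -> str:
        return "".join(rng.choice(list("ACGT"), size=n, p=probs))

    parts = [_seq(spacer_length)]
    pos = spacer_length
    rows = []
    for ko in gene_list:
        rows.append({"contig": "contig_1", "start": pos,
                     "end": pos + gene_length, "ko": ko})
        parts.append(_seq(gene_length))
        pos += gene_length
        parts.append(_seq(spacer_length))
        pos += spacer_length
    seq = "".join(parts)
    body = "\n".join(seq[i:i + 80] for i in range(0, len(seq), 80))
    fasta = f">contig_1\n{body}\n"
    genes = pd.DataFrame(rows, columns=["contig", "start", "end", "ko"])
    return GeneMap(genome_id=genome_id, fasta=fasta, genes=genes)


def fragmentation_robustness_profile(
    dataset,
    registry,
    levels: tuple[float, ...] = (0.9, 0.7, 0.5),
    seed: int = 0,
    gene_length: int = 300,
    spacer_length: int = 200,
) -> pd.DataFrame:
    """Mean per-class MCC of a registry on fragmented fixture genomes.

    Every genome of the dataset is materialized as a synthetic sequence
    carrying one interval per KO gene copy, fragmented at each
    completeness level, re-counted (a gene copy counts only if its
    interval survives intact) and re-predicted.  Returns one row per
    level — plus a ``complete`` row at level 1.0 — with the mean MCC over
    classes (zero-positive classes scored 0).
    """
    from .apply import evaluate_predictions, predict_functions
    from .dataset import KOVector
    from .fragsim import FragmentationSpec, derive_seed, fragment_genome

    gene_maps = {}
    for genome_id in dataset.features.index:
        counts = {k: int(v) for k, v in dataset.features.loc[genome_id].items()
                  if v > 0}
        gene_maps[genome_id] = synth_genome_with_genes(
            genome_id, counts, gene_length=gene_length,
            spacer_length=spacer_length,
            seed=derive_seed(seed, genome_id, 1.0),
        )

    rows = []
    for level in (1.0, *levels):
        queries = []
        for genome_id, gm in gene_maps.items():
            if level == 1.0:
                counts = {k: int(v)
                          for k, v in dataset.features.loc[genome_id].items()
                          if v > 0}
            else:
                spec = FragmentationSpec(
                    target_completeness=level,
                    seed=derive_seed(seed, genome_id, level),
                )
                result = fragment_genome(gm.fasta, spec)
                counts = surviving_ko_counts(result, gm)
            queries.append(KOVector(genome_id, counts))
        report = predict_functions(registry, queries)
        table = evaluate_predictions(
            report, dataset.labels, zero_positive_mcc_as_zero=True
        )
        rows.append({"level": level, "mean_mcc": float(table["mcc"].mean()),
                     "n_genomes": len(queries)})
    return pd.DataFrame(rows).set_index("level")


def surviving_ko_counts(result: FragmentationResult,
                        gene_map: GeneMap) -> dict[str, int]:
    """KO copy numbers of the genes left intact after fragmentation.

    A gene copy survives iff its full interval lies inside one retained
    fragment of its contig.
    """
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for frag in result.fragments:
        by_contig.setdefault(frag.parent, []).append((frag.start, frag.end))
    counts: dict[str, int] = {}
    for row in gene_map.genes.itertuples(index=False):
        for lo, hi in by_contig.get(row.contig, ()):
            if lo <= row.start and row.end <= hi:
                counts[row.ko] = counts.get(row.ko, 0) + 1
                break
    return counts
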