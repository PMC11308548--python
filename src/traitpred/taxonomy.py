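"""NCBI taxonomy handling: dump loading, name matching, genome selection.

Reads the ``names.dmp`` / ``nodes.dmp`` / ``merged.dmp`` pipe-delimited
dump dialect, matches FAPROTAX leaf names to taxids (perfect match first,
then a fixed imperfect-match cascade), expands descendant subtrees, applies
the per-species genome cap with complete-genome priority, and filters
genomes on completeness/contamination estimates.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MATCH_PERFECT = "perfect"
MATCH_IMPERFECT = "imperfect"
MATCH_UNMATCHED = "unmatched"


class TaxonomyError(ValueError):
    pass


@dataclass
class TaxonMatch:
    query: str
    taxid: int | None
    match_type: str
    matched_name: str = ""


@dataclass
class GenomeRecord:
    """One candidate genome with its quality and assembly metadata."""

    accession: str
    taxid: int
    species_taxid: int
    assembly_level: str = "other"  # "complete" or "other"
    completeness: float | None = None
    contamination: float | None = None
    path: str = ""


@dataclass
class SelectionPolicy:
    """Per-species download cap with complete-genome priority."""

    per_species_cap: int = 30
    prioritize_complete: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.per_species_cap < 1:
            raise ValueError("per_species_cap must be >= 1")


def _split_dmp_line(line: str) -> list[str]:
    # dmp rows are "<f>\t|\t<f>\t|\t...\t|" (tab-pipe-tab separators)
    return [f.strip() for f in line.rstrip("\n").rstrip("|\t").split("\t|\t")]


@dataclass
class TaxonomyIndex:
    """In-memory index over an NCBI taxonomy dump.

    ``nodes`` maps taxid -> (rank, parent_id, scientific_name); name lookup
    covers scientific names and synonym name classes; ``merged`` redirects
    retired ids to their replacement in one hop.
    """

    nodes: dict[int, tuple[str, int, str]] = field(default_factory=dict)
    name_to_ids: dict[str, set[int]] = field(default_factory=dict)
    synonym_to_ids: dict[str, set[int]] = field(default_factory=dict)
    merged: dict[int, int] = field(default_factory=dict)
    children: dict[int, list[int]] = field(default_factory=dict)

    def resolve_id(self, taxid: int) -> int:
        return self.merged.get(taxid, taxid)

    def __contains__(self, taxid: int) -> bool:
        return self.resolve_id(taxid) in self.nodes

    def rank(self, taxid: int) -> str:
        return self.nodes[self.resolve_id(taxid)][0]

    def parent(self, taxid: int) -> int:
        return self.nodes[self.resolve_id(taxid)][1]

    def scientific_name(self, taxid: int) -> str:
        return self.nodes[self.resolve_id(taxid)][2]

    def lineage(self, taxid: int) -> list[int]:
        """Taxids from the node up to (and including) the root."""
        taxid = self.resolve_id(taxid)
        if taxid not in self.nodes:
            raise TaxonomyError(f"unknown taxid {taxid}")
        out = [taxid]
        seen = {taxid}
        while True:
            parent = self.nodes[taxid][1]
            if parent == taxid or parent in seen:
                break
            if parent not in self.nodes:
                break
            out.append(parent)
            seen.add(parent)
            taxid = parent
        return out

    def ancestor_at_rank(self, taxid: int, rank: str) -> int | None:
        for anc in self.lineage(taxid):
            if self.nodes[anc][0] == rank:
                return anc
        return None


def load_taxonomy(names_table: str, nodes_table: str,
                  merged_table: str = "") -> TaxonomyIndex:
    """Build a :class:`TaxonomyIndex` from dump-file content strings.

    ``names_table``/``nodes_table``/``merged_table`` are the *contents* of
    ``names.dmp``, ``nodes.dmp`` and ``merged.dmp``.  Malformed rows raise
    :class:`TaxonomyError` with the offending line number.
    """
    idx = TaxonomyIndex()

    for lineno, line in enumerate(nodes_table.splitlines(), start=1):
        if not line.strip():
            continue
        fields = _split_dmp_line(line)
        if len(fields) < 3:
            raise TaxonomyError(f"nodes table line {lineno}: malformed row")
        try:
            taxid, parent = int(fields[0]), int(fields[1])
        except ValueError as exc:
            raise TaxonomyError(
                f"nodes table line {lineno}: non-integer taxid"
            ) from exc
        idx.nodes[taxid] = (fields[2], parent, "")
        if parent != taxid:
            idx.children.setdefault(parent, []).append(taxid)
    if not idx.nodes:
        raise TaxonomyError("nodes table is empty")

    for lineno, line in enumerate(names_table.splitlines(), start=1):
        if not line.strip():
            continue
        fields = _split_dmp_line(line)
        if len(fields) < 4:
            raise TaxonomyError(f"names table line {lineno}: malformed row")
        try:
            taxid = int(fields[0])
        except ValueError as exc:
            raise TaxonomyError(
                f"names table line {lineno}: non-integer taxid"
            ) from exc
        name, name_class = fields[1], fields[3]
        if taxid not in idx.nodes:
            logger.warning("names table line %d: taxid %d not in nodes",
                           lineno, taxid)
            continue
        if name_class == "scientific name":
            rank, parent, _ = idx.nodes[taxid]
            idx.nodes[taxid] = (rank, parent, name)
            idx.name_to_ids.setdefault(name, set()).add(taxid)
        else:  # synonym, equivalent name, common name, ...
            idx.synonym_to_ids.setdefault(name, set()).add(taxid)

    for lineno, line in enumerate(merged_table.splitlines(), start=1):
        if not line.strip():
            continue
        fields = _split_dmp_line(line)
        if len(fields) < 2:
            raise TaxonomyError(f"merged table line {lineno}: malformed row")
        try:
            old, new = int(fields[0]), int(fields[1])
        except ValueError as exc:
            raise TaxonomyError(
                f"merged table line {lineno}: non-integer taxid"
            ) from exc
        idx.merged[old] = new

    for kids in idx.children.values():
        kids.sort()
    return idx


_BRACKET_RE = re.compile(r"[\[\](){}]")


def _normalize_name(name: str) -> str:
    return " ".join(_BRACKET_RE.sub("", name).split()).lower()


def _unique_or_none(ids: set[int], query: str) -> int | None:
    if len(ids) == 1:
        return next(iter(ids))
    logger.warning("taxon name %r is ambiguous across taxids %s; "
                   "left unmatched", query, sorted(ids))
    return None


def match_taxon_names(queries: list[str],
                      index: TaxonomyIndex) -> list[TaxonMatch]:
    """Match leaf names against the taxonomy.

    Perfect = exact string equality with a scientific name.  Imperfect
    matching then tries, in order: case-insensitive comparison, synonym
    name classes, and comparison after stripping bracketed qualifiers and
    collapsing whitespace; the first success wins.  A name hitting more
    than one taxid is left unmatched with a logged ambiguity.
    """
    folded_sci: dict[str, set[int]] = {}
    normalized_sci: dict[str, set[int]] = {}
    for name, ids in index.name_to_ids.items():
        folded_sci.setdefault(name.lower(), set()).update(ids)
        normalized_sci.setdefault(_normalize_name(name), set()).update(ids)
    normalized_syn: dict[str, set[int]] = {}
    for name, ids in index.synonym_to_ids.items():
        normalized_syn.setdefault(_normalize_name(name), set()).update(ids)

    out: list[TaxonMatch] = []
    for query in queries:
        ids = index.name_to_ids.get(query)
        if ids:
            taxid = _unique_or_none(ids, query)
            if taxid is not None:
                out.append(TaxonMatch(query, taxid, MATCH_PERFECT, query))
                continue
            out.append(TaxonMatch(query, None, MATCH_UNMATCHED))
            continue

        matched: int | None = None
        for table in (
            folded_sci.get(query.strip().lower()),
            index.synonym_to_ids.get(query),
            normalized_syn.get(_normalize_name(query)),
            normalized_sci.get(_normalize_name(query)),
        ):
            if table:
                matched = _unique_or_none(table, query)
                break
        if matched is not None:
            out.append(TaxonMatch(query, matched, MATCH_IMPERFECT,
                                  index.scientific_name(matched)))
        else:
            out.append(TaxonMatch(query, None, MATCH_UNMATCHED))
    return out


def expand_descendants(taxid: int, index: TaxonomyIndex) -> list[int]:
    """All strict descendants of ``taxid`` plus the node itself.

    Deterministic preorder with numerically sorted children.
    """
    taxid = index.resolve_id(taxid)
    if taxid not in index.nodes:
        raise TaxonomyError(f"unknown taxid {taxid}")
    out: list[int] = []
    stack = [taxid]
    while stack:
        node = stack.pop()
        out.append(node)
        stack.extend(reversed(index.children.get(node, ())))
    return out


def select_genomes(candidates: list[GenomeRecord],
                   policy: SelectionPolicy | None = None) -> list[GenomeRecord]:
    """Apply the per-species cap, prioritizing complete genomes.

    Within each species (grouped by ``species_taxid``): if the species has
    at most ``per_species_cap`` candidates, all are kept; otherwise complete
    genomes are kept first (seeded subsample if they alone exceed the cap)
    and the remaining slots are filled by seeded uniform sampling without
    replacement from the draft genomes.
    """
    policy = policy or SelectionPolicy()
    by_species: dict[int, list[GenomeRecord]] = {}
    for rec in candidates:
        by_species.setdefault(rec.species_taxid, []).append(rec)

    selected: list[GenomeRecord] = []
    for species in sorted(by_species):
        recs = sorted(by_species[species], key=lambda r: r.accession)
        if len(recs) <= policy.per_species_cap:
            selected.extend(recs)
            continue
        rng = np.random.default_rng((policy.seed, species))
        if policy.prioritize_complete:
            complete = [r for r in recs if r.assembly_level == "complete"]
            drafts = [r for r in recs if r.assembly_level != "complete"]
        else:
            complete, drafts = [], recs
        if len(complete) >= policy.per_species_cap:
            pick = rng.choice(len(complete), size=policy.per_species_cap,
                              replace=False)
            selected.extend(complete[i] for i in sorted(pick))
        else:
            selected.extend(complete)
            n_fill = policy.per_species_cap - len(complete)
            pick = rng.choice(len(drafts), size=n_fill, replace=False)
            selected.extend(drafts[i] for i in sorted(pick))
    return selected


def qc_filter(
    records: list[GenomeRecord],
    min_completeness: float = 90.0,
    max_contamination: float = 5.0,
) -> tuple[list[GenomeRecord], list[tuple[GenomeRecord, str]]]:
    """Partition genomes into (kept, rejected-with-reason).

    A genome is kept iff completeness >= 90 and contamination <= 5 (the
    removal rule is strict: *lower than* 90, *higher than* 5, so the
    boundary values pass).  Genomes missing either estimate are rejected
    as ``unscored``.
    """
    kept: list[GenomeRecord] = []
    rejected: list[tuple[GenomeRecord, str]] = []
    for rec in records:
        if rec.completeness is None or rec.contamination is None:
            rejected.append((rec, "unscored"))
        elif rec.completeness < min_completeness:
            rejected.append((rec, f"completeness {rec.completeness} < "
                                  f"{min_completeness}"))
        elif rec.contamination > max_contamination:
            rejected.append((rec, f"contamination {rec.contamination} > "
                                  f"{max_contamination}"))
        else:
            kept.append(rec)
    return kept, rejected


def rank_distribution(records: list[GenomeRecord], target_rank: str,
                      index: TaxonomyIndex) -> pd.DataFrame:
    """Distribution of genomes over ancestors at ``target_rank``.

    Genomes whose lineage lacks the rank are bucketed as ``unranked``.
    Returns a DataFrame with columns ``count`` and ``percentage`` indexed
    by ancestor scientific name.
    """
    buckets: dict[str, int] = {}
    for rec in records:
        anc = index.ancestor_at_rank(rec.taxid, target_rank)
        label = index.scientific_name(anc) if anc is not None else "unranked"
        buckets[label] = buckets.get(label, 0) + 1
    table = pd.DataFrame(
        {"count": pd.Series(buckets, dtype=int)}
    ).sort_values("count", ascending=False)
    table["percentage"] = 100.0 * table["count"] / max(len(records), 1)
    table.index.name = target_rank
    return table
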