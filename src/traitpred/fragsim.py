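"""Simulated fragmented genomes (SFGs) by random segment removal.

Emulates the incompleteness of metagenome-assembled genomes: segments of
normally-distributed length are excised at random positions until the
retained length falls to a target fraction of the species' reference
genome size.  Completeness here is purely length-based — the effect on
gene content is whatever the removed coordinates happen to hit.

Coordinates are 0-based, half-open throughout; output headers record the
parent contig and the retained interval as ``parent:start-end``.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

DEFAULT_LEVELS = (0.9, 0.7, 0.5)


@dataclass
class FragmentationSpec:
    """Parameters of one fragmentation run.

    ``target_completeness`` is the retained fraction of
    ``reference_size`` (the species genome size; defaults to the input's
    own total length).  Removal lengths are drawn from
    Normal(removal_length_mean, removal_length_sd), truncated to the
    remaining excess.
    """

    target_completeness: float
    removal_length_mean: float = 5000.0
    removal_length_sd: float = 1500.0
    reference_size: int | None = None
    seed: int = 0
    tolerance: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.target_completeness <= 1:
            raise ValueError("target_completeness must be in (0, 1]")
        if self.removal_length_mean <= 0:
            raise ValueError("removal_length_mean must be > 0")
        if self.removal_length_sd <= 0:
            raise ValueError("removal_length_sd must be > 0")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")


@dataclass
class Fragment:
    """A retained interval of a parent contig."""

    parent: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class FragmentationResult:
    fragments: list[Fragment]
    records: list[SeqRecord]
    removed_length: int
    original_length: int
    achieved_completeness: float
    spec: FragmentationSpec = field(repr=False, default=None)

    @property
    def retained_length(self) -> int:
        return self.original_length - self.removed_length


def _read_fasta(fasta) -> list[SeqRecord]:
    if isinstance(fasta, (str, Path)) and "\n" not in str(fasta) \
            and Path(fasta).exists():
        return list(SeqIO.parse(str(fasta), "fasta"))
    return list(SeqIO.parse(StringIO(str(fasta)), "fasta"))


def fragment_genome(fasta, spec: FragmentationSpec) -> FragmentationResult:
    """Fragment one genome down to the target completeness.

    Repeatedly draws a removal length L ~ Normal(mean, sd) truncated to
    [1, remaining excess], picks a contig weighted by current length and a
    uniform start position, and excises ``[start, start+L)``, splitting
    the contig in two (empty pieces are discarded).  Stops once
    ``retained <= target * reference_size * (1 + tolerance)``.  Every
    output sequence is an exact substring of an input sequence, and
    retained + removed lengths equal the original total exactly.
    """
    parents = _read_fasta(fasta)
    if not parents:
        raise ValueError("no sequences in input FASTA")
    for rec in parents:
        if len(rec.seq) == 0:
            raise ValueError(f"empty sequence {rec.id!r}")
    seqs = {rec.id: str(rec.seq) for rec in parents}
    total = sum(len(s) for s in seqs.values())
    reference = spec.reference_size or total
    target_len = spec.target_completeness * reference
    stop_len = target_len * (1 + spec.tolerance)
    if total < target_len:
        raise ValueError(
            f"target unachievable: input holds {total} bp, below the "
            f"target of {target_len:.0f} bp"
        )

    rng = np.random.default_rng(spec.seed)
    fragments = [Fragment(rec.id, 0, len(rec.seq)) for rec in parents]
    retained = total

    while retained > stop_len:
        excess = retained - target_len
        L = int(round(rng.normal(spec.removal_length_mean,
                                 spec.removal_length_sd)))
        L = max(1, min(L, int(np.ceil(excess))))
        lengths = np.array([len(f) for f in fragments], dtype=float)
        fi = int(rng.choice(len(fragments), p=lengths / lengths.sum()))
        frag = fragments[fi]
        start = frag.start + int(rng.integers(0, len(frag)))
        end = min(start + L, frag.end)
        removed = end - start
        left = Fragment(frag.parent, frag.start, start)
        right = Fragment(frag.parent, end, frag.end)
        replacement = [p for p in (left, right) if len(p) > 0]
        fragments[fi:fi + 1] = replacement
        retained -= removed
        if not fragments:
            break

    records = [
        SeqRecord(
            Seq(seqs[f.parent][f.start:f.end]),
            id=f"{f.parent}:{f.start}-{f.end}",
            description=f"parent={f.parent} start={f.start} end={f.end}",
        )
        for f in fragments
    ]
    return FragmentationResult(
        fragments=fragments,
        records=records,
        removed_length=total - retained,
        original_length=total,
        achieved_completeness=retained / reference,
        spec=spec,
    )


def write_fasta(records: list[SeqRecord], path) -> None:
    """FASTA output wrapped at 80 columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id} {rec.description}\n")
            s = str(rec.seq)
            for i in range(0, len(s), 80):
                fh.write(s[i:i + 80] + "\n")


def derive_seed(master_seed: int, genome_id: str, level: float) -> int:
    """Deterministic per-genome, per-level seed below 2**31."""
    digest = hashlib.sha256(
        f"{master_seed}:{genome_id}:{level}".encode()
    ).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def build_sfg_dataset(
    genomes: dict[str, object],
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    seed: int = 0,
    reference_sizes: dict[str, int] | None = None,
    outdir=None,
    removal_length_mean: float = 5000.0,
    removal_length_sd: float = 1500.0,
    tolerance: float = 0.01,
) -> tuple[dict[float, dict[str, FragmentationResult]], pd.DataFrame]:
    """Fragment every genome at every completeness level.

    ``genomes`` maps genome id -> FASTA (path or text).  Per-genome seeds
    are derived deterministically from the master seed and genome id.
    Returns one collection per level plus a manifest recording the
    achieved completeness of each output; genomes that fail at a level are
    skipped there with a logged reason.  When ``outdir`` is given, each
    fragmented genome is written to ``<outdir>/<level>/<genome>.fna``.
    """
    reference_sizes = reference_sizes or {}
    collections: dict[float, dict[str, FragmentationResult]] = {}
    manifest_rows = []
    for level in levels:
        collections[level] = {}
        for genome_id, fasta in genomes.items():
            spec = FragmentationSpec(
                target_completeness=level,
                removal_length_mean=removal_length_mean,
                removal_length_sd=removal_length_sd,
                reference_size=reference_sizes.get(genome_id),
                seed=derive_seed(seed, genome_id, level),
                tolerance=tolerance,
            )
            try:
                result = fragment_genome(fasta, spec)
            except ValueError as exc:
                logger.warning("genome %r skipped at level %.2f: %s",
                               genome_id, level, exc)
                continue
            collections[level][genome_id] = result
            manifest_rows.append({
                "genome": genome_id,
                "level": level,
                "achieved_completeness": result.achieved_completeness,
                "n_contigs_out": len(result.records),
                "seed": spec.seed,
                "removal_length_mean": removal_length_mean,
                "removal_length_sd": removal_length_sd,
            })
            if outdir is not None:
                level_dir = Path(outdir) / f"{int(level * 100)}"
                level_dir.mkdir(parents=True, exist_ok=True)
                write_fasta(result.records,
                            level_dir / f"{genome_id}.fna")
    manifest = pd.DataFrame(manifest_rows)
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        manifest.to_csv(Path(outdir) / "manifest.tsv", sep="\t",
                        index=False)
    return collections, manifest
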