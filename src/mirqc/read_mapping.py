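"""Mismatch-tolerant read assignment with genome preference.

Annotation follows a two-step scheme.  Step 1 maps each insert against
the species genome and against bacterial/viral contaminant genomes,
allowing at most one substitution; genome hits always win over
contaminant hits (multi-mapping preference for the reference genome).
Step 2 queries genome-mapped inserts against annotation sets in fixed
priority order: miRNA (mature, then hairpin) > rRNA > tRNA > other ncRNA
> mRNA; the first annotation set with any hit decides the category, and
mismatch counts break ties only within a set, never across sets.
Genome-mapped inserts with no annotation hit are ``genomeOther``.

Matching is seed-and-verify, full-length, substitutions only (no
indels), on both strands — the Bowtie ``-v 1`` alignment model.  Under a
1-substitution budget the pigeonhole principle guarantees an exact seed:
for inserts >= 24 nt either the first or last 12-mer is clean; shorter
inserts are split into two halves (one of which must be clean) anchored
through a secondary 7-mer table.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

from .fastq_io import ReferenceSet

logger = logging.getLogger(__name__)

# assignment categories
MIRNA = "miRNA"
RRNA = "rRNA"
TRNA = "tRNA"
OTHER_NCRNA = "otherNcRNA"
MRNA = "mRNA"
GENOME_OTHER = "genomeOther"
CONTAMINANT_BACTERIAL = "contaminantBacterial"
CONTAMINANT_VIRAL = "contaminantViral"
UNMAPPED = "unmapped"

ASSIGNMENT_CATEGORIES = (
    MIRNA,
    RRNA,
    TRNA,
    OTHER_NCRNA,
    MRNA,
    GENOME_OTHER,
    CONTAMINANT_BACTERIAL,
    CONTAMINANT_VIRAL,
    UNMAPPED,
)

#: step-2 annotation priority: (reference set name, category)
ANNOTATION_PRIORITY = (
    ("mirna_mature", MIRNA),
    ("mirna_hairpin", MIRNA),
    ("rrna", RRNA),
    ("trna", TRNA),
    ("other_ncrna", OTHER_NCRNA),
    ("mrna", MRNA),
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_SEED_LENGTH = 12
SHORT_SEED_LENGTH = 7


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


class Hit(NamedTuple):
    """One end-to-end alignment of an insert inside a reference strand."""

    reference_id: str
    offset: int  # 0-based start within the given strand's sequence
    strand: str  # '+' or '-'
    mismatches: int


@dataclass
class MatchIndex:
    """K-mer seed tables over both strands of a reference set."""

    reference_set_name: str
    seed_length: int
    strands: dict[tuple[str, str], str]  # (reference id, strand) -> sequence
    seeds: dict[str, list[tuple[str, str, int]]]
    short_seeds: dict[str, list[tuple[str, str, int]]]

    def is_empty(self) -> bool:
        return not self.strands


def build_index(
    refset: ReferenceSet, seed_length: int = DEFAULT_SEED_LENGTH
) -> MatchIndex:
    """Index every seed of the forward and reverse-complement strand.

    References shorter than ``seed_length`` are skipped with a warning: no
    insert of mappable length could align end-to-end inside them anyway.
    """
    strands: dict[tuple[str, str], str] = {}
    seeds: dict[str, list[tuple[str, str, int]]] = defaultdict(list)
    short_seeds: dict[str, list[tuple[str, str, int]]] = defaultdict(list)
    for rid, seq in refset.entries.items():
        if len(seq) < seed_length:
            logger.warning(
                "reference %s/%s shorter than seed length %d; skipped",
                refset.name,
                rid,
                seed_length,
            )
            continue
        for strand, sseq in (("+", seq), ("-", reverse_complement(seq))):
            strands[(rid, strand)] = sseq
            for off in range(len(sseq) - seed_length + 1):
                seeds[sseq[off : off + seed_length]].append((rid, strand, off))
            for off in range(len(sseq) - SHORT_SEED_LENGTH + 1):
                short_seeds[sseq[off : off + SHORT_SEED_LENGTH]].append(
                    (rid, strand, off)
                )
    return MatchIndex(refset.name, seed_length, strands, dict(seeds), dict(short_seeds))


def _mismatches_at(insert: str, reference: str, start: int, budget: int) -> int:
    """Count substitutions of ``insert`` vs reference[start:], early exit."""
    mm = 0
    for i, base in enumerate(insert):
        if base != reference[start + i]:
            mm += 1
            if mm > budget:
                return mm
    return mm


def match_read(
    insert: str, index: MatchIndex, max_mismatches: int = 1
) -> list[Hit]:
    """All end-to-end alignments of ``insert`` with <= 1 substitution.

    Candidate positions come from exact seed lookups; each candidate is
    verified over the full insert length.  Seeds are chosen so that any
    alignment within the mismatch budget is anchored by at least one
    exact seed (pigeonhole over halves / first+last 12-mer).
    """
    L = len(insert)
    if index.is_empty() or L < 2 * SHORT_SEED_LENGTH:
        return []
    # (position of seed within insert, seed string) pairs
    anchors: list[tuple[int, str]]
    if L >= 2 * index.seed_length:
        anchors = [
            (0, insert[: index.seed_length]),
            (L - index.seed_length, insert[L - index.seed_length :]),
        ]
        table = index.seeds
    else:
        half = L // 2
        anchors = [
            (0, insert[:SHORT_SEED_LENGTH]),
            (half, insert[half : half + SHORT_SEED_LENGTH]),
        ]
        table = index.short_seeds
    candidates: set[tuple[str, str, int]] = set()
    for seed_pos, seed in anchors:
        for rid, strand, off in table.get(seed, ()):
            candidates.add((rid, strand, off - seed_pos))
    hits: list[Hit] = []
    for rid, strand, start in candidates:
        ref_seq = index.strands[(rid, strand)]
        if start < 0 or start + L > len(ref_seq):
            continue
        mm = _mismatches_at(insert, ref_seq, start, max_mismatches)
        if mm <= max_mismatches:
            hits.append(Hit(rid, start, strand, mm))
    hits.sort(key=lambda h: (h.mismatches, h.reference_id, h.strand, h.offset))
    return hits


@dataclass
class ReadAssignment:
    insert_sequence: str
    multiplicity: int
    category: str
    best_hit: Hit | None = None
    mirna_id: str | None = None

    def __post_init__(self) -> None:
        if (self.mirna_id is not None) != (self.category == MIRNA):
            raise ValueError("mirna_id must be set iff category is miRNA")


def _best(hits: Sequence[Hit]) -> Hit:
    # hits are pre-sorted (mismatches, id, strand, offset)
    return hits[0]


def assign_read(
    insert: str,
    multiplicity: int,
    indexes: Mapping[str, MatchIndex],
) -> ReadAssignment:
    """Assign one collapsed insert to its category.

    ``indexes`` maps reference-set names to MatchIndexes; missing sets
    (e.g. no contaminant references configured) are treated as empty.
    """
    genome_hits = (
        match_read(insert, indexes["genome"]) if "genome" in indexes else []
    )
    if genome_hits:
        for set_name, category in ANNOTATION_PRIORITY:
            idx = indexes.get(set_name)
            if idx is None:
                continue
            hits = match_read(insert, idx)
            if hits:
                best = _best(hits)
                return ReadAssignment(
                    insert,
                    multiplicity,
                    category,
                    best_hit=best,
                    mirna_id=best.reference_id if category == MIRNA else None,
                )
        return ReadAssignment(
            insert, multiplicity, GENOME_OTHER, best_hit=_best(genome_hits)
        )
    bact_hits = (
        match_read(insert, indexes["contaminant_bacterial"])
        if "contaminant_bacterial" in indexes
        else []
    )
    viral_hits = (
        match_read(insert, indexes["contaminant_viral"])
        if "contaminant_viral" in indexes
        else []
    )
    if bact_hits or viral_hits:
        # fewer mismatches win; bacterial wins ties
        if not viral_hits or (
            bact_hits and _best(bact_hits).mismatches <= _best(viral_hits).mismatches
        ):
            if bact_hits:
                return ReadAssignment(
                    insert, multiplicity, CONTAMINANT_BACTERIAL, best_hit=_best(bact_hits)
                )
        return ReadAssignment(
            insert, multiplicity, CONTAMINANT_VIRAL, best_hit=_best(viral_hits)
        )
    return ReadAssignment(insert, multiplicity, UNMAPPED)


def collapse_inserts(inserts: Iterable[str]) -> Counter:
    """Collapse identical inserts, keeping their multiplicity."""
    return Counter(inserts)


def assign_all(
    insert_counts: Mapping[str, int], indexes: Mapping[str, MatchIndex]
) -> list[ReadAssignment]:
    """Assign every collapsed insert; deterministic (sorted) order."""
    return [
        assign_read(insert, mult, indexes)
        for insert, mult in sorted(insert_counts.items())
    ]


@dataclass
class MiRNAProfile:
    """Read counts per miRNA for one sample."""

    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_mirna_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def n_detected(self) -> int:
        return len(self.counts)


def profile_mirnas(assignments: Iterable[ReadAssignment]) -> MiRNAProfile:
    """Aggregate miRNA-assigned reads (weighted by multiplicity)."""
    counts: Counter = Counter()
    for a in assignments:
        if a.category == MIRNA:
            counts[a.mirna_id] += a.multiplicity
    return MiRNAProfile(dict(counts))
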