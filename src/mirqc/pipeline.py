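"""End-to-end per-sample processing: trim, map, profile, featurise."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from . import quality_features as qf
from . import read_mapping as rm
from . import trimming as tr
from .fastq_io import ReadRecord, ReferenceSet, read_fastq
from .read_mapping import MatchIndex, MiRNAProfile, ReadAssignment

logger = logging.getLogger(__name__)


@dataclass
class SampleResult:
    """Everything computed for one sample."""

    sample_id: str
    trim_counts: tr.TrimCounts
    assignments: list[ReadAssignment]
    profile: MiRNAProfile
    length_histogram: qf.LengthHistogram
    n_unique_inserts: int
    vector: qf.QualityAttributeVector
    detected_preset: tr.AdapterPreset | None = None
    detection_rate: float | None = None


def build_indexes(
    reference_sets: Mapping[str, ReferenceSet], seed_length: int = rm.DEFAULT_SEED_LENGTH
) -> dict[str, MatchIndex]:
    """Build match indexes for every supplied reference set."""
    return {
        name: rm.build_index(refset, seed_length)
        for name, refset in reference_sets.items()
    }


def process_reads(
    reads: Sequence[ReadRecord],
    indexes: Mapping[str, MatchIndex],
    preset: tr.AdapterPreset,
    sample_id: str,
) -> SampleResult:
    """Run the full QC feature pipeline on in-memory reads."""
    if not reads:
        raise ValueError(f"sample {sample_id!r} contains no reads")
    trim_counts = tr.TrimCounts()
    valid_inserts: list[str] = []
    for read in reads:
        result = tr.trim_read(read, preset)
        trim_counts.add(result.category)
        if result.category in (tr.CATEGORY_SHORT_READ, tr.CATEGORY_VALID):
            valid_inserts.append(result.insert_sequence)

    insert_counts = rm.collapse_inserts(valid_inserts)
    assignments = rm.assign_all(insert_counts, indexes)
    profile = rm.profile_mirnas(assignments)

    hist_counts: dict[int, int] = {}
    for a in assignments:
        if a.category == rm.MIRNA:
            length = len(a.insert_sequence)
            hist_counts[length] = hist_counts.get(length, 0) + a.multiplicity
    length_histogram = qf.LengthHistogram(hist_counts)

    vector = qf.assemble(
        sample_id,
        qf.compute_yield(trim_counts, assignments, profile),
        qf.compute_library_quality(trim_counts, assignments),
        qf.compute_complexity(trim_counts, len(insert_counts), profile),
        qf.contamination(assignments, trim_counts.total_valid),
        qf.length_stats(length_histogram),
        qf.rna_composition(assignments, trim_counts.total_valid),
        qf.sequencing_quality(reads),
    )
    return SampleResult(
        sample_id,
        trim_counts,
        assignments,
        profile,
        length_histogram,
        len(insert_counts),
        vector,
    )


def process_fastq(
    path: str | Path,
    indexes: Mapping[str, MatchIndex],
    preset: tr.AdapterPreset | None = None,
    sample_id: str | None = None,
    catalogue: Sequence[tr.AdapterPreset] = tr.DEFAULT_CATALOGUE,
) -> SampleResult:
    """Process one FASTQ file; auto-detects the protocol when no preset
    is given."""
    path = Path(path)
    if sample_id is None:
        sample_id = path.name.removesuffix(".gz").rsplit(".", 1)[0]
    reads = list(read_fastq(path))
    detected = None
    rate = None
    if preset is None:
        detected, rate = tr.detect_protocol(reads, catalogue)
        preset = detected
        logger.info(
            "sample %s: detected protocol %s (adapter rate %.1f%%)",
            sample_id,
            preset.protocol_name,
            (rate or 0) * 100,
        )
    result = process_reads(reads, indexes, preset, sample_id)
    result.detected_preset = detected
    result.detection_rate = rate
    return result
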