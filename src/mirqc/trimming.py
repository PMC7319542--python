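"""3' adapter detection, trimming, and trimmed-length classification.

Small-RNA reads are sequenced through the insert into the 3' adapter, so
the adapter position determines the insert length.  After trimming, the
insert length carries most of the library-quality signal:

* 0-2 nt     adapter-dimer (5'+3' adapter ligation with no insert; a
             symptom of adapter:input concentration problems)
* 3-14 nt    ultra-short fragment (no known small RNA in this range;
             degradation products)
* 15-17 nt   short read (kept, but flagged: likely degradation)
* >= 18 nt   regular valid read

Reads in which no adapter can be located are classified ``no_adapter`` and
excluded from the valid-read denominator: their true insert length is
unknown.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .fastq_io import ReadRecord

logger = logging.getLogger(__name__)

CATEGORY_NO_ADAPTER = "no_adapter"
CATEGORY_ADAPTER_DIMER = "adapter_dimer"
CATEGORY_ULTRA_SHORT = "ultra_short"
CATEGORY_SHORT_READ = "short_read"
CATEGORY_VALID = "valid"

TRIM_CATEGORIES = (
    CATEGORY_NO_ADAPTER,
    CATEGORY_ADAPTER_DIMER,
    CATEGORY_ULTRA_SHORT,
    CATEGORY_SHORT_READ,
    CATEGORY_VALID,
)

ADAPTER_SEED_LENGTH = 12
#: minimum 3'-anchored adapter prefix considered evidence of an adapter
MIN_ANCHORED_PREFIX = 6


@dataclass(frozen=True)
class AdapterPreset:
    """Protocol-specific 3' adapter layout.

    ``random_bases_5p``/``random_bases_3p`` are randomised bases flanking
    the insert (NextFlex-style); ``umi_length`` is a UMI located after the
    3' adapter (Qiagen-style), discarded together with the adapter.
    """

    protocol_name: str
    adapter_sequence: str
    random_bases_5p: int = 0
    random_bases_3p: int = 0
    umi_length: int = 0

    def __post_init__(self) -> None:
        if self.protocol_name != "adapter_trimmed" and not self.adapter_sequence:
            raise ValueError(
                f"preset {self.protocol_name!r} requires an adapter sequence"
            )


#: Default adapter catalogue.  Sequences are configurable constants, not
#: normative: protocols are library-prep conventions, and custom kits may
#: use any adapter.
DEFAULT_CATALOGUE: tuple[AdapterPreset, ...] = (
    AdapterPreset("Illumina", "TGGAATTCTCGGGTGCCAAGG"),
    AdapterPreset("Illumina_2", "ATCTCGTATGCCGTCTTCTGCTTG"),
    AdapterPreset("NEBnext", "AGATCGGAAGAGCACACGTCT"),
    AdapterPreset("NextFlex", "TGGAATTCTCGGGTGCCAAGG", 4, 4, 0),
    AdapterPreset("Qiagen_UMI", "AACTGTAGGCACCATCAAT", 0, 0, 12),
    AdapterPreset("adapter_trimmed", ""),
)


@dataclass
class TrimResult:
    insert_sequence: str
    adapter_found: bool
    category: str
    insert_length: int = field(init=False)

    def __post_init__(self) -> None:
        self.insert_length = len(self.insert_sequence)


def classify_trimmed_length(insert_length: int, adapter_found: bool) -> str:
    """Map a trimmed insert length to its library-quality category."""
    if insert_length < 0:
        raise ValueError(f"negative insert length {insert_length}")
    if not adapter_found:
        return CATEGORY_NO_ADAPTER
    if insert_length <= 2:
        return CATEGORY_ADAPTER_DIMER
    if insert_length <= 14:
        return CATEGORY_ULTRA_SHORT
    if insert_length <= 17:
        return CATEGORY_SHORT_READ
    return CATEGORY_VALID


def find_with_mismatches(sequence: str, pattern: str, max_mismatches: int) -> int:
    """Leftmost start of ``pattern`` in ``sequence`` with <= max_mismatches
    substitutions, or -1.

    Vectorised window comparison; 'N' never matches any base.
    """
    n, m = len(sequence), len(pattern)
    if m == 0 or m > n:
        return -1
    if max_mismatches >= 1:
        # a 0-mismatch hit can only shadow an earlier <=1-mismatch hit,
        # so a full scan is required for leftmost semantics
        seq = np.frombuffer(sequence.encode(), dtype=np.uint8)
        pat = np.frombuffer(pattern.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(seq, m)
        mismatches = (windows != pat).sum(axis=1)
        hits = np.flatnonzero(mismatches <= max_mismatches)
        return int(hits[0]) if hits.size else -1
    return sequence.find(pattern)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def locate_adapter(sequence: str, adapter: str) -> int:
    """Locate the 3' adapter start in a read; -1 when absent.

    Strategy: leftmost occurrence of the adapter's first 12 nt (or the
    full adapter if shorter) allowing <=1 mismatch; failing that, adapter
    prefixes of length >= 6 anchored at the read's 3' end (<=1 mismatch
    for prefixes >= 10 nt, exact below), longest first.
    """
    probe = adapter[:ADAPTER_SEED_LENGTH]
    pos = find_with_mismatches(sequence, probe, 1)
    if pos >= 0:
        return pos
    longest = min(len(adapter), len(sequence), ADAPTER_SEED_LENGTH - 1)
    for plen in range(longest, MIN_ANCHORED_PREFIX - 1, -1):
        tail = sequence[-plen:]
        budget = 1 if plen >= 10 else 0
        if _hamming(tail, adapter[:plen]) <= budget:
            return len(sequence) - plen
    return -1


def trim_read(read: ReadRecord, preset: AdapterPreset) -> TrimResult:
    """Trim the 3' adapter from one read and classify the insert."""
    sequence = read.sequence
    if preset.protocol_name == "adapter_trimmed" or not preset.adapter_sequence:
        # adapter removed upstream: the read IS the insert
        insert = sequence
        return TrimResult(insert, True, classify_trimmed_length(len(insert), True))
    pos = locate_adapter(sequence, preset.adapter_sequence)
    if pos < 0:
        return TrimResult(sequence, False, CATEGORY_NO_ADAPTER)
    insert = sequence[:pos]
    if preset.random_bases_5p:
        insert = insert[preset.random_bases_5p :]
    if preset.random_bases_3p:
        insert = insert[: max(0, len(insert) - preset.random_bases_3p)]
    return TrimResult(insert, True, classify_trimmed_length(len(insert), True))


@dataclass
class TrimCounts:
    """Per-category read counts for one sample."""

    counts: Counter = field(default_factory=Counter)

    @property
    def total_input(self) -> int:
        return sum(self.counts.values())

    @property
    def total_valid(self) -> int:
        return self.counts[CATEGORY_SHORT_READ] + self.counts[CATEGORY_VALID]

    def __getitem__(self, category: str) -> int:
        return self.counts[category]

    def add(self, category: str) -> None:
        if category not in TRIM_CATEGORIES:
            raise KeyError(category)
        self.counts[category] += 1


def detect_protocol(
    sample_reads: Sequence[ReadRecord],
    catalogue: Iterable[AdapterPreset] = DEFAULT_CATALOGUE,
    n_scan: int = 10_000,
    floor: float = 0.20,
) -> tuple[AdapterPreset, float]:
    """Pick the adapter preset whose adapter occurs in the most reads.

    For each preset the fraction of the first ``n_scan`` reads containing
    the adapter's first 12 nt (<=1 mismatch, any position) is computed;
    the highest-fraction preset wins (catalogue order breaks ties).  If no
    preset reaches ``floor`` the adapter_trimmed fallback is returned with
    a warning.
    """
    catalogue = list(catalogue)
    if not sample_reads:
        raise ValueError("protocol detection needs at least one read")
    if not catalogue:
        raise ValueError("empty adapter catalogue")
    reads = sample_reads[:n_scan]
    best_preset: AdapterPreset | None = None
    best_rate = -1.0
    for preset in catalogue:
        if not preset.adapter_sequence:
            continue
        probe = preset.adapter_sequence[:ADAPTER_SEED_LENGTH]
        n_hit = sum(
            1 for r in reads if find_with_mismatches(r.sequence, probe, 1) >= 0
        )
        rate = n_hit / len(reads)
        if rate > best_rate:
            best_preset, best_rate = preset, rate
    if best_preset is None or best_rate < floor:
        logger.warning(
            "no catalogue adapter found in >= %.0f%% of reads (best %.1f%%); "
            "falling back to adapter_trimmed",
            floor * 100,
            max(best_rate, 0.0) * 100,
        )
        fallback = next(
            (p for p in catalogue if p.protocol_name == "adapter_trimmed"),
            AdapterPreset("adapter_trimmed", ""),
        )
        return fallback, max(best_rate, 0.0)
    return best_preset, best_rate


def get_preset(protocol_name: str, catalogue: Iterable[AdapterPreset] = DEFAULT_CATALOGUE) -> AdapterPreset:
    for preset in catalogue:
        if preset.protocol_name == protocol_name:
            return preset
    raise KeyError(f"unknown protocol {protocol_name!r}")
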