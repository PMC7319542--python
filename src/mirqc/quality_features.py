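"""The 34 miRNA-seq quality attributes, organised into seven report sections.

Attribute registry
------------------
The attribute set is declarative: :data:`ATTRIBUTE_REGISTRY` enumerates
every attribute with its report section and ranking orientation.
Orientation drives the quartile colour code: ``higher_better`` attributes
are good at high percentiles, ``lower_better`` at low ones, ``neutral``
attributes are displayed but never coloured.  Skewness is displayed raw
but ranked on its absolute value (a length distribution skewed either way
signals degradation).

Denominators
------------
Library-preparation artefacts (adapter-dimers, ultra-short fragments) are
fractions of total input reads; biological composition (rRNA, tRNA, mRNA,
contamination, miRNA yield) is a fraction of valid reads (adapter found,
insert >= 15 nt).  Undefined values (e.g. %miRNA of a sample with zero
valid reads) are explicit missing values, never zeros, and are excluded
from percentile ranking.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from . import read_mapping as rm
from . import trimming as tr
from .fastq_io import ReadRecord
from .read_mapping import MiRNAProfile, ReadAssignment

logger = logging.getLogger(__name__)

HIGHER_BETTER = "higher_better"
LOWER_BETTER = "lower_better"
NEUTRAL = "neutral"

SECTIONS = (
    "yield",
    "library_quality",
    "complexity",
    "contamination",
    "length_distribution",
    "rna_composition",
    "sequencing_quality",
)


class AttributeSpec(NamedTuple):
    name: str
    section: str
    orientation: str
    rank_abs: bool = False


ATTRIBUTE_REGISTRY: tuple[AttributeSpec, ...] = (
    # sequencing yield
    AttributeSpec("total_input_reads", "yield", NEUTRAL),
    AttributeSpec("pct_valid_reads", "yield", HIGHER_BETTER),
    AttributeSpec("total_valid_reads", "yield", NEUTRAL),
    AttributeSpec("n_detected_mirnas", "yield", HIGHER_BETTER),
    AttributeSpec("pct_mirna_reads", "yield", HIGHER_BETTER),
    # library quality
    AttributeSpec("pct_min_length_filtered", "library_quality", LOWER_BETTER),
    AttributeSpec("pct_adapter_dimer", "library_quality", LOWER_BETTER),
    AttributeSpec("pct_ultra_short", "library_quality", LOWER_BETTER),
    AttributeSpec("pct_short_reads", "library_quality", LOWER_BETTER),
    AttributeSpec("pct_rrna", "library_quality", LOWER_BETTER),
    # library complexity
    AttributeSpec("complexity_ratio", "complexity", LOWER_BETTER),
    AttributeSpec("n_unique_inserts", "complexity", NEUTRAL),
    AttributeSpec("pct_top1_mirna", "complexity", LOWER_BETTER),
    AttributeSpec("pct_top5_mirna", "complexity", LOWER_BETTER),
    AttributeSpec("pct_top20_mirna", "complexity", LOWER_BETTER),
    AttributeSpec("n_mirnas_50pct", "complexity", HIGHER_BETTER),
    AttributeSpec("n_mirnas_75pct", "complexity", HIGHER_BETTER),
    AttributeSpec("n_mirnas_95pct", "complexity", HIGHER_BETTER),
    # putative contamination
    AttributeSpec("pct_genome_unmapped", "contamination", LOWER_BETTER),
    AttributeSpec("pct_bacterial", "contamination", LOWER_BETTER),
    AttributeSpec("pct_viral", "contamination", LOWER_BETTER),
    # read length distribution (miRNA-assigned reads)
    AttributeSpec("mean_length", "length_distribution", NEUTRAL),
    AttributeSpec("mode_length", "length_distribution", NEUTRAL),
    AttributeSpec("pct_length_peak", "length_distribution", HIGHER_BETTER),
    AttributeSpec("sd_length", "length_distribution", LOWER_BETTER),
    AttributeSpec("skewness_length", "length_distribution", LOWER_BETTER, rank_abs=True),
    # RNA composition
    AttributeSpec("pct_trna", "rna_composition", LOWER_BETTER),
    AttributeSpec("pct_other_ncrna", "rna_composition", LOWER_BETTER),
    AttributeSpec("pct_mrna", "rna_composition", LOWER_BETTER),
    AttributeSpec("pct_genome_other", "rna_composition", LOWER_BETTER),
    # sequencing quality
    AttributeSpec("mean_q_mean", "sequencing_quality", HIGHER_BETTER),
    AttributeSpec("mean_q_median", "sequencing_quality", HIGHER_BETTER),
    AttributeSpec("mean_q_q25", "sequencing_quality", HIGHER_BETTER),
    AttributeSpec("mean_q_q10", "sequencing_quality", HIGHER_BETTER),
)

ATTRIBUTE_NAMES = tuple(a.name for a in ATTRIBUTE_REGISTRY)
ATTRIBUTE_BY_NAME = {a.name: a for a in ATTRIBUTE_REGISTRY}
N_ATTRIBUTES = len(ATTRIBUTE_REGISTRY)
assert N_ATTRIBUTES == 34


@dataclass
class QualityAttributeVector:
    """The 34 attribute values for one sample (missing -> None)."""

    sample_id: str
    values: dict[str, float | None]

    def __post_init__(self) -> None:
        missing = [n for n in ATTRIBUTE_NAMES if n not in self.values]
        extra = [n for n in self.values if n not in ATTRIBUTE_BY_NAME]
        if missing or extra:
            raise ValueError(
                f"attribute registry mismatch: missing={missing} extra={extra}"
            )
        # keep registry order for stable serialisation
        self.values = {n: self.values[n] for n in ATTRIBUTE_NAMES}

    def section_of(self, name: str) -> str:
        return ATTRIBUTE_BY_NAME[name].section

    def orientation_of(self, name: str) -> str:
        return ATTRIBUTE_BY_NAME[name].orientation

    def to_dict(self) -> dict:
        return {"sample_id": self.sample_id, "values": dict(self.values)}

    @classmethod
    def from_dict(cls, data: Mapping) -> "QualityAttributeVector":
        return cls(data["sample_id"], dict(data["values"]))


@dataclass
class LengthHistogram:
    """Insert-length histogram of miRNA-assigned reads."""

    counts: dict[int, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _pct(numerator: float, denominator: float) -> float:
    return 100.0 * numerator / denominator


def _category_reads(assignments: Iterable[ReadAssignment], category: str) -> int:
    return sum(a.multiplicity for a in assignments if a.category == category)


def compute_yield(
    trim_counts: tr.TrimCounts,
    assignments: Sequence[ReadAssignment],
    profile: MiRNAProfile,
) -> dict[str, float | None]:
    """Sequencing-yield attributes: read totals and miRNA recovery."""
    total = trim_counts.total_input
    valid = trim_counts.total_valid
    out: dict[str, float | None] = {
        "total_input_reads": float(total),
        "pct_valid_reads": _pct(valid, total) if total else None,
        "total_valid_reads": float(valid),
    }
    if valid == 0:
        logger.warning("zero valid reads: miRNA yield attributes undefined")
        out["n_detected_mirnas"] = None
        out["pct_mirna_reads"] = None
    else:
        out["n_detected_mirnas"] = float(profile.n_detected)
        out["pct_mirna_reads"] = _pct(profile.total_mirna_reads, valid)
    return out


def compute_library_quality(
    trim_counts: tr.TrimCounts, assignments: Sequence[ReadAssignment]
) -> dict[str, float | None]:
    """Library-quality attributes: trimming artefacts and rRNA load."""
    total = trim_counts.total_input
    if total == 0:
        raise ValueError("cannot compute library quality on an empty sample")
    dimer = trim_counts[tr.CATEGORY_ADAPTER_DIMER]
    ultra = trim_counts[tr.CATEGORY_ULTRA_SHORT]
    short = trim_counts[tr.CATEGORY_SHORT_READ]
    valid = trim_counts.total_valid
    return {
        "pct_min_length_filtered": _pct(dimer + ultra, total),
        "pct_adapter_dimer": _pct(dimer, total),
        "pct_ultra_short": _pct(ultra, total),
        "pct_short_reads": _pct(short, total),
        "pct_rrna": _pct(_category_reads(assignments, rm.RRNA), valid)
        if valid
        else None,
    }


def complexity_ratio(total_valid_reads: int, unique_valid_inserts: int) -> float:
    """Sequencing-library complexity: total reads / unique inserts (>= 1)."""
    if unique_valid_inserts < 1:
        raise ValueError("complexity ratio undefined with zero unique inserts")
    return total_valid_reads / unique_valid_inserts


def _sorted_counts(profile: MiRNAProfile) -> list[int]:
    # descending by count, ascending miRNA id on ties
    return [c for _, c in sorted(profile.counts.items(), key=lambda kv: (-kv[1], kv[0]))]


def top_fraction(profile: MiRNAProfile, k: int) -> float | None:
    """Percent of miRNA expression carried by the top-k miRNAs."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not profile.counts:
        return None
    counts = _sorted_counts(profile)
    return _pct(sum(counts[:k]), profile.total_mirna_reads)


def mirnas_to_reach(profile: MiRNAProfile, threshold_pct: float) -> float | None:
    """Smallest number of top miRNAs whose cumulative share >= threshold."""
    if not profile.counts:
        return None
    counts = _sorted_counts(profile)
    target = threshold_pct / 100.0 * profile.total_mirna_reads
    cumulative = 0
    for m, c in enumerate(counts, start=1):
        cumulative += c
        if cumulative >= target - 1e-9:
            return float(m)
    return float(len(counts))


def compute_complexity(
    trim_counts: tr.TrimCounts,
    unique_valid_inserts: int,
    profile: MiRNAProfile,
) -> dict[str, float | None]:
    valid = trim_counts.total_valid
    out: dict[str, float | None] = {
        "complexity_ratio": complexity_ratio(valid, unique_valid_inserts)
        if unique_valid_inserts
        else None,
        "n_unique_inserts": float(unique_valid_inserts),
        "pct_top1_mirna": top_fraction(profile, 1) if profile.counts else None,
        "pct_top5_mirna": top_fraction(profile, 5) if profile.counts else None,
        "pct_top20_mirna": top_fraction(profile, 20) if profile.counts else None,
        "n_mirnas_50pct": mirnas_to_reach(profile, 50),
        "n_mirnas_75pct": mirnas_to_reach(profile, 75),
        "n_mirnas_95pct": mirnas_to_reach(profile, 95),
    }
    return out


def length_stats(hist: LengthHistogram) -> dict[str, float | None]:
    """Distributional summary of miRNA-read insert lengths.

    Population moments (no Bessel correction); sd and skewness are
    missing for degenerate distributions (N < 3 or zero variance).
    """
    if hist.total == 0:
        return {
            "mean_length": None,
            "mode_length": None,
            "pct_length_peak": None,
            "sd_length": None,
            "skewness_length": None,
        }
    lengths = np.array(sorted(hist.counts), dtype=float)
    weights = np.array([hist.counts[int(l)] for l in lengths], dtype=float)
    n = weights.sum()
    mean = float((lengths * weights).sum() / n)
    mode = float(lengths[int(np.argmax(weights))])  # smallest length on ties
    peak = sum(hist.counts.get(l, 0) for l in (21, 22, 23))
    deviations = lengths - mean
    m2 = float((weights * deviations**2).sum() / n)
    m3 = float((weights * deviations**3).sum() / n)
    if n < 3 or m2 == 0.0:
        sd: float | None = math.sqrt(m2) if n >= 1 else None
        skew: float | None = None
        if n < 3:
            sd = None
    else:
        sd = math.sqrt(m2)
        skew = m3 / m2**1.5
    return {
        "mean_length": mean,
        "mode_length": mode,
        "pct_length_peak": _pct(peak, n),
        "sd_length": sd,
        "skewness_length": skew,
    }


def rna_composition(
    assignments: Sequence[ReadAssignment], total_valid: int
) -> dict[str, float | None]:
    """Relative abundance of non-miRNA RNA classes (degradation signal)."""
    if total_valid < 1:
        return {k: None for k in ("pct_trna", "pct_other_ncrna", "pct_mrna", "pct_genome_other")}
    return {
        "pct_trna": _pct(_category_reads(assignments, rm.TRNA), total_valid),
        "pct_other_ncrna": _pct(
            _category_reads(assignments, rm.OTHER_NCRNA), total_valid
        ),
        "pct_mrna": _pct(_category_reads(assignments, rm.MRNA), total_valid),
        "pct_genome_other": _pct(
            _category_reads(assignments, rm.GENOME_OTHER), total_valid
        ),
    }


def contamination(
    assignments: Sequence[ReadAssignment], total_valid: int
) -> dict[str, float | None]:
    """Genome-unmapped fraction and its bacterial/viral components."""
    if total_valid < 1:
        return {k: None for k in ("pct_genome_unmapped", "pct_bacterial", "pct_viral")}
    bact = _category_reads(assignments, rm.CONTAMINANT_BACTERIAL)
    viral = _category_reads(assignments, rm.CONTAMINANT_VIRAL)
    unmapped = _category_reads(assignments, rm.UNMAPPED)
    return {
        "pct_genome_unmapped": _pct(unmapped + bact + viral, total_valid),
        "pct_bacterial": _pct(bact, total_valid),
        "pct_viral": _pct(viral, total_valid),
    }


def sequencing_quality(
    records: Iterable[ReadRecord], min_coverage: int = 100
) -> dict[str, float | None]:
    """Per-position Phred summaries averaged over read positions.

    For each read position the mean, median, 25th and 10th percentile of
    the Phred scores over all (untrimmed) reads is computed; the four
    attributes are the averages of these summaries over positions.
    Positions covered by fewer than ``min(min_coverage, n_reads)`` reads
    are dropped from the averaging so that 3'-end positions reached by a
    handful of long reads do not dominate.
    """
    per_position: list[list[int]] = []
    n_reads = 0
    for rec in records:
        n_reads += 1
        for pos, q in enumerate(rec.qualities):
            if pos >= len(per_position):
                per_position.append([])
            per_position[pos].append(q)
    if n_reads == 0:
        raise ValueError("sequencing quality needs at least one read")
    floor = min(min_coverage, n_reads)
    means, medians, q25s, q10s = [], [], [], []
    for scores in per_position:
        if len(scores) < floor:
            continue
        arr = np.asarray(scores, dtype=float)
        means.append(float(arr.mean()))
        q10, q25, q50 = np.percentile(arr, [10, 25, 50])
        medians.append(float(q50))
        q25s.append(float(q25))
        q10s.append(float(q10))
    return {
        "mean_q_mean": float(np.mean(means)),
        "mean_q_median": float(np.mean(medians)),
        "mean_q_q25": float(np.mean(q25s)),
        "mean_q_q10": float(np.mean(q10s)),
    }


def assemble(sample_id: str, *partials: Mapping[str, float | None]) -> QualityAttributeVector:
    """Merge the section computations into the 34-attribute vector.

    Raises if any registry attribute is absent or an unknown name sneaks
    in — the registry is the single source of truth for the report shape.
    """
    values: dict[str, float | None] = {}
    for part in partials:
        for name, value in part.items():
            if name not in ATTRIBUTE_BY_NAME:
                raise ValueError(f"unknown attribute {name!r}")
            values[name] = value
    missing = [n for n in ATTRIBUTE_NAMES if n not in values]
    if missing:
        raise ValueError(f"missing attributes: {missing}")
    return QualityAttributeVector(sample_id, values)
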