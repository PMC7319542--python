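"""Seeded synthetic references, miRNA-seq samples and whole corpora.

The generator inverts the QC artefact taxonomy into a read simulator:
a sample is a mixture of miRNA inserts, degradation fragments from
longer RNAs (rRNA/tRNA/other ncRNA/mRNA), intergenic genome fragments,
bacterial/viral contaminant fragments, adapter-dimers, ultra-short
fragments and unmappable random sequence, each carrying a 3' adapter
suffix and synthetic position-dependent Phred qualities.  Every read's
true category, source and insert length are recorded in a truth table.

Reference construction guarantees unambiguous truth: all annotation
sequences (mature miRNAs inside their hairpins, rRNA, tRNA, other
ncRNA, mRNA) are embedded verbatim in the synthetic genome; intergenic
fragments come from a dedicated annotation-free region; contaminant
genomes are rejection-sampled so that no 15-mer (either strand) is
shared with the genome.

Everything is driven by :func:`numpy.random.default_rng`, so a fixed
seed reproduces byte-identical FASTA/FASTQ output across runs and
platforms.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .fastq_io import ReadRecord, ReferenceSet, write_fasta, write_fastq
from .trimming import AdapterPreset, get_preset

logger = logging.getLogger(__name__)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: recipe categories, in draw order
RECIPE_CATEGORIES = (
    "mirna",
    "rrna",
    "trna",
    "other_ncrna",
    "mrna",
    "genome_other",
    "bacterial",
    "viral",
    "adapter_dimer",
    "ultra_short",
    "unmapped_random",
)

#: mature miRNA length distribution: canonical lengths peak at 22 nt
MATURE_LENGTHS = (20, 21, 22, 23, 24)
MATURE_LENGTH_WEIGHTS = (0.05, 0.20, 0.50, 0.20, 0.05)

DISJOINT_K = 15  # contaminant/genome k-mer disjointness scale


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SyntheticReferences:
    """All reference sets plus the sampling helpers the simulator needs."""

    sets: dict[str, dict[str, str]]
    genome_other_region: str  # annotation-free genome stretch
    _mapped_kmers: set[str] | None = field(default=None, repr=False)

    def as_reference_sets(self) -> dict[str, ReferenceSet]:
        return {name: ReferenceSet(name, entries) for name, entries in self.sets.items()}

    def write_dir(self, directory: str | Path) -> dict[str, Path]:
        """Write one FASTA per reference set; returns name -> path."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, entries in self.sets.items():
            path = directory / f"{name}.fasta"
            write_fasta(entries, path)
            paths[name] = path
        return paths

    def mapped_kmers(self) -> set[str]:
        """All 15-mers of genome and contaminants (both strands)."""
        if self._mapped_kmers is None:
            kmers: set[str] = set()
            for name in ("genome", "contaminant_bacterial", "contaminant_viral"):
                for seq in self.sets.get(name, {}).values():
                    kmers |= _kmers(seq, DISJOINT_K)
                    kmers |= _kmers(_revcomp(seq), DISJOINT_K)
            self._mapped_kmers = kmers
        return self._mapped_kmers


def generate_references(
    seed: int,
    n_mirna: int = 60,
    n_rrna: int = 2,
    rrna_length: int = 600,
    n_trna: int = 8,
    trna_length: int = 72,
    n_other_ncrna: int = 6,
    other_ncrna_length: int = 200,
    n_mrna: int = 6,
    mrna_length: int = 400,
    n_bacterial: int = 2,
    bacterial_length: int = 1500,
    n_viral: int = 1,
    viral_length: int = 1200,
    hairpin_flank: int = 20,
    spacer_length: int = 60,
    genome_other_length: int = 4000,
    max_rejections: int = 200,
) -> SyntheticReferences:
    """Build a self-consistent synthetic reference collection.

    The genome is assembled from hairpins (each containing one mature
    miRNA verbatim), the longer-RNA annotation sequences, random spacers
    and a terminal annotation-free region used to sample intergenic
    (``genomeOther``) fragments.  Contaminant genomes share no 15-mer
    with the genome on either strand.
    """
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    sets: dict[str, dict[str, str]] = {
        "mirna_mature": {},
        "mirna_hairpin": {},
        "rrna": {},
        "trna": {},
        "other_ncrna": {},
        "mrna": {},
    }

    def spacer() -> None:
        parts.append(_random_seq(rng, spacer_length))

    length_p = np.array(MATURE_LENGTH_WEIGHTS)
    for i in range(n_mirna):
        mature_len = int(rng.choice(MATURE_LENGTHS, p=length_p))
        mature = _random_seq(rng, mature_len)
        hairpin = _random_seq(rng, hairpin_flank) + mature + _random_seq(rng, hairpin_flank)
        sets["mirna_mature"][f"syn-mir-{i + 1:03d}"] = mature
        sets["mirna_hairpin"][f"syn-mir-{i + 1:03d}-hp"] = hairpin
        parts.append(hairpin)
        spacer()
    for name, n, length in (
        ("rrna", n_rrna, rrna_length),
        ("trna", n_trna, trna_length),
        ("other_ncrna", n_other_ncrna, other_ncrna_length),
        ("mrna", n_mrna, mrna_length),
    ):
        for i in range(n):
            seq = _random_seq(rng, length)
            sets[name][f"syn-{name}-{i + 1}"] = seq
            parts.append(seq)
            spacer()
    genome_other_region = _random_seq(rng, genome_other_length)
    parts.append(genome_other_region)
    genome = "".join(parts)
    sets["genome"] = {"chr1": genome}

    genome_kmers = _kmers(genome, DISJOINT_K) | _kmers(_revcomp(genome), DISJOINT_K)
    for name, n, length in (
        ("contaminant_bacterial", n_bacterial, bacterial_length),
        ("contaminant_viral", n_viral, viral_length),
    ):
        entries = {}
        prefix = "syn-bact" if name == "contaminant_bacterial" else "syn-virus"
        for i in range(n):
            for attempt in range(max_rejections):
                seq = _random_seq(rng, length)
                shared = (_kmers(seq, DISJOINT_K) | _kmers(_revcomp(seq), DISJOINT_K)) & genome_kmers
                if not shared:
                    break
            else:
                raise RuntimeError(
                    "could not sample a contaminant sequence 15-mer-disjoint "
                    "from the genome; reduce sequence sizes"
                )
            entries[f"{prefix}-{i + 1}"] = seq
        sets[name] = entries
    return SyntheticReferences(sets, genome_other_region)


DEFAULT_PROPORTIONS: dict[str, float] = {
    "mirna": 0.55,
    "rrna": 0.08,
    "trna": 0.03,
    "other_ncrna": 0.03,
    "mrna": 0.04,
    "genome_other": 0.08,
    "bacterial": 0.02,
    "viral": 0.01,
    "adapter_dimer": 0.05,
    "ultra_short": 0.06,
    "unmapped_random": 0.05,
}


@dataclass
class SampleRecipe:
    """Everything needed to simulate one sample deterministically."""

    depth: int = 10_000
    proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    mirna_profile_shape: float = 1.0  # Zipf exponent over ranked miRNAs
    fragment_length_range: tuple[int, int] = (16, 28)  # degradation fragments
    mutation_rate: float = 0.02  # per-read probability of 1 substitution
    quality_mean_start: float = 36.0
    quality_slope: float = -0.08  # mean Phred change per position
    quality_sd: float = 3.0
    read_length: int = 50
    protocol: str = "Illumina"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        unknown = set(self.proportions) - set(RECIPE_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown recipe categories: {sorted(unknown)}")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, expected 1")

    def proportion_vector(self) -> np.ndarray:
        return np.array([self.proportions.get(c, 0.0) for c in RECIPE_CATEGORIES])


@dataclass
class TruthTable:
    """Ground truth for one simulated sample."""

    recipe: SampleRecipe
    per_read: dict[str, tuple[str, str, int]]  # id -> (category, source, len)
    realized_counts: dict[str, int]

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "wt") as handle:
            handle.write("read_id\ttrue_category\ttrue_source\ttrue_insert_length\n")
            for rid, (cat, src, length) in self.per_read.items():
                handle.write(f"{rid}\t{cat}\t{src}\t{length}\n")


def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    w = ranks**-exponent
    return w / w.sum()


def _mutate(insert: str, rng: np.random.Generator) -> str:
    if not insert:
        return insert
    pos = int(rng.integers(len(insert)))
    old = insert[pos]
    choices = [b for b in "ACGT" if b != old]
    new = choices[int(rng.integers(3))]
    return insert[:pos] + new + insert[pos + 1 :]


def simulate_sample(
    recipe: SampleRecipe,
    references: SyntheticReferences,
    sample_id: str = "sim_sample",
) -> tuple[list[ReadRecord], TruthTable]:
    """Simulate one FASTQ sample plus its ground-truth table."""
    rng = np.random.default_rng(recipe.seed)
    preset: AdapterPreset = get_preset(recipe.protocol)
    adapter = preset.adapter_sequence

    mirna_ids = sorted(references.sets["mirna_mature"])
    mirna_weights = _zipf_weights(len(mirna_ids), recipe.mirna_profile_shape)
    fragment_sources = {
        cat: sorted(references.sets[key].items())
        for cat, key in (
            ("rrna", "rrna"),
            ("trna", "trna"),
            ("other_ncrna", "other_ncrna"),
            ("mrna", "mrna"),
            ("bacterial", "contaminant_bacterial"),
            ("viral", "contaminant_viral"),
        )
    }
    mapped_kmers = references.mapped_kmers()
    lo, hi = recipe.fragment_length_range

    categories = [
        RECIPE_CATEGORIES[i]
        for i in rng.choice(
            len(RECIPE_CATEGORIES), size=recipe.depth, p=recipe.proportion_vector()
        )
    ]
    reads: list[ReadRecord] = []
    per_read: dict[str, tuple[str, str, int]] = {}
    realized: dict[str, int] = {c: 0 for c in RECIPE_CATEGORIES}
    position_means = recipe.quality_mean_start + recipe.quality_slope * np.arange(
        recipe.read_length
    )

    def fragment_from(cat: str) -> tuple[str, str]:
        entries = fragment_sources[cat]
        rid, seq = entries[int(rng.integers(len(entries)))]
        length = int(rng.integers(lo, min(hi, len(seq)) + 1))
        start = int(rng.integers(len(seq) - length + 1))
        return seq[start : start + length], rid

    for i, category in enumerate(categories):
        source = "-"
        if category == "mirna":
            idx = int(rng.choice(len(mirna_ids), p=mirna_weights))
            source = mirna_ids[idx]
            insert = references.sets["mirna_mature"][source]
        elif category in fragment_sources:
            insert, source = fragment_from(category)
        elif category == "genome_other":
            region = references.genome_other_region
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(len(region) - length + 1))
            insert = region[start : start + length]
            source = "chr1:intergenic"
        elif category == "adapter_dimer":
            insert = _random_seq(rng, int(rng.integers(0, 3)))
        elif category == "ultra_short":
            region = references.genome_other_region
            length = int(rng.integers(3, 15))
            start = int(rng.integers(len(region) - length + 1))
            insert = region[start : start + length]
            source = "chr1:intergenic"
        elif category == "unmapped_random":
            for _ in range(100):
                insert = _random_seq(rng, int(rng.integers(lo, hi + 1)))
                if not (_kmers(insert, DISJOINT_K) & mapped_kmers):
                    break
            source = "random"
        else:  # pragma: no cover - guarded by recipe validation
            raise AssertionError(category)

        if recipe.mutation_rate and rng.random() < recipe.mutation_rate:
            insert = _mutate(insert, rng)

        construct = (
            _random_seq(rng, preset.random_bases_5p)
            + insert
            + _random_seq(rng, preset.random_bases_3p)
            + adapter
            + _random_seq(rng, preset.umi_length)
        )
        if len(construct) < recipe.read_length:
            construct += _random_seq(rng, recipe.read_length - len(construct))
        sequence = construct[: recipe.read_length]
        qualities = np.clip(
            np.rint(
                rng.normal(position_means, recipe.quality_sd, size=recipe.read_length)
            ),
            2,
            40,
        ).astype(int)
        read_id = f"{sample_id}_{i:06d}"
        reads.append(ReadRecord(read_id, sequence, qualities.tolist()))
        per_read[read_id] = (category, source, len(insert))
        realized[category] += 1

    truth = TruthTable(recipe, per_read, realized)
    return reads, truth


def write_sample(
    recipe: SampleRecipe,
    references: SyntheticReferences,
    fastq_path: str | Path,
    truth_path: str | Path | None = None,
    sample_id: str = "sim_sample",
) -> TruthTable:
    reads, truth = simulate_sample(recipe, references, sample_id)
    write_fastq(reads, fastq_path)
    if truth_path is not None:
        truth.write_tsv(truth_path)
    return truth


@dataclass
class CorpusScheme:
    """Metadata layout for a simulated corpus."""

    species: str = "synthetic_species_A"
    kingdom: str = "animal"
    protocol: str = "Illumina"
    low_input_fraction: float = 0.0
    groups: tuple[str, ...] = ("groupA", "groupB")


def draw_recipe(
    base: SampleRecipe,
    rng: np.random.Generator,
    concentration: float = 250.0,
) -> SampleRecipe:
    """Draw one sample recipe from a Dirichlet prior around ``base``.

    ``concentration`` controls between-sample spread: proportions are
    Dirichlet(concentration * base proportions), and the Zipf exponent
    jitters by +-20%.
    """
    alpha = np.maximum(concentration * base.proportion_vector(), 1e-3)
    props = rng.dirichlet(alpha)
    props = props / props.sum()
    proportions = {c: float(p) for c, p in zip(RECIPE_CATEGORIES, props)}
    return dataclasses.replace(
        base,
        proportions=proportions,
        mirna_profile_shape=float(
            base.mirna_profile_shape * rng.uniform(0.8, 1.2)
        ),
        seed=int(rng.integers(2**31 - 1)),
    )


def simulate_corpus(
    n_samples: int,
    references: SyntheticReferences,
    seed: int,
    base_recipe: SampleRecipe | None = None,
    scheme: CorpusScheme | None = None,
    depth: int | None = None,
    min_stratum_size: int | None = None,
):
    """Simulate a whole reference corpus: vectors, metadata, Corpus.

    Each sample's recipe is drawn from the prior, the full feature
    pipeline runs on the simulated reads, and the resulting attribute
    vectors populate the stratified corpus.
    """
    from . import pipeline
    from .reference_corpus import (
        DEFAULT_MIN_STRATUM_SIZE,
        SampleMetadata,
        build_corpus,
    )

    scheme = scheme or CorpusScheme()
    base = base_recipe or SampleRecipe()
    if depth is not None:
        base = dataclasses.replace(base, depth=depth)
    rng = np.random.default_rng(seed)
    indexes = pipeline.build_indexes(references.as_reference_sets())
    preset = get_preset(base.protocol)
    vectors = []
    metadata = []
    for i in range(n_samples):
        recipe = draw_recipe(base, rng)
        sample_id = f"corpus_{i + 1:04d}"
        reads, _ = simulate_sample(recipe, references, sample_id)
        result = pipeline.process_reads(reads, indexes, preset, sample_id)
        vectors.append(result.vector)
        metadata.append(
            SampleMetadata(
                sample_id=sample_id,
                species=scheme.species,
                kingdom=scheme.kingdom,
                protocol=scheme.protocol,
                low_input=bool(rng.random() < scheme.low_input_fraction),
                group=scheme.groups[i % len(scheme.groups)],
            )
        )
    corpus = build_corpus(
        vectors,
        metadata,
        min_stratum_size=min_stratum_size
        if min_stratum_size is not None
        else DEFAULT_MIN_STRATUM_SIZE,
    )
    return vectors, metadata, corpus
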