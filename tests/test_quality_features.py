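"""Attribute computations: yield, complexity, moments, conservation."""

import json
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirqc import quality_features as qf
from mirqc.fastq_io import ReadRecord
from mirqc.read_mapping import MIRNA, RRNA, MiRNAProfile, ReadAssignment
from mirqc.trimming import (
    CATEGORY_ADAPTER_DIMER,
    CATEGORY_SHORT_READ,
    CATEGORY_ULTRA_SHORT,
    CATEGORY_VALID,
    TrimCounts,
)


def _counts(no_adapter=0, dimer=0, ultra=0, short=0, valid=0):
    tc = TrimCounts()
    tc.counts.update(
        {
            "no_adapter": no_adapter,
            CATEGORY_ADAPTER_DIMER: dimer,
            CATEGORY_ULTRA_SHORT: ultra,
            CATEGORY_SHORT_READ: short,
            CATEGORY_VALID: valid,
        }
    )
    return tc


def _mirna(insert, mult, mid):
    return ReadAssignment(insert, mult, MIRNA, mirna_id=mid)


# ------------------------------------------------------------------ yield
def test_yield_arithmetic():
    tc = _counts(dimer=10, ultra=10, valid=80)
    profile = MiRNAProfile({f"mir-{i}": 4 for i in range(10)})
    out = qf.compute_yield(tc, [], profile)
    assert out["total_input_reads"] == 100
    assert out["pct_valid_reads"] == 80.0
    assert out["total_valid_reads"] == 80
    assert out["n_detected_mirnas"] == 10
    assert out["pct_mirna_reads"] == 50.0


def test_yield_with_zero_valid_reads_is_missing():
    tc = _counts(dimer=100)
    out = qf.compute_yield(tc, [], MiRNAProfile())
    assert out["pct_valid_reads"] == 0.0
    assert out["pct_mirna_reads"] is None
    assert out["n_detected_mirnas"] is None


# -------------------------------------------------------------- library q
def test_library_quality_fractions():
    tc = _counts(dimer=10, ultra=5, short=5, valid=80)
    out = qf.compute_library_quality(tc, [])
    assert out["pct_min_length_filtered"] == 15.0
    assert out["pct_adapter_dimer"] == 10.0
    assert out["pct_ultra_short"] == 5.0
    assert out["pct_short_reads"] == 5.0
    assert out["pct_rrna"] == 0.0


def test_library_quality_empty_sample_is_an_error():
    with pytest.raises(ValueError):
        qf.compute_library_quality(_counts(), [])


# -------------------------------------------------------------- complexity
def test_complexity_ratio_extremes():
    assert qf.complexity_ratio(100, 100) == 1.0
    assert qf.complexity_ratio(100, 1) == 100.0
    with pytest.raises(ValueError):
        qf.complexity_ratio(100, 0)


def test_top_fraction_examples():
    profile = MiRNAProfile({"a": 47, "b": 30, "c": 23})
    assert qf.top_fraction(profile, 1) == 47.0
    assert qf.top_fraction(profile, 10) == 100.0
    assert qf.top_fraction(MiRNAProfile(), 1) is None


def test_mirnas_to_reach_examples():
    profile = MiRNAProfile({"a": 47, "b": 30, "c": 23})
    assert qf.mirnas_to_reach(profile, 50) == 2
    assert qf.mirnas_to_reach(MiRNAProfile({"only": 9}), 95) == 1
    uniform = MiRNAProfile({f"m{i:03d}": 7 for i in range(100)})
    assert qf.mirnas_to_reach(uniform, 50) == 50


def test_uniform_profile_closed_forms():
    for k in (1, 3, 10, 41):
        uniform = MiRNAProfile({f"m{i:03d}": 5 for i in range(k)})
        assert qf.top_fraction(uniform, 1) == pytest.approx(100.0 / k)
        assert qf.mirnas_to_reach(uniform, 50) == math.ceil(k / 2)


def _brute_top_fraction(counts, k):
    ordered = sorted(counts.values(), reverse=True)
    return 100.0 * sum(ordered[:k]) / sum(ordered)


def _brute_to_reach(counts, pct):
    ordered = sorted(counts.values(), reverse=True)
    total = sum(ordered)
    acc = 0
    for m, c in enumerate(ordered, 1):
        acc += c
        if acc * 100.0 >= pct * total - 1e-9:
            return m
    return len(ordered)


def test_complexity_oracles_on_random_zipf_profiles():
    rng = np.random.default_rng(2024)
    for _ in range(200):
        n = int(rng.integers(3, 120))
        exponent = rng.uniform(0.5, 1.6)
        weights = np.arange(1, n + 1, dtype=float) ** -exponent
        counts = rng.multinomial(5000, weights / weights.sum())
        profile = MiRNAProfile(
            {f"m{i:04d}": int(c) for i, c in enumerate(counts) if c > 0}
        )
        for k in (1, 5, 20):
            assert qf.top_fraction(profile, k) == pytest.approx(
                _brute_top_fraction(profile.counts, k), abs=1e-9
            )
        for pct in (50, 75, 95):
            assert qf.mirnas_to_reach(profile, pct) == _brute_to_reach(profile.counts, pct)


# ---------------------------------------------------------------- lengths
def test_length_spike_has_zero_sd_and_missing_skewness():
    out = qf.length_stats(qf.LengthHistogram({22: 500}))
    assert out["mean_length"] == 22 and out["mode_length"] == 22
    assert out["pct_length_peak"] == 100.0
    assert out["sd_length"] == 0.0
    assert out["skewness_length"] is None


def test_symmetric_histogram_has_zero_skewness():
    out = qf.length_stats(qf.LengthHistogram({20: 30, 22: 40, 24: 30}))
    assert out["mean_length"] == 22.0
    assert out["skewness_length"] == pytest.approx(0.0, abs=1e-12)


def test_moments_match_direct_expansion():
    rng = np.random.default_rng(9)
    for _ in range(100):
        lengths = rng.integers(15, 31, size=rng.integers(3, 40))
        hist = {}
        for l in lengths:
            hist[int(l)] = hist.get(int(l), 0) + 1
        out = qf.length_stats(qf.LengthHistogram(hist))
        expanded = np.array(lengths, dtype=float)
        assert out["mean_length"] == pytest.approx(expanded.mean())
        assert out["sd_length"] == pytest.approx(expanded.std())
        m2 = ((expanded - expanded.mean()) ** 2).mean()
        m3 = ((expanded - expanded.mean()) ** 3).mean()
        if m2 > 0:
            assert out["skewness_length"] == pytest.approx(m3 / m2**1.5)


def test_mirrored_histogram_negates_skewness():
    hist = {18: 10, 22: 80, 28: 10}
    out = qf.length_stats(qf.LengthHistogram(hist))
    mirrored = {46 - l: c for l, c in hist.items()}
    out_m = qf.length_stats(qf.LengthHistogram(mirrored))
    assert out["skewness_length"] == pytest.approx(-out_m["skewness_length"])
    # mass above the mode pulls skewness positive
    padded = qf.length_stats(qf.LengthHistogram({22: 80, 30: 20}))
    assert padded["skewness_length"] > 0


def test_mode_tie_break_takes_smallest_length():
    out = qf.length_stats(qf.LengthHistogram({21: 50, 23: 50}))
    assert out["mode_length"] == 21


def test_empty_histogram_is_all_missing():
    out = qf.length_stats(qf.LengthHistogram({}))
    assert all(v is None for v in out.values())


# ------------------------------------------------------------ composition
def test_composition_zero_when_all_mirna():
    assignments = [_mirna("A" * 22, 10, "mir-a")]
    out = qf.rna_composition(assignments, 10)
    assert all(v == 0.0 for v in out.values())


def test_category_percentages_conserve_total():
    assignments = [
        _mirna("A" * 22, 30, "mir-a"),
        ReadAssignment("C" * 22, 20, RRNA),
        ReadAssignment("G" * 22, 25, "tRNA"),
        ReadAssignment("T" * 22, 10, "contaminantViral"),
        ReadAssignment("AC" * 11, 15, "unmapped"),
    ]
    total = 100
    comp = qf.rna_composition(assignments, total)
    contam = qf.contamination(assignments, total)
    y = qf.compute_yield(_counts(valid=total), assignments, MiRNAProfile({"mir-a": 30}))
    rrna = qf.compute_library_quality(_counts(valid=total), assignments)["pct_rrna"]
    acct = (
        y["pct_mirna_reads"]
        + rrna
        + comp["pct_trna"]
        + comp["pct_other_ncrna"]
        + comp["pct_mrna"]
        + comp["pct_genome_other"]
        + contam["pct_genome_unmapped"]
    )
    assert acct == pytest.approx(100.0, abs=1e-9)


def test_unmapped_superset_of_contaminants():
    assignments = [
        ReadAssignment("T" * 22, 10, "contaminantViral"),
        ReadAssignment("G" * 22, 5, "contaminantBacterial"),
        ReadAssignment("AC" * 11, 15, "unmapped"),
    ]
    out = qf.contamination(assignments, 30)
    assert out["pct_genome_unmapped"] >= out["pct_bacterial"] + out["pct_viral"]


# -------------------------------------------------------------- seq quality
def test_constant_quality_gives_constant_summaries():
    reads = [ReadRecord(f"r{i}", "ACGT" * 5, [30] * 20) for i in range(150)]
    out = qf.sequencing_quality(reads)
    assert all(v == 30.0 for v in out.values())


def test_seq_quality_matches_full_matrix_oracle():
    rng = np.random.default_rng(31)
    n, L = 200, 40
    matrix = rng.integers(2, 41, size=(n, L))
    reads = [ReadRecord(f"r{i}", "A" * L, list(map(int, matrix[i]))) for i in range(n)]
    out = qf.sequencing_quality(reads)
    assert out["mean_q_mean"] == pytest.approx(matrix.mean(axis=0).mean())
    assert out["mean_q_median"] == pytest.approx(
        np.percentile(matrix, 50, axis=0).mean()
    )
    assert out["mean_q_q25"] == pytest.approx(np.percentile(matrix, 25, axis=0).mean())
    assert out["mean_q_q10"] == pytest.approx(np.percentile(matrix, 10, axis=0).mean())


def test_low_coverage_positions_are_dropped():
    reads = [ReadRecord(f"r{i}", "A" * 20, [30] * 20) for i in range(150)]
    reads += [ReadRecord("long", "A" * 30, [30] * 20 + [2] * 10)]
    out = qf.sequencing_quality(reads)
    assert out["mean_q_mean"] == 30.0  # the lone 30-nt read's tail is ignored


# ---------------------------------------------------------------- assemble
def _full_vector(sample_id="s1"):
    values = {name: float(i) for i, name in enumerate(qf.ATTRIBUTE_NAMES)}
    for name in qf.ATTRIBUTE_NAMES:
        if name.startswith("pct_"):
            values[name] = 50.0
    return qf.QualityAttributeVector(sample_id, values)


def test_registry_has_34_attributes_in_declared_sections():
    assert len(qf.ATTRIBUTE_REGISTRY) == 34
    assert {a.section for a in qf.ATTRIBUTE_REGISTRY} == set(qf.SECTIONS)
    assert all(
        a.orientation in (qf.HIGHER_BETTER, qf.LOWER_BETTER, qf.NEUTRAL)
        for a in qf.ATTRIBUTE_REGISTRY
    )


def test_assemble_requires_every_attribute():
    with pytest.raises(ValueError, match="missing"):
        qf.assemble("s1", {"total_input_reads": 1.0})
    with pytest.raises(ValueError, match="unknown"):
        qf.assemble("s1", {"bogus": 1.0})


def test_vector_json_round_trip_is_lossless():
    vec = _full_vector()
    again = qf.QualityAttributeVector.from_dict(json.loads(json.dumps(vec.to_dict())))
    assert again == vec


def test_same_sample_processed_twice_is_identical(references, indexes, illumina_preset):
    from mirqc import pipeline
    from mirqc.simulate import SampleRecipe, simulate_sample

    reads, _ = simulate_sample(SampleRecipe(depth=400, seed=8), references)
    v1 = pipeline.process_reads(reads, indexes, illumina_preset, "s").vector
    v2 = pipeline.process_reads(reads, indexes, illumina_preset, "s").vector
    assert v1 == v2


def test_scale_invariance_of_percentage_attributes():
    """Doubling every read count leaves percentages and shapes unchanged."""
    tc1 = _counts(dimer=10, ultra=5, short=10, valid=75)
    tc2 = _counts(dimer=20, ultra=10, short=20, valid=150)
    a1 = [_mirna("A" * 22, 40, "mir-a"), ReadAssignment("C" * 22, 45, RRNA)]
    a2 = [_mirna("A" * 22, 80, "mir-a"), ReadAssignment("C" * 22, 90, RRNA)]
    p1 = MiRNAProfile({"mir-a": 40})
    p2 = MiRNAProfile({"mir-a": 80})
    y1, y2 = qf.compute_yield(tc1, a1, p1), qf.compute_yield(tc2, a2, p2)
    assert y1["pct_valid_reads"] == y2["pct_valid_reads"]
    assert y1["pct_mirna_reads"] == y2["pct_mirna_reads"]
    assert y2["total_input_reads"] == 2 * y1["total_input_reads"]
    l1 = qf.length_stats(qf.LengthHistogram({20: 10, 22: 30}))
    l2 = qf.length_stats(qf.LengthHistogram({20: 20, 22: 60}))
    assert l1 == l2
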