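"""Stratified reference corpora, empirical percentiles and quartile colours.

Rather than judging QC attributes against arbitrary absolute thresholds,
every attribute of a query sample is ranked against the empirical
distribution of the same attribute in comparable samples.  Five
comparison strata are maintained: same kingdom, same species, same
kingdom+protocol, same species+protocol, and (when declared) low-input
samples.  Percentiles use the midrank convention, so a value equal to
every corpus value sits at the 50th percentile.  Colours code the
orientation-corrected percentile quartile: green (best) / yellow /
orange / red (worst); neutral attributes are never coloured.
"""

from __future__ import annotations

import bisect
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .quality_features import (
    ATTRIBUTE_BY_NAME,
    ATTRIBUTE_NAMES,
    HIGHER_BETTER,
    LOWER_BETTER,
    NEUTRAL,
    QualityAttributeVector,
)

logger = logging.getLogger(__name__)

CORPUS_FORMAT_VERSION = 1
DEFAULT_MIN_STRATUM_SIZE = 20

STRATUM_KINDS = ("kingdom", "species", "kingdom_protocol", "species_protocol", "low_input")

COLOURS = ("green", "yellow", "orange", "red")


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    species: str
    kingdom: str  # 'animal' or 'plant'
    protocol: str
    low_input: bool = False
    group: str | None = None

    def __post_init__(self) -> None:
        if self.kingdom not in ("animal", "plant"):
            raise ValueError(f"kingdom must be animal|plant, got {self.kingdom!r}")
        if self.group is not None and not self.group:
            raise ValueError("group label must be non-empty when present")

    def stratum_keys(self) -> list[tuple]:
        keys: list[tuple] = [
            ("kingdom", self.kingdom),
            ("species", self.species),
            ("kingdom_protocol", self.kingdom, self.protocol),
            ("species_protocol", self.species, self.protocol),
        ]
        if self.low_input:
            keys.append(("low_input",))
        return keys


@dataclass
class CorpusStratum:
    """Sorted per-attribute value lists for one comparison stratum."""

    stratum_key: tuple
    distributions: dict[str, list[float]] = field(default_factory=dict)
    n_samples: int = 0

    def add_vector(self, vector: QualityAttributeVector) -> None:
        self.n_samples += 1
        for name, value in vector.values.items():
            if value is None:
                continue
            bisect.insort(self.distributions.setdefault(name, []), float(value))

    def usable(self, min_stratum_size: int) -> bool:
        return self.n_samples >= min_stratum_size


@dataclass
class Corpus:
    """All strata built from a collection of processed samples."""

    strata: dict[tuple, CorpusStratum] = field(default_factory=dict)
    sample_ids: set = field(default_factory=set)
    min_stratum_size: int = DEFAULT_MIN_STRATUM_SIZE

    def add_sample(self, vector: QualityAttributeVector, metadata: SampleMetadata) -> None:
        if metadata.sample_id in self.sample_ids:
            raise ValueError(f"duplicate sample id {metadata.sample_id!r} in corpus")
        self.sample_ids.add(metadata.sample_id)
        for key in metadata.stratum_keys():
            stratum = self.strata.get(key)
            if stratum is None:
                stratum = self.strata[key] = CorpusStratum(key)
            stratum.add_vector(vector)

    # -- serialisation ------------------------------------------------
    def save(self, path: str | Path) -> None:
        payload = {
            "format_version": CORPUS_FORMAT_VERSION,
            "attribute_registry": list(ATTRIBUTE_NAMES),
            "min_stratum_size": self.min_stratum_size,
            "sample_ids": sorted(str(s) for s in self.sample_ids),
            "strata": [
                {
                    "key": list(stratum.stratum_key),
                    "n_samples": stratum.n_samples,
                    "distributions": stratum.distributions,
                }
                for stratum in (self.strata[k] for k in sorted(self.strata))
            ],
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "Corpus":
        payload = json.loads(Path(path).read_text())
        if payload.get("format_version") != CORPUS_FORMAT_VERSION:
            raise ValueError(
                f"unsupported corpus format version {payload.get('format_version')}"
            )
        if payload.get("attribute_registry") != list(ATTRIBUTE_NAMES):
            raise ValueError("corpus attribute registry does not match this build")
        corpus = cls(min_stratum_size=payload["min_stratum_size"])
        corpus.sample_ids = set(payload["sample_ids"])
        for item in payload["strata"]:
            key = tuple(item["key"])
            corpus.strata[key] = CorpusStratum(
                key,
                {k: list(v) for k, v in item["distributions"].items()},
                item["n_samples"],
            )
        return corpus


def build_corpus(
    vectors: Sequence[QualityAttributeVector],
    metadata: Sequence[SampleMetadata],
    min_stratum_size: int = DEFAULT_MIN_STRATUM_SIZE,
) -> Corpus:
    """Populate every stratum implied by the sample metadata."""
    if len(vectors) != len(metadata):
        raise ValueError("one metadata record required per vector")
    corpus = Corpus(min_stratum_size=min_stratum_size)
    for vector, meta in zip(vectors, metadata):
        corpus.add_sample(vector, meta)
    return corpus


def percentile(value: float, sorted_values: Sequence[float]) -> float | None:
    """Midrank empirical percentile of ``value`` in a sorted list.

    100 * (count(< value) + 0.5 * count(== value)) / n; None (with a
    warning) for an empty list.
    """
    n = len(sorted_values)
    if n == 0:
        logger.warning("percentile requested against an empty distribution")
        return None
    lo = bisect.bisect_left(sorted_values, value)
    hi = bisect.bisect_right(sorted_values, value)
    return 100.0 * (lo + 0.5 * (hi - lo)) / n


def quartile_colour(pct: float, orientation: str) -> str | None:
    """Colour for an attribute percentile under its orientation.

    Goodness g = percentile (higher_better) or 100 - percentile
    (lower_better); bins [75,100] green, [50,75) yellow, [25,50) orange,
    [0,25) red.  Neutral attributes return None.
    """
    if orientation == NEUTRAL:
        return None
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"percentile out of range: {pct}")
    if orientation == HIGHER_BETTER:
        g = pct
    elif orientation == LOWER_BETTER:
        g = 100.0 - pct
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    if g >= 75.0:
        return "green"
    if g >= 50.0:
        return "yellow"
    if g >= 25.0:
        return "orange"
    return "red"


@dataclass
class RankedAttribute:
    attribute: str
    value: float | None
    percentile: float | None
    quartile_colour: str | None
    stratum_key: tuple
    stratum_n: int


@dataclass
class RankedView:
    """One comparison view (one reference set) of a sample."""

    kind: str
    stratum_key: tuple
    available: bool
    reason: str | None = None
    attributes: list[RankedAttribute] = field(default_factory=list)


def _rank_against(
    vector: QualityAttributeVector, stratum: CorpusStratum
) -> list[RankedAttribute]:
    ranked = []
    for name in ATTRIBUTE_NAMES:
        spec = ATTRIBUTE_BY_NAME[name]
        value = vector.values[name]
        dist = stratum.distributions.get(name, [])
        if value is None or not dist:
            ranked.append(
                RankedAttribute(name, value, None, None, stratum.stratum_key, stratum.n_samples)
            )
            continue
        pct = percentile(value, dist)
        if spec.rank_abs:
            # rank magnitude (e.g. |skewness|): re-rank against |corpus|
            abs_dist = sorted(abs(v) for v in dist)
            colour_pct = percentile(abs(value), abs_dist)
        else:
            colour_pct = pct
        colour = quartile_colour(colour_pct, spec.orientation)
        ranked.append(
            RankedAttribute(name, value, pct, colour, stratum.stratum_key, stratum.n_samples)
        )
    return ranked


def rank_sample(
    vector: QualityAttributeVector,
    metadata: SampleMetadata,
    corpus: Corpus,
) -> dict[str, RankedView]:
    """Rank one sample against every applicable reference stratum.

    Returns up to five views keyed by stratum kind; strata that are
    absent or below the minimum size are flagged unavailable rather than
    silently dropped.  Raises when no stratum at all is usable.
    """
    views: dict[str, RankedView] = {}
    for key in metadata.stratum_keys():
        kind = key[0]
        stratum = corpus.strata.get(key)
        if stratum is None:
            views[kind] = RankedView(kind, key, False, reason="stratum absent from corpus")
        elif not stratum.usable(corpus.min_stratum_size):
            views[kind] = RankedView(
                kind,
                key,
                False,
                reason=f"stratum has {stratum.n_samples} samples "
                f"(< {corpus.min_stratum_size})",
            )
        else:
            views[kind] = RankedView(kind, key, True, attributes=_rank_against(vector, stratum))
    if not any(v.available for v in views.values()):
        raise ValueError(
            "no usable reference stratum for this sample; build or extend the corpus"
        )
    return views
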