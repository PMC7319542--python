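"""Multi-sample report assembly: tables, PCA, group summaries, bundles.

The report bundle mirrors the sectioned QC layout: sequencing yield,
library quality, library complexity, putative contamination, read length
distribution, RNA composition and sequencing quality, each attribute
carrying its absolute value plus its percentile and quartile colour per
reference stratum.  Outputs are machine-readable JSON, TSV tables, and
an optional static HTML page.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .quality_features import (
    ATTRIBUTE_BY_NAME,
    ATTRIBUTE_NAMES,
    SECTIONS,
    QualityAttributeVector,
)
from .read_mapping import MiRNAProfile
from .reference_corpus import RankedView, SampleMetadata

logger = logging.getLogger(__name__)

RPM_SCALE = 1e6


@dataclass
class ExpressionMatrix:
    """Samples x miRNAs matrix, reads-per-million normalised per sample."""

    rpm: pd.DataFrame  # index: sample ids, columns: miRNA ids

    @classmethod
    def from_profiles(cls, profiles: Mapping[str, MiRNAProfile]) -> "ExpressionMatrix":
        counts = pd.DataFrame(
            {sid: pd.Series(p.counts, dtype=float) for sid, p in profiles.items()}
        ).T.fillna(0.0)
        counts = counts.reindex(sorted(counts.columns), axis=1)
        totals = counts.sum(axis=1)
        rpm = counts.div(totals.where(totals > 0, np.nan), axis=0) * RPM_SCALE
        return cls(rpm.fillna(0.0))


@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # columns PC1, PC2
    explained_variance: tuple[float, float]
    mirna_ids: list[str]


def pca_top50(matrix: ExpressionMatrix, n_top: int = 50) -> PCAResult:
    """PCA of the 50 most expressed miRNAs across samples.

    Selection is by mean normalised expression; values are log10(x+1)
    transformed and column-centred.  Component signs are fixed so the
    largest-magnitude loading of each axis is positive, making the
    projection deterministic.
    """
    if len(matrix.rpm) < 3:
        raise ValueError("PCA requires at least 3 samples")
    means = matrix.rpm.mean(axis=0)
    top = means.sort_values(ascending=False, kind="stable").index[:n_top]
    data = np.log10(matrix.rpm[top].to_numpy() + 1.0)
    pca = PCA(n_components=min(2, data.shape[0] - 1, data.shape[1]))
    coords = pca.fit_transform(data)
    components = pca.components_
    for i in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] *= -1
            coords[:, i] *= -1
    if coords.shape[1] < 2:  # degenerate: single informative axis
        coords = np.column_stack([coords, np.zeros(len(coords))])
        explained = (float(pca.explained_variance_ratio_[0]), 0.0)
    else:
        explained = (
            float(pca.explained_variance_ratio_[0]),
            float(pca.explained_variance_ratio_[1]),
        )
    frame = pd.DataFrame(coords[:, :2], index=matrix.rpm.index, columns=["PC1", "PC2"])
    return PCAResult(frame, explained, list(top))


@dataclass
class GroupSummary:
    attribute: str
    group: str
    n: int
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    outlier_sample_ids: list[str] = field(default_factory=list)


def group_summaries(
    vectors: Sequence[QualityAttributeVector],
    metadata: Sequence[SampleMetadata],
) -> list[GroupSummary]:
    """Tukey five-number summary + outliers per group per attribute."""
    by_group: dict[str, list[tuple[str, QualityAttributeVector]]] = {}
    for vec, meta in zip(vectors, metadata):
        group = meta.group or "all"
        by_group.setdefault(group, []).append((meta.sample_id, vec))
    summaries: list[GroupSummary] = []
    for attribute in ATTRIBUTE_NAMES:
        for group in sorted(by_group):
            pairs = [
                (sid, vec.values[attribute])
                for sid, vec in by_group[group]
                if vec.values[attribute] is not None
            ]
            if not pairs:
                continue
            values = np.array([v for _, v in pairs], dtype=float)
            q1, med, q3 = np.percentile(values, [25, 50, 75])
            iqr = q3 - q1
            lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            outliers = [sid for sid, v in pairs if v < lo or v > hi]
            summaries.append(
                GroupSummary(
                    attribute,
                    group,
                    len(pairs),
                    float(values.min()),
                    float(q1),
                    float(med),
                    float(q3),
                    float(values.max()),
                    outliers,
                )
            )
    return summaries


def _ranked_view_payload(view: RankedView) -> dict:
    payload: dict = {
        "stratum_key": list(view.stratum_key),
        "available": view.available,
    }
    if not view.available:
        payload["reason"] = view.reason
        payload["attributes"] = {
            name: {"value": None, "percentile": None, "colour": None, "status": "unavailable"}
            for name in ATTRIBUTE_NAMES
        }
        return payload
    payload["stratum_n"] = view.attributes[0].stratum_n if view.attributes else 0
    payload["attributes"] = {
        ra.attribute: {
            "value": ra.value,
            "percentile": ra.percentile,
            "colour": ra.quartile_colour,
            "status": "ranked" if ra.percentile is not None else "missing",
        }
        for ra in view.attributes
    }
    return payload


def report_payload(
    vectors: Sequence[QualityAttributeVector],
    metadata: Sequence[SampleMetadata],
    ranked: Mapping[str, Mapping[str, RankedView]],
    pca: PCAResult | None,
    summaries: Sequence[GroupSummary],
) -> dict:
    """Assemble the machine-readable report structure."""
    meta_by_id = {m.sample_id: m for m in metadata}
    samples = []
    for vec in vectors:
        meta = meta_by_id[vec.sample_id]
        samples.append(
            {
                "sample_id": vec.sample_id,
                "species": meta.species,
                "kingdom": meta.kingdom,
                "protocol": meta.protocol,
                "low_input": meta.low_input,
                "group": meta.group,
                "attributes": {
                    name: {
                        "value": vec.values[name],
                        "section": ATTRIBUTE_BY_NAME[name].section,
                        "orientation": ATTRIBUTE_BY_NAME[name].orientation,
                    }
                    for name in ATTRIBUTE_NAMES
                },
                "ranked_views": {
                    kind: _ranked_view_payload(view)
                    for kind, view in ranked.get(vec.sample_id, {}).items()
                },
            }
        )
    payload: dict = {
        "report_version": 1,
        "sections": list(SECTIONS),
        "attribute_registry": [
            {
                "name": a.name,
                "section": a.section,
                "orientation": a.orientation,
                "ranked_on_absolute_value": a.rank_abs,
            }
            for a in ATTRIBUTE_BY_NAME.values()
        ],
        "notes": {
            "percentile": "midrank empirical percentile against the stratum distribution",
            "colour_code": "quartiles of the orientation-corrected percentile: "
            "green (best), yellow, orange, red (worst)",
            "pca_preprocessing": "reads-per-million, log10(x+1), column-centred; "
            "top 50 miRNAs by mean normalised expression",
            "moments": "length sd/skewness use population (uncorrected) moments",
        },
        "samples": samples,
        "group_summaries": [
            {
                "attribute": s.attribute,
                "group": s.group,
                "n": s.n,
                "min": s.minimum,
                "q1": s.q1,
                "median": s.median,
                "q3": s.q3,
                "max": s.maximum,
                "outlier_sample_ids": s.outlier_sample_ids,
            }
            for s in summaries
        ],
    }
    if pca is not None:
        payload["pca"] = {
            "explained_variance": list(pca.explained_variance),
            "mirna_ids": pca.mirna_ids,
            "coordinates": {
                sid: [float(row.PC1), float(row.PC2)]
                for sid, row in pca.coordinates.iterrows()
            },
        }
    else:
        payload["pca"] = {"available": False, "reason": "fewer than 3 samples"}
    return payload


def attributes_table(vectors: Sequence[QualityAttributeVector]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"sample_id": v.sample_id, **v.values} for v in vectors]
    ).set_index("sample_id")


_HTML_STYLE = """
table{border-collapse:collapse;font-family:sans-serif;font-size:12px}
td,th{border:1px solid #999;padding:2px 6px}
.green{background:#b6e3b6}.yellow{background:#f4ef9f}
.orange{background:#f7c789}.red{background:#f2a3a3}
"""


def _render_html(payload: dict) -> str:
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        "<title>miRNA-seq comparative QC report</title>",
        f"<style>{_HTML_STYLE}</style></head><body>",
        "<h1>miRNA-seq comparative QC report</h1>",
    ]
    registry = payload["attribute_registry"]
    for section in payload["sections"]:
        names = [a["name"] for a in registry if a["section"] == section]
        parts.append(f"<h2>{section.replace('_', ' ')}</h2><table><tr><th>sample</th>")
        parts.extend(f"<th>{n}</th>" for n in names)
        parts.append("</tr>")
        for sample in payload["samples"]:
            parts.append(f"<tr><td>{sample['sample_id']}</td>")
            view = next(
                (v for v in sample["ranked_views"].values() if v.get("available")),
                None,
            )
            for name in names:
                value = sample["attributes"][name]["value"]
                text = "NA" if value is None else f"{value:.3g}"
                colour = ""
                if view is not None:
                    cell = view["attributes"].get(name, {})
                    if cell.get("colour"):
                        colour = f" class='{cell['colour']}'"
                    if cell.get("percentile") is not None:
                        text += f" (p{cell['percentile']:.1f})"
                parts.append(f"<td{colour}>{text}</td>")
            parts.append("</tr>")
        parts.append("</table>")
    parts.append("</body></html>")
    return "".join(parts)


def render_report(
    out_dir: str | Path,
    vectors: Sequence[QualityAttributeVector],
    metadata: Sequence[SampleMetadata],
    ranked: Mapping[str, Mapping[str, RankedView]],
    pca: PCAResult | None,
    summaries: Sequence[GroupSummary],
    html: bool = False,
) -> dict[str, Path]:
    """Write the report bundle; returns the paths written.

    report.json carries every attribute's absolute value, percentile per
    reference stratum and colour; attributes.tsv is the samples x
    attributes matrix; ranked_<kind>.tsv one table per stratum kind;
    pca.tsv the sample coordinates.  No timestamps are written, so
    identical inputs yield byte-identical bundles.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = report_payload(vectors, metadata, ranked, pca, summaries)
    paths: dict[str, Path] = {}

    report_json = out_dir / "report.json"
    report_json.write_text(json.dumps(payload, indent=1, sort_keys=True))
    paths["report.json"] = report_json

    table = attributes_table(vectors)
    attributes_tsv = out_dir / "attributes.tsv"
    table.to_csv(attributes_tsv, sep="\t")
    paths["attributes.tsv"] = attributes_tsv

    kinds = sorted({kind for views in ranked.values() for kind in views})
    for kind in kinds:
        rows = []
        for vec in vectors:
            view = ranked.get(vec.sample_id, {}).get(kind)
            if view is None:
                continue
            for name in ATTRIBUTE_NAMES:
                if view.available:
                    ra = next(a for a in view.attributes if a.attribute == name)
                    rows.append(
                        {
                            "sample_id": vec.sample_id,
                            "attribute": name,
                            "value": ra.value,
                            "percentile": ra.percentile,
                            "colour": ra.quartile_colour,
                            "status": "ranked" if ra.percentile is not None else "missing",
                        }
                    )
                else:
                    rows.append(
                        {
                            "sample_id": vec.sample_id,
                            "attribute": name,
                            "value": vec.values[name],
                            "percentile": None,
                            "colour": None,
                            "status": "unavailable",
                        }
                    )
        path = out_dir / f"ranked_{kind}.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        paths[path.name] = path

    if pca is not None:
        pca_tsv = out_dir / "pca.tsv"
        pca.coordinates.to_csv(pca_tsv, sep="\t")
        paths["pca.tsv"] = pca_tsv

    if html:
        html_path = out_dir / "report.html"
        html_path.write_text(_render_html(payload))
        paths["report.html"] = html_path
    return paths
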