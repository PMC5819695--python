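"""Fold-change calling, pairwise group contrasts, and the
triple-differential intersection.

The pooled screen has no replication, so calls are pure fold-change
thresholding: UP iff fold change strictly exceeds ``up_threshold``,
DOWN iff strictly below ``down_threshold``, otherwise NS. Triple
membership requires a non-NS call in every contrast, regardless of
direction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .errors import ArgumentError, ConfigurationError, ContrastError
from .io import AnnotationTable
from .quantify import delta_delta_ct, fold_change
from .types import Call, ContrastResult, NormalizedMatrix, TripleDifferentialRecord

log = logging.getLogger(__name__)

DEFAULT_CONTRASTS: tuple[tuple[str, str], ...] = (("PER", "LM"), ("PER", "M0"), ("LM", "M0"))


def contrast_label(group: str, reference: str) -> str:
    return f"{group}_vs_{reference}"


@dataclass(frozen=True)
class ScreenConfig:
    """Strict fold-change thresholds and the ordered contrast list."""

    up_threshold: float = 2.00
    down_threshold: float = 0.500
    contrasts: tuple[tuple[str, str], ...] = DEFAULT_CONTRASTS

    def __post_init__(self):
        if not (0 < self.down_threshold < 1 < self.up_threshold):
            raise ConfigurationError(
                "thresholds must satisfy 0 < down_threshold < 1 < up_threshold, got "
                f"down={self.down_threshold}, up={self.up_threshold}"
            )


def classify(fc: float, config: ScreenConfig) -> Call:
    """Threshold one fold change; boundary equality is NS."""
    if fc > config.up_threshold:
        return Call.UP
    if fc < config.down_threshold:
        return Call.DOWN
    return Call.NS


def call_contrast(
    norm: NormalizedMatrix,
    contrast: tuple[str, str],
    config: ScreenConfig = ScreenConfig(),
    sample_of_group: Optional[Mapping[str, str]] = None,
) -> list[ContrastResult]:
    """Call every retained assay for one (group, reference) contrast.

    ``norm`` holds pooled dCT columns. By default a group's pooled
    sample is the column named after the group; ``sample_of_group``
    overrides that mapping. Results keep the input assay order.
    """
    group, reference = contrast
    mapping = sample_of_group or {}
    out: list[ContrastResult] = []
    names = []
    for g in (group, reference):
        name = mapping.get(g, g)
        if name not in norm.samples:
            raise ContrastError(f"no pooled sample for group {g!r}")
        names.append(name)
    ddct = delta_delta_ct(norm, names[0], names[1])
    label = contrast_label(group, reference)
    for assay_id in norm.assay_ids:
        if assay_id not in ddct.index:
            continue
        d = float(ddct[assay_id])
        fc = fold_change(d)
        out.append(ContrastResult(assay_id, label, d, fc, classify(fc, config)))
    return out


def triple_differential(
    per_contrast: Sequence[Sequence[ContrastResult]],
) -> list[TripleDifferentialRecord]:
    """Intersect the contrasts: triple iff non-NS in every one.

    Direction need not agree across contrasts. All result lists must
    cover the same assay universe.
    """
    if not per_contrast:
        raise ArgumentError("no contrast results given")
    universes = [set(r.assay_id for r in results) for results in per_contrast]
    base = universes[0]
    for other in universes[1:]:
        if other != base:
            diff = sorted(base.symmetric_difference(other))
            raise ArgumentError(f"assay universe mismatch: {diff}")
    by_assay: dict[str, dict[str, Call]] = {}
    order: list[str] = []
    for results in per_contrast:
        for r in results:
            if r.assay_id not in by_assay:
                by_assay[r.assay_id] = {}
                order.append(r.assay_id)
            by_assay[r.assay_id][r.contrast] = r.call
    records = []
    for assay_id in order:
        calls = by_assay[assay_id]
        is_triple = all(c is not Call.NS for c in calls.values())
        records.append(TripleDifferentialRecord(assay_id, calls, is_triple))
    n_triple = sum(r.is_triple for r in records)
    log.info("triple-differential: %d of %d assays", n_triple, len(records))
    return records


def rank_candidates(results: Sequence[ContrastResult]) -> list[ContrastResult]:
    """Order by fold-change magnitude |log2 fc| descending, ties by assay_id."""
    if not results:
        raise ArgumentError("no results to rank")
    return sorted(results, key=lambda r: (-abs(math.log2(r.fold_change)), r.assay_id))


def _stem(assay_id: str) -> str:
    """Drop a -5p/-3p strand suffix for suffix-tolerant matching."""
    lower = assay_id.lower()
    for suffix in ("-5p", "-3p"):
        if lower.endswith(suffix):
            return lower[: -len(suffix)]
    return lower


def annotate_candidates(
    records: Sequence[TripleDifferentialRecord],
    annotation: AnnotationTable,
    *,
    suffix_tolerant: bool = False,
) -> list[TripleDifferentialRecord]:
    """Join disease terms onto records by assay id.

    Matching is exact on the case-normalized assay id; with
    ``suffix_tolerant`` a stem entry (e.g. an id without -5p/-3p) also
    matches both strand records.
    """
    exact: dict[str, list[str]] = {}
    stems: dict[str, list[str]] = {}
    for _, row in annotation.frame.iterrows():
        aid = str(row["assay_id"]).lower()
        exact.setdefault(aid, []).append(str(row["disease"]))
        stems.setdefault(_stem(aid), []).append(str(row["disease"]))
    out = []
    for rec in records:
        key = rec.assay_id.lower()
        terms = list(exact.get(key, []))
        if suffix_tolerant and not terms:
            terms = list(stems.get(_stem(key), []))
        out.append(
            TripleDifferentialRecord(rec.assay_id, dict(rec.calls), rec.is_triple, sorted(set(terms)))
        )
    return out
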