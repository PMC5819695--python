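"""Delimited-text readers and writers for every pipeline artifact.

Canonical output dialect is TSV; comma/semicolon input is accepted via
:class:`Dialect`. The non-detected state is serialized as
``"Undetermined"`` (the instrument-export convention) and a configurable
token set maps to it on read. All writers are deterministic: the same
object always produces byte-identical text.
"""

from __future__ import annotations

import io as _stdio
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ArgumentError, FormatError
from .types import (
    AssayDefinition,
    Call,
    ContrastResult,
    CtMatrix,
    NormalizedMatrix,
    SampleManifest,
    TripleDifferentialRecord,
    default_assay_roles,
)

NON_DETECTED_TOKEN = "Undetermined"

Source = Union[str, IO[str]]


@dataclass(frozen=True)
class Dialect:
    """Input dialect: field separator and tokens mapping to non-detected."""

    separator: str = "\t"
    missing_tokens: tuple[str, ...] = ("Undetermined", "NA", "")


def _open(source: Source, mode: str):
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(source, mode, newline=""), True


# ---------------------------------------------------------------------------
# CT matrix


def read_ct_table(
    source: Source,
    dialect: Dialect = Dialect(),
    *,
    housekeeper_ids: Sequence[str] = ("RNU44", "RNU48", "U6"),
    negative_control_id: str = "ath-miR-159a",
) -> CtMatrix:
    """Parse a CT table: first column assay id, remaining columns samples.

    Missing-value tokens from the dialect become the non-detected state.
    Assay roles are assigned by name from the configured housekeeper and
    negative-control ids.
    """
    fh, close = _open(source, "r")
    try:
        text = fh.read()
    finally:
        if close:
            fh.close()
    lines = [ln for ln in text.splitlines() if ln != ""]
    if not lines:
        raise FormatError("empty CT table")
    sep = dialect.separator
    header = lines[0].split(sep)
    samples = header[1:]
    missing = set(dialect.missing_tokens)
    assay_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split(sep)
        if len(fields) != len(header):
            raise FormatError(f"line {lineno}: expected {len(header)} fields, got {len(fields)}")
        aid = fields[0]
        row = []
        for sample, tok in zip(samples, fields[1:]):
            tok = tok.strip() if tok.strip() in missing or tok in missing else tok
            if tok in missing:
                row.append(np.nan)
            else:
                try:
                    row.append(float(tok))
                except ValueError:
                    raise FormatError(
                        f"unparseable CT at assay {aid!r}, sample {sample!r}: {tok!r}"
                    ) from None
        assay_ids.append(aid)
        rows.append(row)
    values = pd.DataFrame(rows, index=assay_ids, columns=samples, dtype=float)
    assays = default_assay_roles(assay_ids, housekeeper_ids, negative_control_id)
    return CtMatrix(assays, values)


def write_ct_table(ct: CtMatrix, sink: Source) -> None:
    """Write a CT table as TSV; non-detected cells become ``Undetermined``."""
    fh, close = _open(sink, "w")
    try:
        fh.write("assay_id\t" + "\t".join(ct.samples) + "\n")
        for aid in ct.assay_ids:
            cells = []
            for s in ct.samples:
                v = ct.values.at[aid, s]
                cells.append(NON_DETECTED_TOKEN if pd.isna(v) else repr(float(v)))
            fh.write(aid + "\t" + "\t".join(cells) + "\n")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# Sample manifest


def read_manifest(source: Source, dialect: Dialect = Dialect()) -> SampleManifest:
    """Parse a manifest with columns sample_id, group, is_pool, attributes."""
    fh, close = _open(source, "r")
    try:
        frame = pd.read_csv(fh, sep=dialect.separator, dtype=str)
    finally:
        if close:
            fh.close()
    required = ("sample_id", "group", "is_pool")
    for col in required:
        if col not in frame.columns:
            raise FormatError(f"manifest missing column {col!r}")
    frame = frame.set_index("sample_id")
    frame["is_pool"] = frame["is_pool"].astype(int).astype(bool)
    for col in frame.columns:
        if col not in ("group", "is_pool"):
            frame[col] = frame[col].astype(int)
    return SampleManifest(frame)


def write_manifest(manifest: SampleManifest, sink: Source) -> None:
    fh, close = _open(sink, "w")
    try:
        attrs = manifest.attributes
        fh.write("\t".join(["sample_id", "group", "is_pool", *attrs]) + "\n")
        for sid in manifest.sample_ids:
            row = manifest.frame.loc[sid]
            cells = [sid, str(row["group"]), str(int(row["is_pool"]))]
            cells += [str(int(row[a])) for a in attrs]
            fh.write("\t".join(cells) + "\n")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# Annotation table


@dataclass
class AnnotationTable:
    """miRNA -> disease-association rows joined onto screening candidates."""

    frame: pd.DataFrame  # columns: assay_id, disease, evidence

    def __post_init__(self):
        for col in ("assay_id", "disease"):
            if col not in self.frame.columns:
                raise FormatError(f"annotation table missing column {col!r}")
        if (self.frame["assay_id"].astype(str).str.len() == 0).any():
            raise FormatError("annotation table has an empty assay_id")


def read_annotation_table(source: Source, dialect: Dialect = Dialect()) -> AnnotationTable:
    fh, close = _open(source, "r")
    try:
        frame = pd.read_csv(fh, sep=dialect.separator, dtype=str).fillna("")
    finally:
        if close:
            fh.close()
    if "evidence" not in frame.columns:
        frame["evidence"] = ""
    return AnnotationTable(frame)


# ---------------------------------------------------------------------------
# Result tables


def _format_fc(fc: float) -> str:
    """Three significant digits, plain decimal where possible."""
    if fc == 0 or not math.isfinite(fc):
        return repr(fc)
    return f"{fc:.3g}"


CONTRAST_COLUMNS = ("assay_id", "contrast", "ddCT", "fold_change", "call")


def write_contrast_table(results: Sequence[ContrastResult], sink: Source) -> None:
    if not results:
        raise ArgumentError("no contrast results to write")
    fh, close = _open(sink, "w")
    try:
        fh.write("\t".join(CONTRAST_COLUMNS) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    [r.assay_id, r.contrast, repr(float(r.ddct)), _format_fc(r.fold_change), r.call.value]
                )
                + "\n"
            )
    finally:
        if close:
            fh.close()


def read_contrast_table(source: Source) -> list[ContrastResult]:
    fh, close = _open(source, "r")
    try:
        frame = pd.read_csv(fh, sep="\t", dtype=str)
    finally:
        if close:
            fh.close()
    return [
        ContrastResult(
            assay_id=row["assay_id"],
            contrast=row["contrast"],
            ddct=float(row["ddCT"]),
            fold_change=float(row["fold_change"]),
            call=Call(row["call"]),
        )
        for _, row in frame.iterrows()
    ]


def write_triple_table(records: Sequence[TripleDifferentialRecord], sink: Source) -> None:
    if not records:
        raise ArgumentError("no triple-differential records to write")
    contrasts = list(records[0].calls)
    fh, close = _open(sink, "w")
    try:
        cols = ["assay_id", *[f"call_{c}" for c in contrasts], "is_triple", "annotations"]
        fh.write("\t".join(cols) + "\n")
        for r in records:
            cells = [r.assay_id]
            cells += [r.calls[c].value for c in contrasts]
            cells.append(str(int(r.is_triple)))
            cells.append(";".join(r.annotations))
            fh.write("\t".join(cells) + "\n")
    finally:
        if close:
            fh.close()


def read_triple_table(source: Source) -> list[TripleDifferentialRecord]:
    fh, close = _open(source, "r")
    try:
        frame = pd.read_csv(fh, sep="\t", dtype=str).fillna("")
    finally:
        if close:
            fh.close()
    call_cols = [c for c in frame.columns if c.startswith("call_")]
    out = []
    for _, row in frame.iterrows():
        calls = {c[len("call_"):]: Call(row[c]) for c in call_cols}
        anns = [a for a in row["annotations"].split(";") if a]
        out.append(
            TripleDifferentialRecord(
                assay_id=row["assay_id"],
                calls=calls,
                is_triple=bool(int(row["is_triple"])),
                annotations=anns,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Heat-map export


def export_dct_heatmap_matrix(norm: NormalizedMatrix, sink: Source) -> tuple[float, float]:
    """Write the assay x sample dCT matrix as TSV with color-scale anchors.

    The anchors (observed min and max dCT) are recorded in comment lines
    preceding the header and returned.
    """
    if norm.values.empty:
        raise ArgumentError("empty normalized matrix")
    finite = norm.values.to_numpy(dtype=float)
    finite = finite[~np.isnan(finite)]
    if finite.size == 0:
        raise ArgumentError("normalized matrix has no dCT values")
    lo, hi = float(finite.min()), float(finite.max())
    fh, close = _open(sink, "w")
    try:
        fh.write(f"# color_anchor_min_dct\t{lo!r}\n")
        fh.write(f"# color_anchor_max_dct\t{hi!r}\n")
        fh.write("assay_id\t" + "\t".join(norm.samples) + "\n")
        for aid in norm.assay_ids:
            cells = []
            for s in norm.samples:
                v = norm.values.at[aid, s]
                cells.append(NON_DETECTED_TOKEN if pd.isna(v) else repr(float(v)))
            fh.write(aid + "\t" + "\t".join(cells) + "\n")
    finally:
        if close:
            fh.close()
    return lo, hi


def read_dct_heatmap_matrix(source: Source) -> tuple[NormalizedMatrix, tuple[float, float]]:
    """Round-trip reader for the heat-map export (tests and downstream use)."""
    fh, close = _open(source, "r")
    try:
        text = fh.read()
    finally:
        if close:
            fh.close()
    lines = text.splitlines()
    anchors = {}
    body = []
    for ln in lines:
        if ln.startswith("# "):
            key, val = ln[2:].split("\t")
            anchors[key] = float(val)
        elif ln:
            body.append(ln)
    header = body[0].split("\t")
    samples = header[1:]
    ids, rows = [], []
    for ln in body[1:]:
        fields = ln.split("\t")
        ids.append(fields[0])
        rows.append([np.nan if f == NON_DETECTED_TOKEN else float(f) for f in fields[1:]])
    values = pd.DataFrame(rows, index=ids, columns=samples, dtype=float)
    return (
        NormalizedMatrix(values),
        (anchors["color_anchor_min_dct"], anchors["color_anchor_max_dct"]),
    )
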