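"""Core domain types shared across the pipeline.

CT values live in pandas DataFrames with ``NaN`` standing for the
distinguished non-detected state ("Undetermined" on instrument exports).
All containers validate their invariants on construction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError, FormatError

#: The fixed three-level group factor of the study design.
GROUPS = ("LM", "PER", "M0")

#: Maximum cycle number a well can report.
CT_MAX = 40.0


class AssayRole(str, enum.Enum):
    TARGET = "TARGET"
    HOUSEKEEPER = "HOUSEKEEPER"
    NEGATIVE_CONTROL = "NEGATIVE_CONTROL"


class Call(str, enum.Enum):
    """Differential-expression call for one assay in one contrast."""

    UP = "UP"
    DOWN = "DOWN"
    NS = "NS"


@dataclass(frozen=True)
class AssayDefinition:
    """One panel assay: a miRNA target, a housekeeper, or the negative control."""

    assay_id: str
    role: AssayRole = AssayRole.TARGET


class CtMatrix:
    """Assay x sample grid of cycle-threshold values.

    Parameters
    ----------
    assays
        Ordered assay definitions; ids must be unique and match the
        value frame's index.
    values
        DataFrame indexed by assay_id with one column per sample.
        ``NaN`` encodes the non-detected state; numeric entries must lie
        in ``(0, 40]``.
    """

    def __init__(self, assays: Sequence[AssayDefinition], values: pd.DataFrame):
        assays = list(assays)
        ids = [a.assay_id for a in assays]
        if len(set(ids)) != len(ids):
            dup = _first_duplicate(ids)
            raise FormatError(f"duplicate assay name: {dup!r}")
        samples = list(values.columns)
        if len(set(samples)) != len(samples):
            dup = _first_duplicate(samples)
            raise FormatError(f"duplicate sample name: {dup!r}")
        if list(values.index) != ids:
            raise FormatError("assay definitions do not match value rows")
        arr = values.to_numpy(dtype=float)
        bad = np.where(~np.isnan(arr) & ((arr <= 0) | (arr > CT_MAX)))
        if bad[0].size:
            i, j = bad[0][0], bad[1][0]
            raise FormatError(
                f"CT outside (0, {CT_MAX:g}] at assay {ids[i]!r}, "
                f"sample {samples[j]!r}: {arr[i, j]!r}"
            )
        self.assays = assays
        self.values = values.astype(float)

    # -- accessors -----------------------------------------------------

    @property
    def assay_ids(self) -> list[str]:
        return [a.assay_id for a in self.assays]

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def roles(self) -> dict[str, AssayRole]:
        return {a.assay_id: a.role for a in self.assays}

    def ids_with_role(self, role: AssayRole) -> list[str]:
        return [a.assay_id for a in self.assays if a.role is role]

    def subset_assays(self, keep: Iterable[str]) -> "CtMatrix":
        keep = set(keep)
        assays = [a for a in self.assays if a.assay_id in keep]
        return CtMatrix(assays, self.values.loc[[a.assay_id for a in assays]])

    def subset_samples(self, keep: Sequence[str]) -> "CtMatrix":
        missing = [s for s in keep if s not in self.values.columns]
        if missing:
            raise ArgumentError(f"unknown sample(s): {missing}")
        return CtMatrix(self.assays, self.values[list(keep)])

    def equals(self, other: "CtMatrix") -> bool:
        return (
            self.assays == other.assays
            and self.samples == other.samples
            and self.values.equals(other.values)
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"CtMatrix({len(self.assays)} assays x {len(self.samples)} samples)"


class SampleManifest:
    """Per-sample group labels, pool flags, and binary clinical attributes.

    Wraps a DataFrame indexed by sample_id with mandatory columns
    ``group`` and ``is_pool``; every further column is a 0/1 attribute.
    """

    RESERVED = ("group", "is_pool")

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            dup = frame.index[frame.index.duplicated()][0]
            raise FormatError(f"duplicate sample_id: {dup!r}")
        for col in self.RESERVED:
            if col not in frame.columns:
                raise FormatError(f"manifest missing column {col!r}")
        bad_groups = sorted(set(frame["group"]) - set(GROUPS))
        if bad_groups:
            raise FormatError(f"unknown group label: {bad_groups[0]!r}")
        attrs = [c for c in frame.columns if c not in self.RESERVED]
        for col in attrs:
            vals = set(frame[col].astype(int)) - {0, 1}
            if vals:
                raise FormatError(f"attribute {col!r} has non-binary value {vals.pop()!r}")
        self.frame = frame[["group", "is_pool", *attrs]].copy()
        self.frame["is_pool"] = self.frame["is_pool"].astype(bool)
        for col in attrs:
            self.frame[col] = self.frame[col].astype(int)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def attributes(self) -> list[str]:
        return [c for c in self.frame.columns if c not in self.RESERVED]

    def group_of(self, sample_id: str) -> str:
        try:
            return str(self.frame.at[sample_id, "group"])
        except KeyError:
            raise ArgumentError(f"unknown sample: {sample_id!r}") from None

    def samples_in_group(self, group: str, *, pools: bool = False) -> list[str]:
        mask = (self.frame["group"] == group) & (self.frame["is_pool"] == pools)
        return list(self.frame.index[mask])

    def census(self, *, pools: bool = False) -> dict[str, int]:
        return {g: len(self.samples_in_group(g, pools=pools)) for g in GROUPS}

    def attribute_value(self, sample_id: str, attribute: str) -> int:
        if attribute not in self.frame.columns:
            raise ArgumentError(f"attribute {attribute!r} missing for sample {sample_id!r}")
        val = self.frame.at[sample_id, attribute]
        if pd.isna(val):
            raise ArgumentError(f"attribute {attribute!r} missing for sample {sample_id!r}")
        return int(val)

    def equals(self, other: "SampleManifest") -> bool:
        return self.frame.equals(other.frame)


@dataclass
class NormalizedMatrix:
    """Per-sample dCT values for detected TARGET assays.

    ``values`` is indexed by assay_id (targets only) with one column per
    sample; ``NaN`` marks a target that was non-detected in that sample.
    ``housekeeper_aggregation`` records the normalization provenance.
    """

    values: pd.DataFrame
    housekeeper_aggregation: str = "MEAN_CT"

    @property
    def assay_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class ContrastResult:
    """ddCT, fold change, and call for one assay in one group contrast."""

    assay_id: str
    contrast: str
    ddct: float
    fold_change: float
    call: Call


@dataclass
class TripleDifferentialRecord:
    """Per-contrast calls for one assay plus triple-differential membership."""

    assay_id: str
    calls: dict[str, Call]
    is_triple: bool
    annotations: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 count table: rows are groups, columns attribute positive/negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        counts = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in counts):
            raise ArgumentError(f"counts must be non-negative integers, got {counts}")
        if sum(counts) == 0:
            raise ArgumentError("contingency table total must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass
class GroupComparison:
    """Two-group comparison summary for one assay."""

    assay_id: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    fold_change: float
    t: float
    df: int
    p: float
    significant: bool
    scale: str = "dct"
    degenerate: bool = False


def _first_duplicate(items: Sequence) -> object:
    seen: set = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def default_assay_roles(
    assay_ids: Sequence[str],
    housekeeper_ids: Iterable[str],
    negative_control_id: str,
) -> list[AssayDefinition]:
    """Assign roles by name: configured housekeepers, one negative control,
    everything else a target."""
    hk = set(housekeeper_ids)
    out = []
    for aid in assay_ids:
        if aid in hk:
            role = AssayRole.HOUSEKEEPER
        elif aid == negative_control_id:
            role = AssayRole.NEGATIVE_CONTROL
        else:
            role = AssayRole.TARGET
        out.append(AssayDefinition(aid, role))
    return out
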