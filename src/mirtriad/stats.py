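"""Cohort-level inferential statistics.

Two declared procedures: the two-sided Fisher exact test on 2x2
clinico-pathological tables and the pooled-variance (Student's) two-
sample t-test on per-sample expression, plus the whole-cohort
single-assay validation built on them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ArgumentError
from .types import ContingencyTable2x2, GroupComparison, NormalizedMatrix, SampleManifest

log = logging.getLogger(__name__)


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Uses the standard two-sided convention: the sum of hypergeometric
    probabilities of all margin-preserving tables no more probable than
    the observed one. The tail sum is accumulated in exact integer
    arithmetic (probabilities share the common denominator C(n, c1)), so
    tied tables are handled without floating-point tolerance games. A
    table with an empty row or column margin carries no information;
    p = 1 is returned with a log note.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        log.info("degenerate 2x2 table with a zero margin: %s; p = 1", [[a, b], [c, d]])
        return 1.0
    # numerator of P(k) over the common denominator C(n, c1)
    observed = math.comb(r1, a) * math.comb(r2, c)
    total = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = math.comb(r1, k) * math.comb(r2, c1 - k)
        if w <= observed:
            total += w
    return total / math.comb(n, c1)


def students_t_two_sample(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t-test.

    Returns (t, df, two-sided p) with df = nA + nB - 2. Degenerate
    zero-variance inputs give p = 1 for equal means and p = 0 (flagged
    in the log) for unequal means.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ArgumentError(f"need >= 2 values per group, got {a.size} and {b.size}")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ArgumentError("non-finite values in t-test input")
    df = a.size + b.size - 2
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    if pooled_var == 0.0:
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        log.warning("degenerate t-test: zero pooled variance with unequal means")
        t = math.inf if a.mean() > b.mean() else -math.inf
        return t, df, 0.0
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), df, float(res.pvalue)


def whole_cohort_validation(
    per_sample_dct: NormalizedMatrix,
    manifest: SampleManifest,
    assays: Sequence[str],
    alpha: float = 0.05,
    *,
    group_a: str = "PER",
    group_b: str = "LM",
    test_scale: Literal["dct", "linear"] = "dct",
) -> list[GroupComparison]:
    """Per-assay two-group validation on the full (unpooled) cohort.

    Fold change is the ratio of group mean linear expressions
    (mean 2^-dCT in ``group_a`` over ``group_b``); means and SEMs are
    reported on the linear scale. The t-test runs on dCT values by
    default (``test_scale='linear'`` tests 2^-dCT instead). Assays with
    fewer than two usable samples in either group are skipped with a
    logged reason.
    """
    out: list[GroupComparison] = []
    samples_a = manifest.samples_in_group(group_a)
    samples_b = manifest.samples_in_group(group_b)
    for assay_id in assays:
        if assay_id not in per_sample_dct.assay_ids:
            log.warning("validation: assay %r absent from matrix, skipped", assay_id)
            continue
        row = per_sample_dct.values.loc[assay_id]
        dct_a = row[[s for s in samples_a if s in row.index]].dropna()
        dct_b = row[[s for s in samples_b if s in row.index]].dropna()
        if len(dct_a) < 2 or len(dct_b) < 2:
            log.warning(
                "validation: assay %r has %d/%d usable samples in %s/%s, skipped",
                assay_id, len(dct_a), len(dct_b), group_a, group_b,
            )
            continue
        lin_a = 2.0 ** (-dct_a)
        lin_b = 2.0 ** (-dct_b)
        if test_scale == "linear":
            t, df, p = students_t_two_sample(lin_a, lin_b)
        else:
            t, df, p = students_t_two_sample(dct_a, dct_b)
        out.append(
            GroupComparison(
                assay_id=assay_id,
                group_a=group_a,
                group_b=group_b,
                n_a=len(dct_a),
                n_b=len(dct_b),
                mean_a=float(lin_a.mean()),
                mean_b=float(lin_b.mean()),
                sem_a=float(lin_a.sem()),
                sem_b=float(lin_b.sem()),
                fold_change=float(lin_a.mean() / lin_b.mean()),
                t=t,
                df=df,
                p=p,
                significant=p < alpha,
                scale=test_scale,
                degenerate=not math.isfinite(t),
            )
        )
    return out


def attribute_association(
    manifest: SampleManifest,
    attribute: str,
    group_a: str,
    group_b: str,
) -> tuple[ContingencyTable2x2, float]:
    """Build the 2x2 attribute-by-group table and apply Fisher's exact test.

    Rows are the two groups, columns attribute positive/negative.
    """
    counts = []
    for g in (group_a, group_b):
        samples = manifest.samples_in_group(g)
        if not samples:
            raise ArgumentError(f"no samples in group {g!r}")
        pos = sum(manifest.attribute_value(s, attribute) for s in samples)
        counts.append((pos, len(samples) - pos))
    table = ContingencyTable2x2(counts[0][0], counts[0][1], counts[1][0], counts[1][1])
    return table, fisher_exact_two_sided(table)


def comparisons_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    """Flatten validation results into the TSV-ready column layout."""
    return pd.DataFrame(
        [
            {
                "assay_id": c.assay_id,
                "group_a": c.group_a,
                "group_b": c.group_b,
                "n_a": c.n_a,
                "n_b": c.n_b,
                "mean_a": c.mean_a,
                "mean_b": c.mean_b,
                "sem_a": c.sem_a,
                "sem_b": c.sem_b,
                "fold_change": c.fold_change,
                "t": c.t,
                "df": c.df,
                "p": c.p,
                "significant": c.significant,
                "scale": c.scale,
            }
            for c in comparisons
        ]
    )
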