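"""Detection filtering and the 2^-ddCT relative-quantification chain.

The chain is: strict CT-threshold detection filter on target assays,
housekeeper aggregation per sample, dCT = target CT - housekeeper CT,
ddCT = dCT(sample of interest) - dCT(reference sample), and fold change
2^-ddCT.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .errors import ArgumentError, ConfigurationError, NormalizationError
from .types import AssayRole, CtMatrix, NormalizedMatrix

log = logging.getLogger(__name__)


class DetectionRule(str, enum.Enum):
    """Whether detection must hold in every scoped sample or at least one."""

    ALL_SAMPLES = "ALL_SAMPLES"
    ANY_SAMPLE = "ANY_SAMPLE"


@dataclass(frozen=True)
class QuantConfig:
    """Quantification settings.

    ``detection_ct_threshold`` is a strict bound: an assay is detected in
    a sample iff its CT is strictly below the threshold. Housekeeper
    aggregation is either ``"MEAN_CT"`` (arithmetic mean CT of the
    detected housekeepers, i.e. geometric mean of their linear
    abundances) or ``"SINGLE:<assay_id>"``.
    """

    detection_ct_threshold: float = 30.0
    detection_rule: DetectionRule = DetectionRule.ALL_SAMPLES
    housekeeper_aggregation: str = "MEAN_CT"

    def __post_init__(self):
        if not (0 < self.detection_ct_threshold <= 40):
            raise ConfigurationError(
                f"detection_ct_threshold must be in (0, 40], got {self.detection_ct_threshold}"
            )
        if self.housekeeper_aggregation != "MEAN_CT" and not self.housekeeper_aggregation.startswith(
            "SINGLE:"
        ):
            raise ConfigurationError(
                "housekeeper_aggregation must be 'MEAN_CT' or 'SINGLE:<assay_id>', "
                f"got {self.housekeeper_aggregation!r}"
            )


def detection_filter(
    ct: CtMatrix,
    config: QuantConfig,
    samples_in_scope: Sequence[str],
) -> tuple[list[str], CtMatrix]:
    """Select target assays detected below the CT threshold.

    A target is detected in a sample iff its CT is strictly below
    ``config.detection_ct_threshold``; non-detected wells fail. Under
    ``ALL_SAMPLES`` the target must be detected in every scoped sample,
    under ``ANY_SAMPLE`` in at least one. Housekeepers and the negative
    control are never retained as targets but are preserved in the
    filtered matrix for downstream normalization.

    Returns
    -------
    (retained, filtered)
        ``retained`` — target assay ids passing the filter, in input
        order; ``filtered`` — the matrix restricted to those targets
        plus housekeeper assays.
    """
    if not samples_in_scope:
        raise ArgumentError("samples_in_scope must be non-empty")
    missing = [s for s in samples_in_scope if s not in ct.samples]
    if missing:
        raise ArgumentError(f"scoped sample(s) not in matrix: {missing}")

    scoped = ct.values[list(samples_in_scope)]
    detected = scoped < config.detection_ct_threshold  # NaN compares False
    if config.detection_rule is DetectionRule.ALL_SAMPLES:
        ok = detected.all(axis=1)
    else:
        ok = detected.any(axis=1)
    roles = ct.roles
    retained = [aid for aid in ct.assay_ids if roles[aid] is AssayRole.TARGET and ok[aid]]
    keep = set(retained) | set(ct.ids_with_role(AssayRole.HOUSEKEEPER))
    log.info(
        "detection filter (CT < %g, %s): retained %d of %d targets",
        config.detection_ct_threshold,
        config.detection_rule.value,
        len(retained),
        len(ct.ids_with_role(AssayRole.TARGET)),
    )
    return retained, ct.subset_assays(keep)


def aggregate_housekeepers(ct: CtMatrix, sample: str, config: QuantConfig = QuantConfig()) -> float:
    """Aggregate housekeeper CTs for one sample.

    ``MEAN_CT`` averages the CTs of the housekeepers detected in the
    sample (equivalently, the geometric mean of their linear
    abundances). ``SINGLE:<id>`` returns that assay's CT.
    """
    if sample not in ct.samples:
        raise ArgumentError(f"unknown sample: {sample!r}")
    if config.housekeeper_aggregation.startswith("SINGLE:"):
        hk_id = config.housekeeper_aggregation.split(":", 1)[1]
        if hk_id not in ct.assay_ids:
            raise NormalizationError(f"housekeeper {hk_id!r} absent from matrix")
        val = ct.values.at[hk_id, sample]
        if pd.isna(val):
            raise NormalizationError(f"housekeeper {hk_id!r} non-detected in sample {sample!r}")
        return float(val)
    hk_ids = ct.ids_with_role(AssayRole.HOUSEKEEPER)
    vals = ct.values.loc[hk_ids, sample].dropna() if hk_ids else pd.Series(dtype=float)
    if vals.empty:
        raise NormalizationError(f"no detected housekeeper in sample {sample!r}")
    return float(vals.mean())


def delta_ct(ct: CtMatrix, config: QuantConfig = QuantConfig()) -> NormalizedMatrix:
    """Compute dCT = target CT - housekeeper aggregate, per (target, sample).

    Non-detected targets propagate as missing dCT values.
    """
    hk = {s: aggregate_housekeepers(ct, s, config) for s in ct.samples}
    target_ids = ct.ids_with_role(AssayRole.TARGET)
    values = ct.values.loc[target_ids].copy()
    for s in ct.samples:
        values[s] = values[s] - hk[s]
    return NormalizedMatrix(values, housekeeper_aggregation=config.housekeeper_aggregation)


def delta_delta_ct(
    norm: NormalizedMatrix, target_sample: str, reference_sample: str
) -> pd.Series:
    """Per-assay ddCT = dCT(target sample) - dCT(reference sample).

    Assays missing a dCT in either sample are omitted (with a log note).
    """
    for s in (target_sample, reference_sample):
        if s not in norm.samples:
            raise ArgumentError(f"unknown sample: {s!r}")
    ddct = norm.values[target_sample] - norm.values[reference_sample]
    dropped = ddct.index[ddct.isna()]
    if len(dropped):
        log.info(
            "ddCT %s vs %s: omitting %d assay(s) missing in one sample: %s",
            target_sample,
            reference_sample,
            len(dropped),
            ", ".join(dropped[:5]),
        )
    return ddct.dropna()


def fold_change(ddct: Union[float, np.ndarray, pd.Series]):
    """Relative expression 2^-ddCT."""
    if isinstance(ddct, (pd.Series, np.ndarray)):
        return 2.0 ** (-ddct)
    return 2.0 ** (-float(ddct))
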