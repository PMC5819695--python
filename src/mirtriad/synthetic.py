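"""Synthetic CT-data generator emulating a pooled miRNA-panel study.

Generates a 754-target + 4-control panel across three patient groups
(LM, PER, M0) with planted group-specific log2 fold changes, Gaussian CT
noise, a detection ceiling, and numeric emulation of physical pooling.
The planted effects serve as ground truth for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ArgumentError, ConfigurationError
from .types import (
    CtMatrix,
    SampleManifest,
    default_assay_roles,
)

# Housekeepers sit in a narrow well-expressed band, shared across groups.
_HK_BASELINE_RANGE = (18.0, 22.0)


@dataclass(frozen=True)
class PlantedEffect:
    """Ground-truth effect: one assay shifted by ``log2fc`` in one group
    relative to the M0 baseline (CT drops one cycle per doubling)."""

    assay_id: str
    group: str
    log2fc: float


@dataclass
class SimulationConfig:
    n_targets: int = 754
    housekeeper_ids: tuple[str, ...] = ("RNU44", "RNU48", "U6")
    negative_control_id: str = "ath-miR-159a"
    group_sizes: dict[str, int] = field(default_factory=lambda: {"LM": 10, "PER": 10, "M0": 3})
    pool_size: int = 3
    baseline_ct_range: tuple[float, float] = (18.0, 38.0)
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    noise_sd: float = 0.25
    detection_ceiling: Optional[float] = 35.0  # None disables the ceiling
    classifier_positive_prob: dict[str, float] = field(
        default_factory=lambda: {"LM": 1.0, "PER": 0.2, "M0": 0.0}
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_targets <= 0:
            raise ConfigurationError(f"n_targets must be positive, got {self.n_targets}")
        if self.pool_size <= 0:
            raise ConfigurationError(f"pool_size must be positive, got {self.pool_size}")
        for g, n in self.group_sizes.items():
            if n <= 0:
                raise ConfigurationError(f"group_sizes[{g!r}] must be positive, got {n}")
            if self.pool_size > n:
                raise ConfigurationError(
                    f"pool_size {self.pool_size} exceeds group_sizes[{g!r}] = {n}"
                )
        lo, hi = self.baseline_ct_range
        if not lo < hi:
            raise ConfigurationError(f"baseline_ct_range low must be < high, got {lo}, {hi}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for g, p in self.classifier_positive_prob.items():
            if not 0 <= p <= 1:
                raise ConfigurationError(
                    f"classifier_positive_prob[{g!r}] must be in [0, 1], got {p}"
                )
        controls = set(self.housekeeper_ids) | {self.negative_control_id}
        for eff in self.planted_effects:
            if eff.assay_id in controls:
                raise ConfigurationError(
                    f"planted_effects: {eff.assay_id!r} is a control assay, not a target"
                )
            if eff.group not in self.group_sizes:
                raise ConfigurationError(
                    f"planted_effects: unknown group {eff.group!r} for {eff.assay_id!r}"
                )

    @property
    def target_ids(self) -> list[str]:
        return [f"hsa-miR-sim-{i:04d}" for i in range(1, self.n_targets + 1)]


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[CtMatrix, SampleManifest, list[PlantedEffect]]:
    """Draw a per-patient CT matrix, a manifest, and the planted truth.

    Generative model
    ----------------
    Each target gets a baseline CT drawn uniformly over
    ``baseline_ct_range``, shared across patients. A patient's CT is
    baseline minus the planted log2 fold change of their group (zero if
    none) plus Gaussian(0, ``noise_sd``) noise. Housekeepers use a fixed
    per-assay baseline with the same noise and no group effect. The
    negative control never amplifies. Any drawn CT above
    ``detection_ceiling`` is stored as non-detected. Classifier status
    is independent Bernoulli per patient with the group's probability.
    Identical config (including seed) gives bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    target_ids = config.target_ids
    lo, hi = config.baseline_ct_range
    baselines = rng.uniform(lo, hi, size=config.n_targets)
    hk_baselines = rng.uniform(*_HK_BASELINE_RANGE, size=len(config.housekeeper_ids))

    effect: dict[tuple[str, str], float] = {
        (e.assay_id, e.group): e.log2fc for e in config.planted_effects
    }
    unknown = [a for a, _ in effect if a not in set(target_ids)]
    if unknown:
        raise ConfigurationError(f"planted_effects: unknown assay id(s) {unknown}")

    sample_ids: list[str] = []
    groups: list[str] = []
    for g in config.group_sizes:  # insertion order of the mapping
        for i in range(1, config.group_sizes[g] + 1):
            sample_ids.append(f"{g}-{i:02d}")
            groups.append(g)

    n_samples = len(sample_ids)
    target_block = np.empty((config.n_targets, n_samples))
    for j, g in enumerate(groups):
        shift = np.array([effect.get((aid, g), 0.0) for aid in target_ids])
        target_block[:, j] = baselines - shift
    target_block += rng.normal(0.0, config.noise_sd, size=target_block.shape)

    hk_block = hk_baselines[:, None] + rng.normal(
        0.0, config.noise_sd, size=(len(config.housekeeper_ids), n_samples)
    )

    if config.detection_ceiling is not None:
        target_block[target_block > config.detection_ceiling] = np.nan
        hk_block[hk_block > config.detection_ceiling] = np.nan
    # the panel never reports cycles beyond 40 regardless of ceiling
    target_block[target_block > 40.0] = np.nan
    hk_block[hk_block > 40.0] = np.nan

    neg_block = np.full((1, n_samples), np.nan)

    all_ids = target_ids + list(config.housekeeper_ids) + [config.negative_control_id]
    values = pd.DataFrame(
        np.vstack([target_block, hk_block, neg_block]),
        index=all_ids,
        columns=sample_ids,
        dtype=float,
    )
    assays = default_assay_roles(all_ids, config.housekeeper_ids, config.negative_control_id)
    ct = CtMatrix(assays, values)

    classifier = [
        int(rng.random() < config.classifier_positive_prob.get(g, 0.0)) for g in groups
    ]
    manifest = SampleManifest(
        pd.DataFrame(
            {
                "group": groups,
                "is_pool": [False] * n_samples,
                "classifier_positive": classifier,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    return ct, manifest, list(config.planted_effects)


def pool_patients(
    ct: CtMatrix,
    manifest: SampleManifest,
    pool_size: int = 3,
    seed: int = 0,
) -> tuple[CtMatrix, SampleManifest, dict[str, list[str]]]:
    """Numerically pool ``pool_size`` patients per group into one sample.

    Pooling happens in linear abundance space: the pooled abundance is
    the arithmetic mean of 2^-CT over the pooled patients and the pooled
    CT is -log2 of that mean. A non-detected well contributes zero
    abundance; if every pooled patient is non-detected the pooled value
    is non-detected. Patient selection per group is reproducible from
    ``seed``. Pooled columns are named by their group label.

    Returns the pooled matrix, a pool manifest, and the group -> chosen
    patient mapping.
    """
    rng = np.random.default_rng(seed)
    groups = sorted(set(manifest.frame["group"]), key=list(manifest.frame["group"]).index)
    chosen: dict[str, list[str]] = {}
    pooled_cols = {}
    for g in groups:
        members = manifest.samples_in_group(g)
        members = [s for s in members if s in ct.samples]
        if len(members) < pool_size:
            raise ArgumentError(
                f"group {g!r} has {len(members)} patients with CT data, needs {pool_size}"
            )
        picked = sorted(rng.choice(members, size=pool_size, replace=False).tolist())
        chosen[g] = picked
        sub = ct.values[picked]
        abundance = (2.0 ** (-sub)).fillna(0.0).mean(axis=1)
        with np.errstate(divide="ignore"):
            pooled = -np.log2(abundance)
        pooled[abundance == 0.0] = np.nan
        pooled_cols[g] = pooled
    pooled_values = pd.DataFrame(pooled_cols, index=ct.values.index)
    pooled_ct = CtMatrix(ct.assays, pooled_values)
    pool_manifest = SampleManifest(
        pd.DataFrame(
            {"group": groups, "is_pool": [True] * len(groups)},
            index=pd.Index(groups, name="sample_id"),
        )
    )
    return pooled_ct, pool_manifest, chosen


# ---------------------------------------------------------------------------
# Truth-table serialization (TSV: assay_id, group, log2fc)


def write_truth_table(truth: Sequence[PlantedEffect], sink: Union[str, IO[str]]) -> None:
    close = False
    if not hasattr(sink, "write"):
        sink = open(sink, "w", newline="")
        close = True
    try:
        sink.write("assay_id\tgroup\tlog2fc\n")
        for e in truth:
            sink.write(f"{e.assay_id}\t{e.group}\t{e.log2fc!r}\n")
    finally:
        if close:
            sink.close()


def read_truth_table(source: Union[str, IO[str]]) -> list[PlantedEffect]:
    close = False
    if not hasattr(source, "read"):
        source = open(source, "r", newline="")
        close = True
    try:
        frame = pd.read_csv(source, sep="\t", dtype={"assay_id": str, "group": str})
    finally:
        if close:
            source.close()
    return [
        PlantedEffect(row["assay_id"], row["group"], float(row["log2fc"]))
        for _, row in frame.iterrows()
    ]
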