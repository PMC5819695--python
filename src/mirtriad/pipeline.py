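"""End-to-end orchestration: simulate/read -> pool -> filter -> normalize
-> contrast -> intersect -> annotate -> validate -> report.

Every run is driven by a :class:`RunConfig` (YAML file plus flag
overrides); identical config and seed yield byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import io as qio
from .errors import ConfigurationError, MirtriadError
from .quantify import DetectionRule, QuantConfig, delta_ct, detection_filter
from .screen import (
    ScreenConfig,
    annotate_candidates,
    call_contrast,
    contrast_label,
    triple_differential,
)
from .stats import comparisons_to_frame, whole_cohort_validation
from .synthetic import (
    PlantedEffect,
    SimulationConfig,
    pool_patients,
    simulate_cohort,
    write_truth_table,
)
from .types import Call, CtMatrix, SampleManifest

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    out_dir: Path
    ct_table: Optional[Path] = None
    manifest: Optional[Path] = None
    annotation: Optional[Path] = None
    simulate: Optional[SimulationConfig] = None
    quant: QuantConfig = field(default_factory=QuantConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    pool_size: int = 3
    alpha: float = 0.05
    seed: Optional[int] = None
    log_level: str = "INFO"
    suffix_tolerant_annotation: bool = False
    validation_test_scale: str = "dct"

    def __post_init__(self):
        self.out_dir = Path(self.out_dir)
        if self.simulate is not None and self.seed is None:
            raise ConfigurationError("seed is mandatory in simulate mode")
        if self.simulate is None and (self.ct_table is None or self.manifest is None):
            raise ConfigurationError(
                "ct_table and manifest paths are required unless simulate mode is on"
            )

    def echo(self) -> dict:
        d = {
            "out_dir": str(self.out_dir),
            "ct_table": str(self.ct_table) if self.ct_table else None,
            "manifest": str(self.manifest) if self.manifest else None,
            "annotation": str(self.annotation) if self.annotation else None,
            "simulate": self.simulate is not None,
            "quant": {
                "detection_ct_threshold": self.quant.detection_ct_threshold,
                "detection_rule": self.quant.detection_rule.value,
                "housekeeper_aggregation": self.quant.housekeeper_aggregation,
            },
            "screen": {
                "up_threshold": self.screen.up_threshold,
                "down_threshold": self.screen.down_threshold,
                "contrasts": [list(c) for c in self.screen.contrasts],
            },
            "pool_size": self.pool_size,
            "alpha": self.alpha,
            "seed": self.seed,
        }
        return d


@dataclass
class RunReport:
    """Counts and summaries for one screening run."""

    n_assays_total: int
    n_detected: int
    detected_fraction: float
    contrast_counts: dict[str, dict[str, int]]
    n_triple: int
    n_annotated: int
    validation_summary: dict
    config_echo: dict
    seed: Optional[int]

    def validate(self) -> None:
        if self.n_detected > self.n_assays_total:
            raise MirtriadError("report invariant violated: n_detected > n_assays_total")
        for label, counts in self.contrast_counts.items():
            if self.n_triple > counts["UP"] + counts["DOWN"]:
                raise MirtriadError(
                    f"report invariant violated: n_triple exceeds differential count of {label}"
                )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"

    def to_text(self) -> str:
        lines = [
            "mirtriad screening report",
            f"  seed: {self.seed}",
            f"  targets on panel: {self.n_assays_total}",
            f"  detected (CT filter): {self.n_detected} "
            f"({100 * self.detected_fraction:.1f}%)",
        ]
        for label, counts in self.contrast_counts.items():
            lines.append(
                f"  {label}: UP {counts['UP']}, DOWN {counts['DOWN']}, NS {counts['NS']}"
            )
        lines.append(f"  triple-differential: {self.n_triple}")
        lines.append(f"  annotated candidates: {self.n_annotated}")
        if self.validation_summary:
            lines.append(f"  validation: {json.dumps(self.validation_summary, sort_keys=True)}")
        return "\n".join(lines) + "\n"


def run_config_from_mapping(raw: dict, **overrides) -> RunConfig:
    """Build a RunConfig from a parsed YAML mapping; keyword overrides win.

    Recognized override keys: seed, out_dir, ct_threshold, detection_rule,
    up_fc, down_fc, alpha.
    """
    raw = dict(raw or {})
    sim_raw = raw.get("simulate")
    sim = None
    if sim_raw:
        sim_raw = dict(sim_raw)
        enabled = sim_raw.pop("enabled", True)
        if enabled:
            effects = [
                PlantedEffect(e["assay_id"], e["group"], float(e["log2fc"]))
                for e in sim_raw.pop("planted_effects", [])
            ]
            seed = overrides.get("seed", raw.get("seed"))
            if seed is None:
                raise ConfigurationError("seed is mandatory in simulate mode")
            kwargs = {}
            for key in (
                "n_targets", "housekeeper_ids", "negative_control_id", "group_sizes",
                "pool_size", "baseline_ct_range", "noise_sd", "detection_ceiling",
                "classifier_positive_prob",
            ):
                if key in sim_raw:
                    kwargs[key] = sim_raw[key]
            if "housekeeper_ids" in kwargs:
                kwargs["housekeeper_ids"] = tuple(kwargs["housekeeper_ids"])
            if "baseline_ct_range" in kwargs:
                kwargs["baseline_ct_range"] = tuple(kwargs["baseline_ct_range"])
            sim = SimulationConfig(planted_effects=effects, seed=int(seed), **kwargs)

    quant_raw = dict(raw.get("quant", {}))
    quant = QuantConfig(
        detection_ct_threshold=float(
            overrides.get("ct_threshold") or quant_raw.get("ct_threshold", 30.0)
        ),
        detection_rule=DetectionRule(
            overrides.get("detection_rule") or quant_raw.get("detection_rule", "ALL_SAMPLES")
        ),
        housekeeper_aggregation=quant_raw.get("housekeeper_aggregation", "MEAN_CT"),
    )
    screen_raw = dict(raw.get("screen", {}))
    contrasts = tuple(
        tuple(c) for c in screen_raw.get("contrasts", [["PER", "LM"], ["PER", "M0"], ["LM", "M0"]])
    )
    screen = ScreenConfig(
        up_threshold=float(overrides.get("up_fc") or screen_raw.get("up_fc", 2.00)),
        down_threshold=float(overrides.get("down_fc") or screen_raw.get("down_fc", 0.500)),
        contrasts=contrasts,
    )
    inputs = dict(raw.get("inputs", {}))
    seed = overrides.get("seed", raw.get("seed"))
    return RunConfig(
        out_dir=Path(overrides.get("out_dir") or raw.get("out_dir", "mirtriad_out")),
        ct_table=Path(inputs["ct_table"]) if inputs.get("ct_table") else None,
        manifest=Path(inputs["manifest"]) if inputs.get("manifest") else None,
        annotation=Path(inputs["annotation"]) if inputs.get("annotation") else None,
        simulate=sim,
        quant=quant,
        screen=screen,
        pool_size=int(raw.get("pool_size", 3)),
        alpha=float(overrides.get("alpha") or raw.get("alpha", 0.05)),
        seed=int(seed) if seed is not None else None,
        log_level=str(raw.get("log_level", "INFO")),
        suffix_tolerant_annotation=bool(raw.get("suffix_tolerant_annotation", False)),
        validation_test_scale=str(raw.get("validation_test_scale", "dct")),
    )


def _load_inputs(config: RunConfig) -> tuple[CtMatrix, SampleManifest, list[PlantedEffect]]:
    if config.simulate is not None:
        sim = config.simulate
        ct, manifest, truth = simulate_cohort(sim)
        return ct, manifest, truth
    ct = qio.read_ct_table(str(config.ct_table))
    manifest = qio.read_manifest(str(config.manifest))
    return ct, manifest, []


def run_screen(config: RunConfig) -> RunReport:
    """Execute the full screening cascade and write all result files.

    Outputs under ``config.out_dir``: per-patient CT table, manifests,
    truth table (simulate mode), pooled CT table, per-contrast result
    tables, the triple-differential table, the dCT heat-map matrix, and
    the run report as JSON and text. Any stage failure aborts with the
    stage name and removes this run's partial outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def sink(name: str) -> str:
        p = out / name
        written.append(p)
        return str(p)

    stage = "load"
    try:
        ct, manifest, truth = _load_inputs(config)
        log.info("loaded %d assays x %d samples", len(ct.assays), len(ct.samples))
        if config.simulate is not None:
            qio.write_ct_table(ct, sink("ct_patients.tsv"))
            qio.write_manifest(manifest, sink("manifest_patients.tsv"))
            write_truth_table(truth, sink("truth.tsv"))

        stage = "pool"
        pooled, pool_manifest, chosen = pool_patients(
            ct, manifest, config.pool_size, seed=config.seed or 0
        )
        qio.write_ct_table(pooled, sink("ct_pooled.tsv"))
        qio.write_manifest(pool_manifest, sink("manifest_pools.tsv"))
        log.info("pooled %d patients per group: %s", config.pool_size, chosen)

        stage = "detection_filter"
        retained, filtered = detection_filter(pooled, config.quant, pooled.samples)

        stage = "normalize"
        norm = delta_ct(filtered, config.quant)

        stage = "contrast"
        per_contrast = []
        contrast_counts: dict[str, dict[str, int]] = {}
        for group, reference in config.screen.contrasts:
            results = call_contrast(norm, (group, reference), config.screen)
            per_contrast.append(results)
            label = contrast_label(group, reference)
            contrast_counts[label] = {
                call.value: sum(r.call is call for r in results) for call in Call
            }
            qio.write_contrast_table(results, sink(f"contrast_{label}.tsv"))

        stage = "intersect"
        records = triple_differential(per_contrast)

        stage = "annotate"
        n_annotated = 0
        if config.annotation is not None:
            annotation = qio.read_annotation_table(str(config.annotation))
            records = annotate_candidates(
                records, annotation, suffix_tolerant=config.suffix_tolerant_annotation
            )
            n_annotated = sum(bool(r.annotations) for r in records if r.is_triple)
        qio.write_triple_table(records, sink("triple_differential.tsv"))

        stage = "heatmap"
        triple_ids = [r.assay_id for r in records if r.is_triple]
        if triple_ids:
            from .types import NormalizedMatrix

            sub = NormalizedMatrix(
                norm.values.loc[triple_ids], housekeeper_aggregation=norm.housekeeper_aggregation
            )
            qio.export_dct_heatmap_matrix(sub, sink("dct_heatmap.tsv"))

        stage = "report"
        n_targets = sum(1 for a in ct.assays if a.role.value == "TARGET")
        report = RunReport(
            n_assays_total=n_targets,
            n_detected=len(retained),
            detected_fraction=len(retained) / n_targets if n_targets else 0.0,
            contrast_counts=contrast_counts,
            n_triple=sum(r.is_triple for r in records),
            n_annotated=n_annotated,
            validation_summary={},
            config_echo=config.echo(),
            seed=config.seed,
        )
        report.validate()
        Path(sink("report.json")).write_text(report.to_json())
        Path(sink("report.txt")).write_text(report.to_text())
        return report
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        if isinstance(exc, MirtriadError):
            raise type(exc)(f"stage {stage!r} failed: {exc}") from exc
        raise MirtriadError(f"stage {stage!r} failed: {exc}") from exc


def run_validation(config: RunConfig, assays: Sequence[str]) -> Path:
    """Whole-cohort validation of named assays; writes validation.tsv.

    Assays absent from the matrix are listed as missing in the output
    and the run continues. An empty assay list yields an empty table.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ct, manifest, _ = _load_inputs(config)
    norm = delta_ct(ct, config.quant)
    present = [a for a in assays if a in norm.assay_ids]
    missing = [a for a in assays if a not in norm.assay_ids]
    comparisons = whole_cohort_validation(
        norm,
        manifest,
        present,
        alpha=config.alpha,
        test_scale=config.validation_test_scale,  # type: ignore[arg-type]
    )
    frame = comparisons_to_frame(comparisons)
    path = out / "validation.tsv"
    with open(path, "w", newline="") as fh:
        if frame.empty:
            fh.write(
                "assay_id\tgroup_a\tgroup_b\tn_a\tn_b\tmean_a\tmean_b\tsem_a\tsem_b\t"
                "fold_change\tt\tdf\tp\tsignificant\tscale\n"
            )
        else:
            frame.to_csv(fh, sep="\t", index=False)
        for a in missing:
            fh.write(f"{a}\tMISSING\t\t\t\t\t\t\t\t\t\t\t\t\t\n")
    if missing:
        log.warning("validation: missing assay(s): %s", ", ".join(missing))
    return path
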