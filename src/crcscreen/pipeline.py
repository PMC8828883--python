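"""End-to-end orchestration: simulate -> mask -> segment -> features ->
train -> predict -> evaluate.

A single YAML config drives every stage; one global seed deterministically
derives per-stage seeds, so any stage can be re-run in isolation and two
identical runs produce byte-identical reports. The default cohort shape
mirrors a screening study: 105 resection-like training slides (full-size
tissue) and 150 biopsy-like validation slides (smaller tissue), disjoint by
construction.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classifier import (
    ClassifierConfig,
    cross_validate_select,
    fit_final,
    predict_risk,
    save_model,
)
from .errors import ConfigError, CrcScreenError
from .evaluation import evaluate
from .features import FeatureConfig, features_table
from .segmentation import derive_rng, oracle_segment
from .synthetic import SyntheticConfig, iter_slides
from .tiling import compute_tissue_mask
from .types import RiskLabel

log = logging.getLogger("crcscreen")


def stage_seed(global_seed: int, stage: str) -> int:
    """A stable 31-bit per-stage seed derived from the global seed."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) & 0x7FFFFFFF


@dataclass
class CohortSpec:
    """Size and tissue geometry of one synthetic cohort."""

    n_slides: int = 105
    high_risk_prevalence: float = 0.5
    tissue_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_slides < 0:
            raise ConfigError("n_slides must be >= 0")
        if not 0.0 <= self.high_risk_prevalence <= 1.0:
            raise ConfigError("high_risk_prevalence must lie in [0, 1]")
        if not 0.0 < self.tissue_scale <= 1.0:
            raise ConfigError("tissue_scale must lie in (0, 1]")


@dataclass
class GeneratorSpec:
    """Shared synthetic-slide rendering parameters."""

    image_size: tuple[int, int] = (2325, 1566)
    mpp: float = 4.0
    false_high_risk_rate: float = 0.3
    high_risk_certainty: tuple[float, float] = (16.0, 2.0)
    false_object_certainty: tuple[float, float] = (2.0, 8.0)


@dataclass
class TilingSpec:
    min_object_px: int = 64
    min_tissue_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.min_object_px < 0:
            raise ConfigError("min_object_px must be >= 0")
        if not 0.0 <= self.min_tissue_fraction < 1.0:
            raise ConfigError("min_tissue_fraction must lie in [0, 1)")


@dataclass
class PipelineConfig:
    """Everything a full run needs; see the package docs for field meaning."""

    seed: int = 0
    train: CohortSpec = field(default_factory=CohortSpec)
    validation: CohortSpec = field(
        default_factory=lambda: CohortSpec(n_slides=150, tissue_scale=0.6)
    )
    synthetic: GeneratorSpec = field(default_factory=GeneratorSpec)
    tiling: TilingSpec = field(default_factory=TilingSpec)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)

    def to_dict(self) -> dict:
        doc = asdict(self)
        # frozensets / tuples -> lists for YAML/JSON friendliness
        doc["features"]["high_risk_categories"] = sorted(
            c.value for c in self.features.high_risk_categories
        )
        return json.loads(json.dumps(doc, default=list, sort_keys=True))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


_SECTION_TYPES = {
    "train": CohortSpec,
    "validation": CohortSpec,
    "synthetic": GeneratorSpec,
    "tiling": TilingSpec,
    "features": FeatureConfig,
    "classifier": ClassifierConfig,
}

_TUPLE_FIELDS = {
    "image_size",
    "high_risk_certainty",
    "false_object_certainty",
}


def _build_section(name: str, cls, mapping: dict):
    if not isinstance(mapping, dict):
        raise ConfigError(f"section {name!r} must be a mapping")
    allowed = set(cls.__dataclass_fields__)
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section {name!r}")
    kwargs = {}
    for key, value in mapping.items():
        if key in _TUPLE_FIELDS and isinstance(value, list):
            value = tuple(value)
        if key == "high_risk_categories" and isinstance(value, list):
            value = frozenset(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except ConfigError as exc:
        raise ConfigError(f"section {name!r}: {exc}") from exc


def config_from_dict(doc: dict) -> PipelineConfig:
    """Schema-checked construction; unknown keys are rejected by name."""
    if not isinstance(doc, dict):
        raise ConfigError("pipeline config must be a mapping")
    allowed = {"seed"} | set(_SECTION_TYPES)
    unknown = set(doc) - allowed
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs: dict = {}
    if "seed" in doc:
        if not isinstance(doc["seed"], int):
            raise ConfigError("key 'seed' must be an integer")
        kwargs["seed"] = doc["seed"]
    for name, cls in _SECTION_TYPES.items():
        if name in doc:
            kwargs[name] = _build_section(name, cls, doc[name])
    return PipelineConfig(**kwargs)


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML pipeline config file."""
    doc = yaml.safe_load(Path(path).read_text())
    if doc is None:
        doc = {}
    return config_from_dict(doc)


def _synthetic_config(
    config: PipelineConfig, cohort: CohortSpec, prefix: str, seed: int
) -> SyntheticConfig:
    gen = config.synthetic
    return SyntheticConfig(
        n_slides=cohort.n_slides,
        high_risk_prevalence=cohort.high_risk_prevalence,
        image_size=tuple(gen.image_size),
        mpp=gen.mpp,
        false_high_risk_rate=gen.false_high_risk_rate,
        high_risk_certainty=tuple(gen.high_risk_certainty),
        false_object_certainty=tuple(gen.false_object_certainty),
        tissue_scale=cohort.tissue_scale,
        slide_id_prefix=prefix,
        seed=seed,
    )


def cohort_features(
    config: PipelineConfig, cohort: CohortSpec, prefix: str
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Simulate a cohort and aggregate it into the per-slide feature table.

    Slides are generated, masked and oracle-segmented one at a time (only
    features and labels are retained), so memory stays flat in cohort size.
    """
    syn = _synthetic_config(
        config, cohort, prefix, seed=stage_seed(config.seed, f"simulate-{prefix}")
    )
    corruption = syn.corruption()
    seg_seed = stage_seed(config.seed, f"segment-{prefix}")
    segs = []
    labels: dict[str, str] = {}
    for slide in iter_slides(syn):
        mask = compute_tissue_mask(slide.image, config.tiling.min_object_px)
        seg = oracle_segment(
            slide.regions,
            corruption,
            slide.image.mpp_x,
            slide.image.mpp_y,
            tissue_area_mm2=mask.tissue_area_mm2,
            slide_id=slide.slide_id,
            tissue_mask=mask,
            rng=derive_rng(seg_seed, slide.slide_id),
        )
        segs.append(seg)
        labels[slide.slide_id] = slide.true_label.value
    return features_table(segs, config.features), labels


def run_all(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the full pipeline and persist every artifact under ``out_dir``.

    Writes: cohort manifest, train/validation feature tables, the selected
    model (JSON), per-slide predictions, the evaluation report, and run
    metadata (config + hash + versions). Returns the run directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "simulate+features(train)"
        log.info("stage %s", stage)
        feat_train, labels_train = cohort_features(config, config.train, "train")

        stage = "simulate+features(validation)"
        log.info("stage %s", stage)
        feat_val, labels_val = cohort_features(config, config.validation, "val")
        assert not set(labels_train) & set(labels_val), "cohort slide ids overlap"

        manifest = pd.DataFrame(
            [
                {"slide_id": sid, "true_label": lab, "cohort": cohort}
                for labels, cohort in ((labels_train, "train"), (labels_val, "validation"))
                for sid, lab in sorted(labels.items())
            ]
        )
        manifest.to_csv(out / "manifest.csv", index=False)
        feat_train.to_csv(out / "features_train.csv", index=False)
        feat_val.to_csv(out / "features_validation.csv", index=False)

        stage = "train"
        log.info("stage %s", stage)
        chosen, cv_report = cross_validate_select(
            feat_train, labels_train, config.classifier
        )
        log.info("selected hyperparameters: %s", chosen)
        clf = fit_final(
            feat_train,
            labels_train,
            chosen,
            seed=stage_seed(config.seed, "fit-final"),
            training_set_id="train",
        )
        save_model(clf, out / "model.json")
        cv_report.assign(
            fold_accuracies=cv_report["fold_accuracies"].map(json.dumps)
        ).to_csv(out / "cv_report.csv", index=False)

        stage = "predict"
        log.info("stage %s", stage)
        preds = predict_risk(clf, feat_val, config.classifier.decision_threshold)
        preds.to_csv(out / "predictions.csv", index=False)

        stage = "evaluate"
        log.info("stage %s", stage)
        report = evaluate(
            dict(zip(preds["slide_id"], preds["label"])),
            labels_val,
            scores=dict(zip(preds["slide_id"], preds["probability_high"])),
        )
        doc = report.to_dict()
        doc["decision_threshold"] = config.classifier.decision_threshold
        doc["n_train"] = len(feat_train)
        doc["n_validation"] = len(feat_val)
        (out / "report.json").write_text(json.dumps(doc, sort_keys=True, indent=1) + "\n")

        stage = "metadata"
        metadata = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "package_version": __version__,
            "chosen_hyperparameters": chosen,
        }
        (out / "run_metadata.json").write_text(
            json.dumps(metadata, sort_keys=True, indent=1) + "\n"
        )
        (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    except CrcScreenError as exc:
        raise CrcScreenError(f"pipeline stage {stage!r} failed: {exc}") from exc
    log.info(
        "run complete: sensitivity=%s specificity=%s auc=%s",
        report.sensitivity,
        report.specificity,
        report.auc,
    )
    return out
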