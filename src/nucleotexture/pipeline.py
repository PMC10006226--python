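"""End-to-end orchestration: simulate → features → compare → classify.

Stages communicate only via files (manifest / CSV), so user-supplied
real micrographs can enter at the feature-extraction stage unchanged.
A run is fully determined by (RunConfig, seed); the SHA-256 hash of the
serialized config is recorded in ``run_info.json`` and the run log next
to every output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import ClassifierConfig, ClassifierReport, train_and_evaluate
from .compare import summarize_groups, summary_table
from .glcm import GLCMFeatureConfig, patch_glcm_features
from .ingest import GrayPatch, QuantizationConfig, RoiRecord, iter_patches, read_manifest, quantize_gray
from .synthetic import SyntheticConfig, generate_dataset, generate_records, patch_from_arrays
from .wavelet import patch_wavelet_energies

__all__ = ["RunConfig", "run_pipeline", "extract_features", "FEATURE_TABLE_COLUMNS"]

logger = logging.getLogger("nucleotexture")

FEATURE_TABLE_COLUMNS = [
    "roi_id", "group", "animal_id",
    "ASM", "IDM", "CON", "COR", "SA", "SVAR", "EnLH", "EnHL", "EnHH",
]


@dataclass
class RunConfig:
    """One reproducible run of the whole pipeline."""

    quantization: QuantizationConfig = field(default_factory=QuantizationConfig)
    glcm: GLCMFeatureConfig = field(default_factory=GLCMFeatureConfig)
    wavelet_on_raw: bool = True
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    seed: int = 0
    out_dir: str = "run"

    def to_yaml(self) -> str:
        def listify(obj):
            if isinstance(obj, dict):
                return {k: listify(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [listify(v) for v in obj]
            return obj

        return yaml.safe_dump(listify(dataclasses.asdict(self)), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text) or {}

        def build(klass, key):
            kwargs = raw.get(key) or {}
            for k, v in kwargs.items():  # YAML lists back to tuples
                if isinstance(v, list):
                    kwargs[k] = tuple(v)
            return klass(**kwargs)

        return cls(
            quantization=build(QuantizationConfig, "quantization"),
            glcm=build(GLCMFeatureConfig, "glcm"),
            wavelet_on_raw=raw.get("wavelet_on_raw", True),
            synthetic=build(SyntheticConfig, "synthetic"),
            classifier=build(ClassifierConfig, "classifier"),
            seed=raw.get("seed", 0),
            out_dir=raw.get("out_dir", "run"),
        )

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def _patch_features(patch: GrayPatch, glcm_cfg: GLCMFeatureConfig, wavelet_on_raw: bool) -> dict:
    g = patch_glcm_features(patch, glcm_cfg)
    w = patch_wavelet_energies(patch, use_raw=wavelet_on_raw)
    return {**g.as_dict(), **w.as_dict()}


def extract_features(
    items: Iterable[tuple[RoiRecord, GrayPatch]],
    glcm_cfg: GLCMFeatureConfig = GLCMFeatureConfig(),
    wavelet_on_raw: bool = True,
) -> pd.DataFrame:
    """Build the per-ROI feature table (one row per ROI, 12 columns)."""
    rows = []
    for rec, patch in items:
        try:
            feats = _patch_features(patch, glcm_cfg, wavelet_on_raw)
        except Exception as exc:  # stage context for the operator
            raise RuntimeError(f"feature extraction failed for ROI {rec.roi_id}: {exc}") from exc
        rows.append(
            {"roi_id": rec.roi_id, "group": rec.group, "animal_id": rec.animal_id, **feats}
        )
    return pd.DataFrame(rows, columns=FEATURE_TABLE_COLUMNS)


def synthetic_feature_table(config: RunConfig) -> pd.DataFrame:
    """Generate the synthetic dataset in memory and extract its features
    (no files written; used by tests and the acceptance analysis)."""
    items = []
    for roi_id, animal, group, img, mask in generate_records(config.synthetic):
        rec = RoiRecord(roi_id=roi_id, image_path="", mask_path="", group=group, animal_id=animal)
        patch = patch_from_arrays(img, mask)
        patch = quantize_gray(patch, config.quantization.levels, config.quantization.strategy)
        items.append((rec, patch))
    return extract_features(items, config.glcm, config.wavelet_on_raw)


def _report_dict(r: ClassifierReport) -> dict:
    return {
        "model": r.model,
        "accuracy": r.accuracy,
        "auc": r.auc,
        "roc": {"fpr": r.fpr.tolist(), "tpr": r.tpr.tolist()},
        "split_seed": r.split_seed,
        "n_train": r.n_train,
        "n_test": r.n_test,
    }


def _setup_run_logging(log_path: Path) -> logging.Handler:
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler) and h.stream is sys.stderr
               for h in logger.handlers):
        logger.addHandler(logging.StreamHandler(sys.stderr))
    logger.setLevel(logging.INFO)
    return handler


def run_pipeline(config: RunConfig) -> Path:
    """Run simulate → features → compare → classify; return the run dir.

    Outputs: ``manifest.csv`` (+ images/masks), ``features.csv``,
    ``group_summary.csv``, ``classifier_report.json``, ``run.log``,
    ``run_info.json`` and the serialized config.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logging(out / "run.log")
    chash = config.config_hash()
    try:
        logger.info("nucleotexture %s | python %s | numpy %s", __version__,
                    sys.version.split()[0], np.__version__)
        logger.info("config hash %s | seed %d", chash, config.seed)
        (out / "config.yaml").write_text(config.to_yaml())

        stage = "simulate"
        records = generate_dataset(config.synthetic, out)
        logger.info("[simulate] wrote %d ROIs to %s", len(records), out)

        stage = "features"
        features = extract_features(
            iter_patches(records, config.quantization, root=out),
            config.glcm, config.wavelet_on_raw,
        )
        features.to_csv(out / "features.csv", index=False)
        logger.info("[features] %d rows × %d cols", *features.shape)

        stage = "compare"
        summaries = summarize_groups(features)
        summary_table(summaries).to_csv(out / "group_summary.csv", index=False)
        logger.info("[compare] %d features summarized", len(summaries))

        stage = "classify"
        reports = train_and_evaluate(features, config.seed, config.classifier)
        (out / "classifier_report.json").write_text(
            json.dumps({"config_hash": chash, "models": [_report_dict(r) for r in reports]},
                       indent=2)
        )
        for r in reports:
            logger.info("[classify] %s accuracy=%.3f auc=%.3f", r.model, r.accuracy, r.auc)

        info = {
            "config_hash": chash,
            "seed": config.seed,
            "outputs": ["manifest.csv", "features.csv", "group_summary.csv",
                        "classifier_report.json", "config.yaml", "run.log"],
        }
        (out / "run_info.json").write_text(json.dumps(info, indent=2))
    except Exception as exc:
        logger.error("pipeline failed in stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out
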