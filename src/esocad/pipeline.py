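"""End-to-end orchestration: preprocess -> extract 37 features -> select -> classify.

One :class:`PipelineConfig` document fully determines every numeric output
(the determinism contract); :func:`run` executes all stages and writes the
feature table, per-arm selection artifacts and the evaluation report to an
output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import ClassifierSpec, CvPlan, two_stage_cascade
from .complexity import kc_feature
from .image import GrayImage, RoiSpec
from .preprocess import preprocess_pipeline
from .synth import GeneratorConfig, generate
from .texture import TEXTURE_FEATURE_NAMES, texture_block
from .wavelet import FREQUENCY_FEATURE_NAMES, dwt4, frequency_block

logger = logging.getLogger(__name__)

FEATURE_NAMES: tuple[str, ...] = TEXTURE_FEATURE_NAMES + FREQUENCY_FEATURE_NAMES + ("kc",)

__all__ = ["PipelineConfig", "FEATURE_NAMES", "extract_features", "run"]


@dataclass
class PipelineConfig:
    """All stage parameters in one serializable document."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    median_kernel: int = 3
    glcm_levels: int = 32
    glcm_distance: int = 1
    wavelet_name: str = "haar"
    binarization: str = "global_mean"
    selection_modes: tuple[str, ...] = ("none", "sfs", "pca")
    sfs_stop: str = "no_improvement"
    sfs_fixed_k: int | None = None
    pca_threshold: float = 0.9
    classifiers: tuple[str, ...] = ("svm_rbf", "knn")
    knn_k: int = 15
    n_folds: int = 10
    seed: int = 0
    global_selection: bool = False

    def to_dict(self) -> dict:
        doc = asdict(self)
        doc["selection_modes"] = list(self.selection_modes)
        doc["classifiers"] = list(self.classifiers)
        return doc

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def extract_features(
    images: list[tuple[GrayImage, str]],
    glcm_levels: int = 32,
    glcm_distance: int = 1,
    wavelet_name: str = "haar",
    binarization: str = "global_mean",
) -> pd.DataFrame:
    """Concatenate texture (16) + frequency (20) + complexity (1) per image.

    Returns a table with ``image_id``, ``label`` and the 37 feature columns
    in the frozen :data:`FEATURE_NAMES` order. All images must share one
    shape (mixed sizes would make subband statistics incomparable).
    """
    if not images:
        raise ValueError("no images to extract features from")
    shapes = {img.shape for img, _ in images}
    if len(shapes) > 1:
        raise ValueError(f"mixed image sizes {sorted(shapes)}; preprocess to a common ROI first")
    rows = []
    for img, label in images:
        row: dict = {"image_id": img.id, "label": label}
        row.update(texture_block(img, d=glcm_distance, L=glcm_levels))
        row.update(frequency_block(dwt4(img, wavelet_name=wavelet_name)))
        row["kc"] = kc_feature(img, method=binarization)
        rows.append(row)
    table = pd.DataFrame(rows)
    return table[["image_id", "label", *FEATURE_NAMES]]


def run(config: PipelineConfig, out_dir: str | Path, images: list[tuple[GrayImage, str]] | None = None) -> dict:
    """Execute the full pipeline and write artifacts.

    If no images are passed, the synthetic cohort described by
    ``config.generator`` is drawn. Writes ``features.csv`` and
    ``report.json`` (the report embeds the config, its hash and per-stage
    wall times; times are informational only).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if images is None:
        images = generate(config.generator)
    timings["generate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    processed = [
        (preprocess_pipeline(img, kernel=config.median_kernel), label) for img, label in images
    ]
    timings["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    table = extract_features(
        processed,
        glcm_levels=config.glcm_levels,
        glcm_distance=config.glcm_distance,
        wavelet_name=config.wavelet_name,
        binarization=config.binarization,
    )
    table.to_csv(out_dir / "features.csv", index=False)
    timings["extract"] = time.perf_counter() - t0

    X = table[list(FEATURE_NAMES)]
    labels = table["label"].to_numpy()
    plan = CvPlan(n_folds=config.n_folds, seed=config.seed)
    arms: dict[str, dict] = {}
    t0 = time.perf_counter()
    for kind in config.classifiers:
        spec = ClassifierSpec(kind=kind, K=config.knn_k) if kind == "knn" else ClassifierSpec(kind=kind)
        for mode in config.selection_modes:
            arms[f"{kind}__{mode}"] = two_stage_cascade(
                X,
                labels,
                spec,
                plan=plan,
                selection=mode,
                sfs_stop=config.sfs_stop,
                sfs_fixed_k=config.sfs_fixed_k,
                pca_threshold=config.pca_threshold,
                global_selection=config.global_selection,
            )
    timings["evaluate"] = time.perf_counter() - t0

    report = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_images": len(images),
        "arms": arms,
    }
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    report_with_timings = dict(report, timings=timings)
    (out_dir / "run_log.json").write_text(json.dumps({"config_hash": config.config_hash(), "timings": timings}, indent=2))
    return report_with_timings
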