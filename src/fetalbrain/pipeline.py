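"""End-to-end driver: segment -> enhance -> features -> (PCA) -> repeated CV.

``RunConfig`` collects every tunable of the five phases; ``run_pipeline``
executes them over a directory of grayscale images with a ``labels.csv``
(columns ``filename,label``; 0 = healthy, 1 = abnormal) and optional
ground-truth masks, writing intermediate masks, the feature table, a JSON
evaluation report and the effective configuration next to the outputs.
Reports are byte-reproducible under a fixed config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import phantom as ph
from .classification import make_classifier
from .enhancement import EnhanceParams, enhance_roi
from .evaluation import repeated_cv, segmentation_scores
from .features import PCA_SUBSETS, FeatureConfig, feature_matrix
from .segmentation import SegmentationConfig, segment_brain

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    input_dir: str = ""
    output_dir: str = "out"
    subset_id: int = 3
    model: str = "knn"
    ensemble: str | None = None
    n_learners: int = 60
    folds: int = 5
    repeats: int = 10
    seed: int = 0
    use_pca: bool = False
    pca_components: int | None = None
    pca_variance: float = 0.95
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    enhancement: EnhanceParams = field(default_factory=EnhanceParams)
    features: FeatureConfig = field(default_factory=FeatureConfig)

    def validate(self) -> None:
        if self.subset_id not in range(1, 7):
            raise ValueError("subset_id must be in 1..6")
        if self.subset_id in PCA_SUBSETS and not self.use_pca:
            raise ValueError(
                f"subset {self.subset_id} is high-dimensional and must be "
                "reduced: enable use_pca")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(asdict(self)),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        from .segmentation import StructuringElement, ThresholdParams
        seg = raw.pop("segmentation", None) or {}
        if seg.get("threshold"):
            seg["threshold"] = ThresholdParams(**seg["threshold"])
        if seg.get("se"):
            seg["se"] = StructuringElement(**seg["se"])
        if seg.get("manual_box"):
            seg["manual_box"] = tuple(seg["manual_box"])
        enh = raw.pop("enhancement", None) or {}
        for key in ("global_percentiles", "local_percentiles"):
            if key in enh:
                enh[key] = tuple(enh[key])
        feat = raw.pop("features", None) or {}
        from .features import GaborBankSpec, WaveletSpec
        if feat.get("gabor"):
            g = dict(feat["gabor"])
            for key in ("orientations", "wavelengths"):
                if g.get(key) is not None:
                    g[key] = tuple(g[key])
            feat["gabor"] = GaborBankSpec(**g)
        if feat.get("wavelet"):
            feat["wavelet"] = WaveletSpec(**feat["wavelet"])
        if feat.get("glcm_offset"):
            feat["glcm_offset"] = tuple(feat["glcm_offset"])
        return cls(segmentation=SegmentationConfig(**seg),
                   enhancement=EnhanceParams(**enh),
                   features=FeatureConfig(**feat), **raw)


def _plain(obj):
    """Recursively convert dataclass dicts/tuples to YAML-safe builtins."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


# --------------------------------------------------------------------------
# Cohort I/O

def write_cohort(items: list[ph.LabeledPhantom], out_dir) -> None:
    """Write phantom images, ground-truth masks and the labels table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, item in enumerate(items):
        name = f"img_{i:04d}.png"
        iio.imwrite(out / name, item.image)
        iio.imwrite(out / f"mask_{i:04d}.png",
                    (item.brain_mask.astype(np.uint8) * 255))
        rows.append({"filename": name,
                     "label": 0 if item.label == ph.HEALTHY else 1})
    pd.DataFrame(rows).to_csv(out / "labels.csv", index=False)


def load_cohort(input_dir) -> tuple[list[np.ndarray], list[np.ndarray | None], np.ndarray]:
    """Images, optional ground-truth masks and labels from a cohort dir."""
    root = Path(input_dir)
    table = pd.read_csv(root / "labels.csv")
    images, masks = [], []
    for name in table["filename"]:
        images.append(np.asarray(iio.imread(root / name)))
        mask_path = root / name.replace("img_", "mask_")
        if mask_path.exists() and mask_path != root / name:
            masks.append(np.asarray(iio.imread(mask_path)) > 0)
        else:
            masks.append(None)
    return images, masks, table["label"].to_numpy()


# --------------------------------------------------------------------------
# Driver

def run_pipeline(config: RunConfig) -> dict:
    """Execute all five phases; returns the report dict (also written to disk)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("pipeline start: subset=%d model=%s ensemble=%s seed=%d",
             config.subset_id, config.model, config.ensemble, config.seed)
    log.info("effective config: %s", _plain(asdict(config)))

    images, truth_masks, labels = load_cohort(config.input_dir)

    # phase 1+2: segmentation and enhancement
    rois, seg_scores = [], []
    mask_dir = out / "masks"
    mask_dir.mkdir(exist_ok=True)
    for i, img in enumerate(images):
        seg = segment_brain(img, config.segmentation)
        iio.imwrite(mask_dir / f"mask_{i:04d}.png",
                    seg.brain_mask.astype(np.uint8) * 255)
        rois.append(enhance_roi(seg.minor_roi, config.enhancement))
        if truth_masks[i] is not None:
            seg_scores.append(segmentation_scores(seg.brain_mask, truth_masks[i]))

    # phase 3: features
    feats = feature_matrix(rois, config.subset_id, config.features)
    table = feats.copy()
    table.insert(0, "label", labels)
    table.to_csv(out / "features.csv", index=False)

    # phases 4+5: fold-local PCA (subsets 2/6) + repeated CV
    factory = lambda s: make_classifier(  # noqa: E731
        config.model, ensemble=config.ensemble,
        n_learners=config.n_learners, seed=s)
    cv = repeated_cv(
        feats.to_numpy(), labels, factory,
        folds=config.folds, repeats=config.repeats, seed=config.seed,
        positive=1,
        pca_components=config.pca_components if config.use_pca else None,
        pca_variance=config.pca_variance if config.use_pca else None)

    report = {
        "model": config.model,
        "ensemble": config.ensemble,
        "subset": config.subset_id,
        "seed": config.seed,
        "n_images": int(len(images)),
        "per_fold": cv.records,
        "summary": {k: {"mean": m, "std": s}
                    for k, (m, s) in cv.summary().items()},
    }
    if seg_scores:
        report["segmentation"] = {
            f: float(np.mean([getattr(s, f) for s in seg_scores]))
            for f in ("dice", "jaccard", "specificity", "sensitivity",
                      "accuracy", "precision")}
    (out / "report.json").write_text(json.dumps(report, indent=2,
                                                sort_keys=True))
    config.to_yaml(out / "config.yaml")
    log.info("pipeline done: mean acc %.4f", report["summary"]["acc"]["mean"])
    return report
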