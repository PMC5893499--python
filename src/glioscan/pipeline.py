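"""End-to-end orchestration: image → mask → texture features → classifier.

A single image flows through load → denoise → seeded region growing →
morphological cleanup → (tumor area, MSE/PSNR of the denoised image
against the original) → multilevel DWT → LL/HL subband selection → GLCM
feature vector. An experiment extracts features for a labeled training
and test cohort, stores the patterns in a PNN, and reports resubstitution
("trained") and held-out ("tested") accuracy. Resubstitution accuracy is
optimistic by construction and is reported for comparison only.

Everything is driven by :class:`PipelineConfig`; unknown config keys are
rejected rather than ignored, and each experiment emits a provenance
record (full parameter dump, config hash, seeds) so runs are replayable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import glcm, pnn, segmentation, wavelet
from .imaging_io import GrayImage, QualityReport, denoise, load_image, mse, psnr
from .phantom import PhantomSpec, generate_dataset
from .segmentation import (
    RegionGrowParams,
    SeedSet,
    StructuringElement,
    auto_seed,
    clean_mask,
    cross_se,
    grow_region,
    region_area,
    square_se,
)

logger = logging.getLogger(__name__)

__all__ = [
    "DenoiseConfig",
    "RegionGrowConfig",
    "MorphologyConfig",
    "WaveletConfig",
    "GlcmConfig",
    "PnnConfig",
    "PipelineConfig",
    "extract_features",
    "run_single",
    "run_experiment",
    "run_phantom_experiment",
    "features_to_frame",
]


@dataclass(frozen=True)
class DenoiseConfig:
    method: str = "median"  # {median, none}
    window: int = 3


@dataclass(frozen=True)
class RegionGrowConfig:
    delta: float = 10.0
    connectivity: int = 4
    mean_mode: str = "running"
    seed_mode: str = "auto"  # {auto, manual}
    seeds: tuple = ()  # (row, col) pairs, used when seed_mode == "manual"


@dataclass(frozen=True)
class MorphologyConfig:
    se_shape: str = "square"  # {square, cross}
    se_size: int = 3
    min_component_px: int = 25


@dataclass(frozen=True)
class WaveletConfig:
    name: str = "haar"
    levels: int = 4
    bands: tuple = ("LL", "HL")
    boundary: str = "symmetric"


@dataclass(frozen=True)
class GlcmConfig:
    n_levels: int = 8  # G, gray levels after re-quantization
    distance: int = 1  # S
    angles: tuple = (0, 45, 90, 135)
    aggregate: str = "mean"
    symmetric: bool = True


@dataclass(frozen=True)
class PnnConfig:
    sigma: float = 0.5
    classes: tuple = ("normal", "abnormal")


@dataclass(frozen=True)
class PipelineConfig:
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    region_grow: RegionGrowConfig = field(default_factory=RegionGrowConfig)
    morphology: MorphologyConfig = field(default_factory=MorphologyConfig)
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    glcm: GlcmConfig = field(default_factory=GlcmConfig)
    pnn: PnnConfig = field(default_factory=PnnConfig)
    seed: int = 0

    _SECTIONS = {
        "denoise": DenoiseConfig,
        "region_grow": RegionGrowConfig,
        "morphology": MorphologyConfig,
        "wavelet": WaveletConfig,
        "glcm": GlcmConfig,
        "pnn": PnnConfig,
    }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        """Build a config from nested dicts, rejecting unknown keys."""
        kwargs: dict = {}
        for key, value in data.items():
            if key == "seed":
                kwargs["seed"] = int(value)
                continue
            section = cls._SECTIONS.get(key)
            if section is None:
                raise ValueError(f"unknown config section {key!r}")
            names = {f.name for f in dataclasses.fields(section)}
            bad = set(value) - names
            if bad:
                raise ValueError(f"unknown key(s) {sorted(bad)} in section {key!r}")
            coerced = {
                k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
            }
            kwargs[key] = section(**coerced)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """SHA-256 of the canonical JSON parameter dump."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()


def _structuring_element(cfg: MorphologyConfig) -> StructuringElement:
    if cfg.se_shape == "square":
        return square_se(cfg.se_size)
    if cfg.se_shape == "cross":
        return cross_se(cfg.se_size)
    raise ValueError(f"unknown structuring element shape {cfg.se_shape!r}")


def extract_features(img: GrayImage, cfg: PipelineConfig) -> dict:
    """Denoise, decompose and compute the GLCM feature vector of one image."""
    pre = denoise(img, method=cfg.denoise.method, window=cfg.denoise.window)
    dec = wavelet.decompose(
        pre,
        wavelet_name=cfg.wavelet.name,
        n_levels=cfg.wavelet.levels,
        boundary_mode=cfg.wavelet.boundary,
    )
    subbands = wavelet.select_subbands(
        dec, levels=range(1, cfg.wavelet.levels + 1), bands=cfg.wavelet.bands
    )
    return glcm.feature_vector(
        subbands,
        G=cfg.glcm.n_levels,
        S=cfg.glcm.distance,
        angles=cfg.glcm.angles,
        aggregate=cfg.glcm.aggregate,
        symmetric=cfg.glcm.symmetric,
    )


def run_single(
    image: GrayImage | str | Path,
    cfg: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    name: str = "image",
) -> dict:
    """Process one image through the full detection pipeline.

    Returns a record with the preprocessed image, the cleaned tumor mask,
    the quality report (denoised vs original) and the texture feature
    vector. When ``out_dir`` is given, intermediates are written as PNGs
    next to a JSON provenance record.
    """
    if cfg is None:
        cfg = PipelineConfig()
    img = image if isinstance(image, GrayImage) else load_image(image)

    logger.info("[denoise] method=%s window=%d", cfg.denoise.method, cfg.denoise.window)
    pre = denoise(img, method=cfg.denoise.method, window=cfg.denoise.window)

    if cfg.region_grow.seed_mode == "manual":
        if not cfg.region_grow.seeds:
            raise ValueError("seed_mode='manual' requires explicit seeds")
        seeds = SeedSet([tuple(s) for s in cfg.region_grow.seeds])
    else:
        seeds = auto_seed(pre)
    logger.info(
        "[grow_region] seeds=%s delta=%g connectivity=%d mean_mode=%s",
        seeds.points,
        cfg.region_grow.delta,
        cfg.region_grow.connectivity,
        cfg.region_grow.mean_mode,
    )
    params = RegionGrowParams(
        delta=cfg.region_grow.delta,
        connectivity=cfg.region_grow.connectivity,
        mean_mode=cfg.region_grow.mean_mode,
    )
    raw_mask = grow_region(pre, seeds, params)

    se = _structuring_element(cfg.morphology)
    logger.info(
        "[clean_mask] se=%s size=%d min_component_px=%d",
        cfg.morphology.se_shape,
        cfg.morphology.se_size,
        cfg.morphology.min_component_px,
    )
    mask = clean_mask(raw_mask, se, cfg.morphology.min_component_px)

    err = mse(img, pre)
    quality = QualityReport(
        mse=err,
        psnr_db=psnr(img, pre),
        area_image_px=img.pixels.size,
        area_region_px=region_area(mask),
    )
    logger.info(
        "[quality] mse=%g psnr=%g area=%d", err, quality.psnr_db, quality.area_region_px
    )

    features = extract_features(img, cfg)

    if out_dir is not None:
        from .imaging_io import save_image, save_mask

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_image(pre, out / f"{name}_preprocessed.png")
        save_mask(mask, out / f"{name}_mask.png")
        (out / f"{name}_provenance.json").write_text(
            json.dumps(
                {"config": cfg.to_dict(), "config_hash": cfg.config_hash()},
                default=list,
            )
        )
    return {
        "preprocessed": pre,
        "mask": mask,
        "quality": quality,
        "features": features,
        "seeds": seeds.points,
    }


def features_to_frame(rows: Sequence[tuple[str, dict]]) -> pd.DataFrame:
    """Flatten per-image feature vectors to the standard CSV layout.

    Columns: ``image,level,band,CON,COR,ENE,HOM,ENT`` (mean aggregation,
    one row per subband).
    """
    records = []
    for name, feats in rows:
        per_subband: dict[tuple[int, str], dict[str, float]] = {}
        for key, value in feats.items():
            level, band, feat = key[0], key[1], key[2]
            per_subband.setdefault((level, band), {})[feat] = value
        band_rank = {"LL": 0, "LH": 1, "HL": 2, "HH": 3}
        ordered = sorted(per_subband.items(), key=lambda kv: (kv[0][0], band_rank[kv[0][1]]))
        for (level, band), vals in ordered:
            records.append(
                {"image": name, "level": level, "band": band}
                | {f: vals.get(f, float("nan")) for f in glcm.FEATURE_ORDER}
            )
    return pd.DataFrame.from_records(
        records, columns=["image", "level", "band", *glcm.FEATURE_ORDER]
    )


def _load_labeled_dir(directory: str | Path) -> list[tuple[str, GrayImage, str]]:
    directory = Path(directory)
    labels_path = directory / "labels.csv"
    if not labels_path.exists():
        raise ValueError(f"missing labels file {labels_path}")
    table = pd.read_csv(labels_path)
    if not {"filename", "label"} <= set(table.columns):
        raise ValueError("labels.csv must have columns filename,label")
    return [
        (row.filename, load_image(directory / row.filename), row.label)
        for row in table.itertuples()
    ]


def run_experiment(
    train_dir: str | Path,
    test_dir: str | Path,
    cfg: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Train a PNN on one labeled directory and evaluate on another.

    Each directory must contain images plus a ``labels.csv``
    (``filename,label``). Returns per-image predictions and the trained
    (resubstitution) and tested accuracies in percent.
    """
    if cfg is None:
        cfg = PipelineConfig()
    train_items = _load_labeled_dir(train_dir)
    test_items = _load_labeled_dir(test_dir)
    return _experiment(
        [(n, img) for n, img, _ in train_items],
        [lab for _, _, lab in train_items],
        [(n, img) for n, img, _ in test_items],
        [lab for _, _, lab in test_items],
        cfg,
        out_dir,
    )


def run_phantom_experiment(
    n_train_per_class: int = 30,
    n_test_per_class: int = 10,
    cfg: PipelineConfig | None = None,
    seed: int = 42,
    out_dir: str | Path | None = None,
) -> dict:
    """Balanced phantom experiment: generate, extract, train, evaluate.

    Train and test cohorts are generated from independent seeded streams
    derived from ``seed``, so the experiment is fully reproducible.
    """
    if cfg is None:
        cfg = PipelineConfig()
    root = np.random.SeedSequence(seed)
    train_seed, test_seed = (int(s.generate_state(1)[0] % 2**31) for s in root.spawn(2))
    train = generate_dataset(n_train_per_class, n_train_per_class, seed=train_seed)
    test = generate_dataset(n_test_per_class, n_test_per_class, seed=test_seed)
    return _experiment(
        [(f"train_{i:03d}", img) for i, (img, _, _) in enumerate(train)],
        [lab for _, _, lab in train],
        [(f"test_{i:03d}", img) for i, (img, _, _) in enumerate(test)],
        [lab for _, _, lab in test],
        cfg,
        out_dir,
    )


def _experiment(
    train_named: list,
    train_labels: list,
    test_named: list,
    test_labels: list,
    cfg: PipelineConfig,
    out_dir: str | Path | None,
) -> dict:
    logger.info(
        "extracting features for %d train / %d test images",
        len(train_named),
        len(test_named),
    )
    train_feats = [(n, extract_features(img, cfg)) for n, img in train_named]
    test_feats = [(n, extract_features(img, cfg)) for n, img in test_named]

    X_train = [f for _, f in train_feats]
    X_test = [f for _, f in test_feats]
    model = pnn.train(
        X_train, train_labels, sigma=cfg.pnn.sigma, classes=cfg.pnn.classes
    )
    train_acc = pnn.accuracy(model, X_train, train_labels)
    test_acc = pnn.accuracy(model, X_test, test_labels)
    logger.info("train accuracy %.1f%%, test accuracy %.1f%%", train_acc, test_acc)

    predictions = []
    for (name, feats), truth in zip(test_feats, test_labels):
        res = pnn.classify(model, feats)
        predictions.append(
            {"image": name, "true_label": truth, "predicted": res.label}
            | {f"score_{c}": res.scores[c] for c in model.classes}
        )

    result = {
        "model": model,
        "train_accuracy": train_acc,
        "test_accuracy": test_acc,
        "predictions": predictions,
        "provenance": {
            "config": cfg.to_dict(),
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
            "n_train": len(train_labels),
            "n_test": len(test_labels),
        },
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        features_to_frame(train_feats).to_csv(out / "train_features.csv", index=False)
        features_to_frame(test_feats).to_csv(out / "test_features.csv", index=False)
        pd.DataFrame(predictions).to_csv(out / "predictions.csv", index=False)
        pnn.save_model(model, out / "pnn_model.json")
        (out / "provenance.json").write_text(
            json.dumps(result["provenance"], default=list)
        )
    return result
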