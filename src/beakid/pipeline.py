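"""End-to-end orchestration: generate -> segment -> extract -> evaluate.

One :class:`RunConfig` reproduces a whole experiment cell (descriptor x
classifier x beak view) from a single global seed.  The seed fans out to
the stages with fixed offsets: synthetic data uses ``seed``, classifier
fits ``seed + 1``, the evaluation split plan ``seed + 2`` and deep-feature
adapters ``seed + 3``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, deep, evaluate, hog, imaging, shape, synthetic
from .errors import InvalidParameterError

logger = logging.getLogger("beakid")

DESCRIPTORS = (
    "gray_hog",
    "colour_hog",
    "msd",
    "gray_hog+msd",
    "colour_hog+msd",
    "vgg19",
    "inceptionv3",
    "resnet50",
)

_SEED_OFFSETS = {"synthetic": 0, "classifier": 1, "evaluate": 2, "deep": 3}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one experiment cell."""

    descriptor: str = "colour_hog+msd"
    classifier: str = "ANN"
    view: str = "lower"
    synthetic_config: synthetic.SyntheticDatasetConfig | None = None
    manifest_path: str | None = None
    data_root: str = "."
    rescale_factor: float = 0.1
    sigma: float = 1.0
    threshold: float = 240.0
    object_polarity: str = "dark"
    min_area: float = 100.0
    hog_params: hog.HogParams = field(default_factory=hog.HogParams)
    runs: int = 10
    folds: int = 5
    test_fraction: float = 0.2
    seed: int = 0
    out_dir: str = "beakid_out"

    def __post_init__(self):
        if self.descriptor not in DESCRIPTORS:
            raise InvalidParameterError(
                f"unknown descriptor {self.descriptor!r}; choose from {DESCRIPTORS}"
            )
        if self.classifier not in classify.CLASSIFIER_NAMES:
            raise InvalidParameterError(f"unknown classifier {self.classifier!r}")
        if self.view not in synthetic.VIEWS:
            raise InvalidParameterError(f"view must be one of {synthetic.VIEWS}")


def _descriptor_row(cfg: RunConfig, img: np.ndarray) -> np.ndarray:
    """Traditional descriptors for one photograph at the working scale."""
    smooth, gray, mask, roi = imaging.segment_image(
        img,
        rescale_factor=cfg.rescale_factor,
        sigma=cfg.sigma,
        threshold=cfg.threshold,
        object_polarity=cfg.object_polarity,
        min_area=cfg.min_area,
    )
    parts = []
    if cfg.descriptor.startswith("gray_hog"):
        parts.append(hog.hog_descriptor(gray, cfg.hog_params))
    elif cfg.descriptor.startswith("colour_hog"):
        parts.append(hog.colour_hog_descriptor(smooth, cfg.hog_params))
    if cfg.descriptor == "msd" or cfg.descriptor.endswith("+msd"):
        parts.append(shape.msd_features(imaging.smooth_contour(roi)).as_array())
    return np.concatenate(parts)


def _feature_names(cfg: RunConfig, n_hog: int) -> list[str]:
    names = []
    if "hog" in cfg.descriptor:
        names += [f"hog_{i}" for i in range(n_hog)]
    if cfg.descriptor == "msd" or cfg.descriptor.endswith("+msd"):
        names += list(shape.MSD_NAMES)
    return names


def compute_features(cfg: RunConfig, manifest: pd.DataFrame) -> pd.DataFrame:
    """Feature table (one row per manifest record, final ``label`` column)."""
    if cfg.descriptor in deep.BACKBONE_TABLE:
        spec = deep.BackboneSpec(cfg.descriptor, weights="random")
        table, errors = deep.extract_deep_features(
            manifest, spec, root=cfg.data_root, seed=cfg.seed + _SEED_OFFSETS["deep"]
        )
        for path, msg in errors:
            logger.warning("skipped %s: %s", path, msg)
        return table
    rows, labels = [], []
    for rec in manifest.itertuples(index=False):
        img = imaging.load_rgb(Path(cfg.data_root) / rec.path)
        rows.append(_descriptor_row(cfg, img))
        labels.append(rec.label)
    n_msd = len(shape.MSD_NAMES) if ("msd" in cfg.descriptor) else 0
    table = pd.DataFrame(np.vstack(rows), columns=_feature_names(cfg, len(rows[0]) - n_msd))
    table["label"] = labels
    return table


def run_pipeline(cfg: RunConfig) -> evaluate.EvalReport:
    """Execute one experiment cell and persist its artifacts.

    Writes the manifest (for synthetic sources), the feature CSV and the
    report JSON under ``cfg.out_dir``; returns the evaluation report.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger.info(
        "pipeline start: descriptor=%s classifier=%s view=%s seed=%d",
        cfg.descriptor,
        cfg.classifier,
        cfg.view,
        cfg.seed,
    )

    if cfg.manifest_path is not None:
        manifest = synthetic.load_manifest(cfg.manifest_path)
        data_root = cfg.data_root
    else:
        syn = cfg.synthetic_config or synthetic.default_study_config()
        syn = replace(syn, view=cfg.view, seed=cfg.seed + _SEED_OFFSETS["synthetic"])
        data_dir = out_dir / "dataset"
        manifest = synthetic.generate_dataset(syn, data_dir)
        data_root = str(data_dir)
        logger.info("generated %d synthetic images in %s", len(manifest), data_dir)
    manifest = manifest[manifest["view"] == cfg.view].reset_index(drop=True)
    if manifest.empty:
        raise InvalidParameterError(f"manifest holds no records for view {cfg.view!r}")

    cfg_rooted = replace(cfg, data_root=data_root)
    features = compute_features(cfg_rooted, manifest)
    features_path = out_dir / f"features_{cfg.descriptor.replace('+', '_')}_{cfg.view}.csv"
    features.to_csv(features_path, index=False)
    logger.info("features: %d rows x %d columns -> %s", *features.shape, features_path)

    plan = evaluate.stratified_shuffle_splits(
        features["label"],
        runs=cfg.runs,
        folds=cfg.folds,
        test_fraction=cfg.test_fraction,
        base_seed=cfg.seed + _SEED_OFFSETS["evaluate"],
    )
    spec = classify.ClassifierSpec(cfg.classifier, seed=cfg.seed + _SEED_OFFSETS["classifier"])
    report = evaluate.run_experiment(
        features, spec, plan, descriptor=cfg.descriptor, view=cfg.view
    )
    report_path = out_dir / f"report_{cfg.descriptor.replace('+', '_')}_{cfg.classifier}_{cfg.view}.json"
    report_path.write_text(report.to_json())
    logger.info(
        "report: mean accuracy %.4f (sd %.4f) -> %s",
        report.mean_accuracy,
        report.sd_accuracy,
        report_path,
    )
    return report


def run_grid(configs: list[RunConfig], out_path: str | Path | None = None) -> pd.DataFrame:
    """Evaluate many experiment cells and tabulate mean ± sd accuracy.

    Rows are classifiers, columns ``descriptor/view``; failed cells are
    recorded as NaN with the error logged, and the grid continues.
    """
    cells = []
    for cfg in configs:
        col = f"{cfg.descriptor}/{cfg.view}"
        try:
            report = run_pipeline(cfg)
        except Exception as exc:  # noqa: BLE001 - cell isolation is the contract
            logger.error("grid cell %s x %s failed: %s", cfg.classifier, col, exc)
            cells.append({"classifier": cfg.classifier, "column": col, "mean": np.nan, "sd": np.nan})
            continue
        cells.append(
            {
                "classifier": cfg.classifier,
                "column": col,
                "mean": report.mean_accuracy,
                "sd": report.sd_accuracy,
            }
        )
    frame = pd.DataFrame(cells)
    summary = frame.pivot(index="classifier", columns="column", values="mean")
    if out_path is not None:
        summary.to_csv(out_path)
    return summary
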