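"""End-to-end orchestration: scene -> FA -> patches -> split -> train -> evaluate -> map.

A single :class:`PipelineConfig` drives one run. Input is either a cube/mask
pair on disk or a synthetic-scene request (exactly one). Every stage derives
its randomness from the one config seed, so a rerun with the same config
reproduces ``metrics.json`` byte for byte; wall-clock timings go to the log
and the comparison table only, never into the metrics.

``compare_models`` trains several architectures on the *identical* patch set
and split (the split's SHA-256 hash is recorded per row so identity is
checkable), mirroring the single-sample-set protocol used when ranking models.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from contextlib import contextmanager
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hsi_io
from .hsi_io import HyperspectralCube, LabelMask
from .metrics import compute_report
from .models import (MODEL_NAMES, TrainingConfig, build_model, predict_labels,
                     predict_map, train_model)
from .preprocessing import extract_patches, reduce_bands_fa, stratified_split
from .synthetic import SceneSpec, generate_scene, make_spectral_library

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "compare_models",
           "DEFAULT_PALETTE", "split_hash"]

logger = logging.getLogger(__name__)

DEFAULT_PALETTE = {
    "normal": (0, 190, 0),
    "tumor": (220, 0, 0),
    "vessel": (0, 80, 255),
    "background": (140, 140, 140),
}
_EXTRA_COLORS = [(255, 200, 0), (160, 0, 200), (0, 200, 200), (255, 120, 180)]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class SyntheticSceneConfig:
    """Synthetic-scene request: geometry plus spectral-library knobs."""

    dims: tuple[int, int, int] = (64, 64, 30)
    labeled_fraction: float = 0.5
    separation: float = 10.0
    sigma: float = 0.05
    corr_length: float = 5.0


@dataclass
class PipelineConfig:
    """One run's resolved configuration.

    Exactly one of (``cube_path`` + ``mask_path``) or ``scene`` must be set.
    Preprocessing and training defaults are the pipeline's standard regime:
    3 FA bands, 3x3 patches, zero padding, 15/15/70 split, 50 epochs,
    batch 256, lr 0.001, Adam.
    """

    out_dir: str = "runs/run"
    seed: int = 0
    cube_path: str | None = None
    mask_path: str | None = None
    scene: SyntheticSceneConfig | None = None
    n_factors: int = 3
    patch_size: int = 3
    padding: str = "zero"
    fractions: tuple[float, float, float] = (0.15, 0.15, 0.70)
    model: str = "scs"
    training: TrainingConfig = field(default_factory=TrainingConfig)
    render_map: bool = True

    def __post_init__(self) -> None:
        has_files = self.cube_path is not None or self.mask_path is not None
        has_scene = self.scene is not None
        if has_files and has_scene:
            raise ValueError("config names both real input paths and a synthetic scene")
        if not has_files and not has_scene:
            raise ValueError("config must name either input paths or a synthetic scene")
        if has_files and (self.cube_path is None or self.mask_path is None):
            raise ValueError("real input needs both cube_path and mask_path")
        if self.model not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODEL_NAMES}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "scene" in d and d["scene"] is not None:
            scene = dict(d["scene"])
            if "dims" in scene:
                scene["dims"] = tuple(scene["dims"])
            d["scene"] = SyntheticSceneConfig(**scene)
        if "training" in d and d["training"] is not None:
            tr = dict(d["training"])
            tr.setdefault("seed", d.get("seed", 0))
            d["training"] = TrainingConfig(**tr)
        else:
            d["training"] = TrainingConfig(seed=d.get("seed", 0))
        if "fractions" in d:
            d["fractions"] = tuple(d["fractions"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict:
        return asdict(self)


@contextmanager
def _stage(name: str):
    logger.info("stage %s: start", name)
    t0 = time.perf_counter()
    try:
        yield
    except Exception as e:
        raise PipelineError(f"stage {name!r} failed: {e}") from e
    logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)


def _palette_for(class_names: list[str]) -> dict[str, tuple[int, int, int]]:
    palette = {}
    extra = iter(_EXTRA_COLORS * 8)
    for name in class_names:
        palette[name] = DEFAULT_PALETTE.get(name, next(extra))
    return palette


def split_hash(split) -> str:
    """SHA-256 over the concatenated train/val/test index arrays."""
    h = hashlib.sha256()
    for part in (split.train, split.val, split.test):
        h.update(np.ascontiguousarray(part, dtype=np.int64).tobytes())
    return h.hexdigest()


def _load_inputs(config: PipelineConfig) -> tuple[HyperspectralCube, LabelMask]:
    if config.scene is not None:
        spec = SceneSpec(dims=config.scene.dims,
                         labeled_fraction=config.scene.labeled_fraction,
                         seed=config.seed)
        library = make_spectral_library(
            C=len(spec.class_names), B=config.scene.dims[2],
            separation=config.scene.separation, seed=config.seed,
            sigma=config.scene.sigma, corr_length=config.scene.corr_length)
        return generate_scene(spec, library)
    cube = hsi_io.read_cube(config.cube_path)
    mask = hsi_io.read_label_mask(config.mask_path)
    mask.check_matches(cube)
    return cube, mask


def _prepare(config: PipelineConfig):
    """Shared front half: inputs -> FA -> patches -> split."""
    with _stage("load-inputs"):
        cube, mask = _load_inputs(config)
    with _stage("factor-analysis"):
        reduced = reduce_bands_fa(cube, n_factors=config.n_factors, seed=config.seed)
    with _stage("patch-extraction"):
        patchset = extract_patches(reduced, mask, s=config.patch_size,
                                   padding=config.padding)
    with _stage("split"):
        split = stratified_split(patchset, fractions=config.fractions,
                                 seed=config.seed)
    return cube, mask, reduced, patchset, split


def _train_and_score(config: PipelineConfig, model_name: str, patchset, split):
    spec = build_model(model_name, patchset.patches.shape[1:],
                       len(patchset.class_names))
    t0 = time.perf_counter()
    trained = train_model(spec, patchset, split, config.training)
    train_time = time.perf_counter() - t0
    t0 = time.perf_counter()
    pred, _ = predict_labels(trained, patchset.patches[split.test])
    test_time = time.perf_counter() - t0
    report = compute_report(patchset.labels[split.test], pred,
                            len(patchset.class_names), patchset.class_names)
    return trained, report, train_time, test_time


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute one full run; returns the run directory.

    Artifacts: ``metrics.json`` (test-split evaluation), ``history.csv``
    (per-epoch curves), ``map.png`` + ``pred_mask.png`` (full-scene
    classification), ``config.json`` (resolved config + seed), ``run.log``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("scshsi")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        (out / "config.json").write_text(
            json.dumps(config.to_dict(), indent=1, sort_keys=True))
        cube, mask, reduced, patchset, split = _prepare(config)
        with _stage("train"):
            trained, report, train_time, test_time = _train_and_score(
                config, config.model, patchset, split)
        logger.info("train %.2fs, test %.2fs", train_time, test_time)
        with _stage("report"):
            (out / "metrics.json").write_text(report.to_json())
            trained.save_history(out / "history.csv")
        if config.render_map:
            with _stage("render-map"):
                pred_mask = predict_map(trained, reduced, s=config.patch_size,
                                        padding=config.padding)
                palette = _palette_for(pred_mask.class_names)
                hsi_io.write_classification_map(pred_mask, palette, out / "map.png")
                hsi_io.write_label_mask(
                    LabelMask(labels=pred_mask.labels,
                              class_names=pred_mask.class_names,
                              unlabeled_value=-1),
                    out / "pred_mask.png")
        return out
    finally:
        root.removeHandler(handler)
        handler.close()


def compare_models(config: PipelineConfig, model_list: list[str]) -> pd.DataFrame:
    """Train several models on one identical split; return the comparison table.

    The table (also written to ``comparison.csv``) carries kappa, OA, AA, F1
    and wall times per model, plus the split hash proving all rows used the
    same samples.
    """
    if len(model_list) < 2:
        raise ValueError("compare_models needs at least 2 models")
    unknown = [m for m in model_list if m not in MODEL_NAMES]
    if unknown:
        raise ValueError(f"unknown model(s) {unknown}; choose from {MODEL_NAMES}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cube, mask, reduced, patchset, split = _prepare(config)
    shash = split_hash(split)
    logger.info("split hash %s", shash)
    rows = []
    for name in model_list:
        with _stage(f"train-{name}"):
            _, report, train_time, test_time = _train_and_score(
                config, name, patchset, split)
        row = {"model": name, **report.csv_row(),
               "train_time_s": train_time, "test_time_s": test_time,
               "split_hash": shash}
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(out / "comparison.csv", index=False)
    return table
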