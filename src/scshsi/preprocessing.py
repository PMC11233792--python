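"""Spectral dimension reduction, patch extraction and per-class splitting.

The pipeline feeds the classifier three kinds of objects produced here:

* a band-reduced cube, where the B raw bands are compressed to a few factor
  scores of a Factor Analysis fitted on the scene's standardized spectra;
* spectral-spatial **patches**: the s x s neighborhood of reduced spectra
  around each labeled focal pixel, labeled by that pixel's class only;
* a per-class stratified split (default 15% train / 15% validation / 70%
  test) with largest-remainder rounding so per-class counts are within one
  sample of the exact fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import FactorAnalysis

from .hsi_io import HyperspectralCube, LabelMask

__all__ = ["PatchSet", "SplitIndices", "reduce_bands_fa", "extract_patches",
           "extract_patches_full", "stratified_split"]

logger = logging.getLogger(__name__)

_PAD_MODES = {"zero": "constant", "mirror": "symmetric"}


@dataclass
class PatchSet:
    """Spectral-spatial samples: (n, s, s, D) patches with focal coords and labels.

    ``labels`` are 0-based indices into ``class_names`` (never the unlabeled
    sentinel); ``coords`` are 0-based (row, col) of each focal pixel.
    """

    patches: np.ndarray
    coords: np.ndarray
    labels: np.ndarray
    s: int
    class_names: list[str]

    def __post_init__(self) -> None:
        if self.s % 2 == 0:
            raise ValueError(f"patch side s must be odd, got {self.s}")
        if self.patches.ndim != 4 or self.patches.shape[1:3] != (self.s, self.s):
            raise ValueError(f"patches must be (n, {self.s}, {self.s}, D)")
        if len(self.labels) != len(self.patches) or len(self.coords) != len(self.patches):
            raise ValueError("patches, coords and labels must align")
        if len(self.labels) and (self.labels.min() < 0
                                 or self.labels.max() >= len(self.class_names)):
            raise ValueError("labels must be 0-based class indices")

    @property
    def n_samples(self) -> int:
        return len(self.patches)

    @property
    def n_bands(self) -> int:
        return self.patches.shape[3]


@dataclass
class SplitIndices:
    """Disjoint, exhaustive train/val/test indices into a PatchSet."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    fractions: tuple[float, float, float]
    seed: int

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"train": self.train, "val": self.val, "test": self.test}


def reduce_bands_fa(cube: HyperspectralCube, n_factors: int = 3, seed: int = 0,
                    mode: str = "scores") -> HyperspectralCube:
    """Compress B spectral bands to ``n_factors`` informative bands via FA.

    A Factor Analysis is fitted on the (M*N) x B matrix of band-standardized
    spectra. ``mode="scores"`` (default) returns the factor-score bands, each
    re-standardized to zero mean / unit variance over the scene;
    ``mode="select"`` instead keeps, per factor, the original band with the
    largest absolute loading (the band-selection reading of "most informative
    bands"). Deterministic given ``seed``.
    """
    if mode not in ("scores", "select"):
        raise ValueError(f"unknown mode {mode!r}")
    M, N, B = cube.shape
    if n_factors > B:
        raise ValueError(f"n_factors {n_factors} exceeds band count {B}")
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    flat = cube.data.reshape(M * N, B)
    mean = flat.mean(axis=0)
    std = flat.std(axis=0)
    keep = std > 0
    if keep.sum() < n_factors:
        raise ValueError(
            f"only {int(keep.sum())} bands have nonzero variance; "
            f"cannot estimate {n_factors} factors"
        )
    if not keep.all():
        logger.warning("excluding %d zero-variance band(s) from standardization",
                       int((~keep).sum()))
    z = (flat[:, keep] - mean[keep]) / std[keep]
    fa = FactorAnalysis(n_components=n_factors, random_state=seed)
    scores = fa.fit_transform(z)
    if mode == "select":
        loading_band = np.argmax(np.abs(fa.components_), axis=1)
        orig = np.flatnonzero(keep)[loading_band]
        data = flat[:, orig].reshape(M, N, n_factors)
        return HyperspectralCube(data=data, name=f"{cube.name}|fa-select{n_factors}")
    scores = (scores - scores.mean(axis=0)) / scores.std(axis=0)
    return HyperspectralCube(data=scores.reshape(M, N, n_factors),
                             name=f"{cube.name}|fa{n_factors}")


def _padded(cube: HyperspectralCube, s: int, padding: str) -> np.ndarray:
    if s % 2 == 0 or s < 1:
        raise ValueError(f"patch side s must be a positive odd integer, got {s}")
    if padding not in _PAD_MODES:
        raise ValueError(f"unknown padding {padding!r}; use one of {list(_PAD_MODES)}")
    r = s // 2
    return np.pad(cube.data, ((r, r), (r, r), (0, 0)), mode=_PAD_MODES[padding])


def extract_patches(cube: HyperspectralCube, mask: LabelMask, s: int = 3,
                    padding: str = "zero") -> PatchSet:
    """One s x s x D patch per labeled pixel, centered on the focal pixel.

    Patch windows that overhang the scene edge are filled by the padding rule
    (``zero`` or ``mirror``). The patch label is the focal pixel's class; the
    neighborhood contributes context only.
    """
    mask.check_matches(cube)
    padded = _padded(cube, s, padding)
    coords = mask.labeled_coords()
    if len(coords) == 0:
        raise ValueError("mask has no labeled pixels; nothing to extract")
    # focal pixel (r, c) maps to padded window starting at (r, c)
    patches = np.stack([padded[r:r + s, c:c + s, :] for r, c in coords])
    labels = mask.labels[coords[:, 0], coords[:, 1]] - 1  # codes 1..C -> 0-based
    return PatchSet(patches=patches, coords=coords, labels=labels, s=s,
                    class_names=list(mask.class_names))


def extract_patches_full(cube: HyperspectralCube, s: int = 3,
                         padding: str = "zero") -> np.ndarray:
    """Patches at *every* pixel, row-major: (M*N, s, s, D). Used for full-scene maps."""
    padded = _padded(cube, s, padding)
    win = np.lib.stride_tricks.sliding_window_view(padded, (s, s), axis=(0, 1))
    M, N = cube.shape[:2]
    return win.transpose(0, 1, 3, 4, 2).reshape(M * N, s, s, cube.n_bands)


def stratified_split(patchset: PatchSet, fractions: tuple[float, float, float]
                     = (0.15, 0.15, 0.70), seed: int = 0,
                     strict: bool = False) -> SplitIndices:
    """Per-class random partition into train/val/test at the given fractions.

    Within each class (processed in ascending class order) indices are
    shuffled, then sizes are rounded by largest remainder with a fixed tie
    order (train, then val, then test). Classes with fewer than 3 samples
    cannot appear in all three splits: they go entirely to train with a
    warning, or raise in ``strict`` mode. Deterministic for a fixed seed.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions) or \
            abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must be 3 non-negatives summing to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    parts: dict[str, list[np.ndarray]] = {"train": [], "val": [], "test": []}
    for cls in range(len(patchset.class_names)):
        idx = np.flatnonzero(patchset.labels == cls)
        if len(idx) == 0:
            continue
        if len(idx) < 3:
            if strict:
                raise ValueError(
                    f"class {patchset.class_names[cls]!r} has only {len(idx)} "
                    "sample(s); cannot stratify into three splits"
                )
            logger.warning("class %r has %d sample(s) < 3; assigning all to train",
                           patchset.class_names[cls], len(idx))
            parts["train"].append(idx)
            continue
        idx = rng.permutation(idx)
        raw = np.array(fractions) * len(idx)
        sizes = np.floor(raw).astype(int)
        remainder = raw - sizes
        # largest remainder; ties resolve to earlier split (train < val < test)
        for j in np.argsort(-remainder, kind="stable")[: len(idx) - sizes.sum()]:
            sizes[j] += 1
        bounds = np.cumsum(sizes)
        parts["train"].append(idx[:bounds[0]])
        parts["val"].append(idx[bounds[0]:bounds[1]])
        parts["test"].append(idx[bounds[1]:])
    cat = {k: np.sort(np.concatenate(v)) if v else np.array([], dtype=int)
           for k, v in parts.items()}
    return SplitIndices(train=cat["train"], val=cat["val"], test=cat["test"],
                        fractions=fractions, seed=seed)
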