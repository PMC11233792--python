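"""Synthetic labeled hyperspectral tissue scenes.

Real intraoperative hyperspectral cubes of exposed brain tissue are access-
restricted, so this module fabricates scenes with the same structure the
pipeline assumes: four tissue classes (normal tissue, tumor, blood vessels,
background) with distinct smooth spectral signatures, spatially contiguous
regions (a background frame around the surgical field, an elliptical tumor
blob inside normal tissue, curvilinear vessel tracks), band-correlated
Gaussian noise, and a partially labeled ground-truth mask.

Class separability is controlled explicitly: ``separation`` is the minimum
pairwise Mahalanobis distance between class-mean spectra under the noise
covariance (band-correlated, per-band std sigma), and the generator rescales
the means so the realized separation matches the request exactly. Under
correlated noise this — not raw distance over sigma — is what determines how
far apart the classes effectively are: a separation of 10 leaves the optimal
per-pixel error rate negligible by construction. Everything is
deterministic per seed, and the cube is identical across different
``labeled_fraction`` values (labels are drawn from an independent stream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular

from .hsi_io import HyperspectralCube, LabelMask

__all__ = ["SpectralLibrary", "SceneSpec", "make_spectral_library",
           "generate_scene", "CLASS_NAMES"]

CLASS_NAMES = ["normal", "tumor", "vessel", "background"]


@dataclass
class SpectralLibrary:
    """Per-class mean spectra plus the within-class noise model.

    ``class_means`` is (C, B), non-negative and smooth (sums of 1-3 Gaussian
    bumps over band index). Noise is Gaussian with per-band std ``sigma`` and
    exponential band-to-band correlation of length ``corr_length``.
    """

    class_means: np.ndarray
    sigma: float
    corr_length: float
    seed: int
    separation: float

    @property
    def n_classes(self) -> int:
        return self.class_means.shape[0]

    @property
    def n_bands(self) -> int:
        return self.class_means.shape[1]

    def realized_separation(self) -> float:
        """Min pairwise Mahalanobis distance between class means under the noise."""
        if self.sigma <= 0:
            return float("inf")
        return float(min(_mahalanobis_distances(
            self.class_means, self.sigma, self.corr_length)))

    def noise_cholesky(self) -> np.ndarray:
        """Cholesky factor of the band correlation matrix."""
        return np.linalg.cholesky(_band_correlation(self.n_bands, self.corr_length))


@dataclass
class SceneSpec:
    """Geometry and labeling of one synthetic surgical scene.

    Layout: a background frame of width ~M/10 around the field, normal tissue
    filling the interior, one elliptical tumor blob, and two sinusoidal vessel
    tracks. ``labeled_fraction`` of each class's pixels carry ground-truth
    labels; the rest are the unlabeled sentinel.
    """

    dims: tuple[int, int, int] = (64, 64, 30)
    labeled_fraction: float = 0.5
    seed: int = 0
    class_names: list[str] = field(default_factory=lambda: list(CLASS_NAMES))

    def __post_init__(self) -> None:
        M, N, B = self.dims
        if M < 16 or N < 16:
            raise ValueError(f"scene dims {M}x{N} too small for the layout (min 16x16)")
        if not 0 < self.labeled_fraction <= 1:
            raise ValueError("labeled_fraction must be in (0, 1]")


def _band_correlation(B: int, corr_length: float) -> np.ndarray:
    b = np.arange(B)
    return np.exp(-np.abs(b[:, None] - b[None, :]) / corr_length)


def _mahalanobis_distances(means: np.ndarray, sigma: float,
                           corr_length: float) -> list[float]:
    """Pairwise Mahalanobis distances of class means under cov = sigma^2 R."""
    C, B = means.shape
    cov = sigma ** 2 * _band_correlation(B, corr_length)
    chol = np.linalg.cholesky(cov)
    # whiten: d_M(a, b) = ||L^-1 (a - b)||
    diffs = [means[i] - means[j] for i in range(C) for j in range(i + 1, C)]
    w = solve_triangular(chol, np.array(diffs).T, lower=True)
    return [float(np.linalg.norm(w[:, k])) for k in range(len(diffs))]


def make_spectral_library(C: int = 4, B: int = 30, separation: float = 10.0,
                          seed: int = 0, sigma: float = 0.05,
                          corr_length: float = 5.0) -> SpectralLibrary:
    """Draw C smooth non-negative spectra with the requested separation.

    Each mean is a flat baseline plus 1-3 Gaussian bumps with class-specific
    centers and widths; the means are then rescaled about their grand mean so
    the minimum pairwise Mahalanobis distance under the noise covariance
    equals ``separation`` exactly, and shifted so all values stay non-negative
    (a common offset preserves all pairwise distances).
    """
    if C < 2:
        raise ValueError("need at least 2 classes")
    if B < 3:
        raise ValueError("need at least 3 bands")
    if separation <= 0:
        raise ValueError("separation must be > 0")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    rng = np.random.default_rng(seed)
    grid = np.arange(B)
    means = np.empty((C, B))
    for c in range(C):
        spectrum = np.full(B, 0.2)
        for _ in range(int(rng.integers(1, 4))):
            amp = rng.uniform(0.3, 1.0)
            center = rng.uniform(0, B - 1)
            width = rng.uniform(B / 10, B / 4)
            spectrum += amp * np.exp(-0.5 * ((grid - center) / width) ** 2)
        means[c] = spectrum
    grand = means.mean(axis=0)
    dmin = min(_mahalanobis_distances(means, sigma, corr_length))
    if dmin < 1e-9:
        raise ValueError("degenerate draw: two class means coincide; change the seed")
    means = grand + (separation / dmin) * (means - grand)
    lo = means.min()
    if lo < 0:
        means -= lo
    return SpectralLibrary(class_means=means, sigma=sigma, corr_length=corr_length,
                           seed=seed, separation=separation)


def _layout(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Full ground-truth class map (every pixel assigned), codes 1..4."""
    M, N, _ = spec.dims
    normal, tumor, vessel, background = 1, 2, 3, 4
    truth = np.full((M, N), normal, dtype=np.int64)

    frame = max(2, min(M, N) // 10)
    truth[:frame, :] = background
    truth[-frame:, :] = background
    truth[:, :frame] = background
    truth[:, -frame:] = background

    rr, cc = np.mgrid[0:M, 0:N]
    cy = M * rng.uniform(0.4, 0.6)
    cx = N * rng.uniform(0.4, 0.6)
    ry = max(3.0, M * rng.uniform(0.12, 0.18))
    rx = max(3.0, N * rng.uniform(0.12, 0.18))
    ellipse = ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0
    truth[ellipse & (truth == normal)] = tumor

    interior = slice(frame, N - frame)
    cols = np.arange(frame, N - frame)
    for _ in range(2):
        base = rng.uniform(0.25, 0.75) * M
        amp = rng.uniform(0.05, 0.15) * M
        freq = rng.uniform(1.0, 2.5)
        phase = rng.uniform(0, 2 * np.pi)
        rows = np.round(base + amp * np.sin(2 * np.pi * freq * cols / N + phase))
        # tracks are ~2 px thick: single-pixel structures would be an
        # unrealistic vessel caliber at this ground resolution
        for off in (0, 1):
            r = np.clip(rows + off, frame, M - frame - 1).astype(int)
            truth[r, cols] = vessel  # vessels overlay the tissue surface

    for code, name in zip((normal, tumor, vessel, background), spec.class_names):
        if not (truth == code).any():
            raise ValueError(f"layout produced no pixels for class {name!r}")
    return truth


def generate_scene(spec: SceneSpec, library: SpectralLibrary
                   ) -> tuple[HyperspectralCube, LabelMask]:
    """Render a scene: per-pixel spectrum = class mean + correlated noise.

    Returns the cube and a partially labeled mask (codes 1..4, unlabeled 0).
    The full ground truth is recovered by regenerating with
    ``labeled_fraction=1.0`` and the same seed — cube and layout are drawn
    from a stream independent of the label subsampling.
    """
    M, N, B = spec.dims
    if library.n_classes != len(spec.class_names):
        raise ValueError(
            f"library has {library.n_classes} classes; scene layout needs "
            f"{len(spec.class_names)}"
        )
    if library.n_bands != B:
        raise ValueError(f"library has {library.n_bands} bands; scene declares {B}")
    rng_scene = np.random.default_rng([spec.seed, 0])
    rng_label = np.random.default_rng([spec.seed, 1])

    truth = _layout(spec, rng_scene)
    data = library.class_means[truth - 1].astype(np.float64)
    if library.sigma > 0:
        z = rng_scene.standard_normal((M, N, B))
        data = data + library.sigma * (z @ library.noise_cholesky().T)

    labels = truth.copy()
    if spec.labeled_fraction < 1.0:
        for code in range(1, library.n_classes + 1):
            idx = np.argwhere(labels == code)
            n_drop = len(idx) - int(round(spec.labeled_fraction * len(idx)))
            drop = idx[rng_label.choice(len(idx), size=n_drop, replace=False)]
            labels[drop[:, 0], drop[:, 1]] = 0

    cube = HyperspectralCube(data=data, name=f"synthetic-{spec.seed}")
    mask = LabelMask(labels=labels, class_names=list(spec.class_names),
                     unlabeled_value=0)
    return cube, mask
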