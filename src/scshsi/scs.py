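"""Sharpened cosine similarity (SCS) scoring and absolute max-pooling.

The SCS operator replaces the sliding dot product of a convolution with a
magnitude-normalized similarity

    SCS(w, x) = sign(c) * |c|**p,   c = (w . x) / ((||w|| + q) (||x|| + q))

where ``q >= 0`` stabilizes the normalization against small-magnitude windows
and the sign-preserving exponent ``p >= 1`` sharpens the response around
perfectly aligned directions. With ``q = 0`` and ``p = 1`` the score is
exactly classical cosine similarity, bounded in [-1, 1]; any ``q > 0`` only
damps the magnitude, so the bound holds for all admissible parameters.

The reading of the stabilizer adds ``q`` to each *norm*. An alternative,
adding ``q`` to every vector *component* before taking norms, is available
via ``q_mode="componentwise"`` for comparison; it does not reduce to cosine
similarity at q=0 for the same inputs unless both vectors are nonzero.

``abs_max_pool`` keeps, per pooling window, the signed value of largest
absolute value — SCS feature maps are signed, and a strong anti-match is as
informative as a strong match. Ties break to the first element in row-major
order so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SCSKernel",
    "SCSLayerConfig",
    "scs_score",
    "scs_score_grad",
    "scs_layer_forward",
    "abs_max_pool",
]


@dataclass
class SCSKernel:
    """One SCS unit: weights ``w`` (window-shaped), stabilizer ``q``, exponent ``p``."""

    w: np.ndarray
    q: float = 0.0
    p: float = 1.0

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64)
        if not np.all(np.isfinite(self.w)):
            raise ValueError("kernel weights must be finite")
        if self.q < 0:
            raise ValueError(f"stabilizer q must be >= 0, got {self.q}")
        if self.p < 1:
            raise ValueError(f"sharpening exponent p must be >= 1, got {self.p}")


@dataclass
class SCSLayerConfig:
    """Configuration of one SCS layer.

    ``q_floor`` is the lower clamp applied to ``q`` during optimization so the
    denominator never collapses; ties in absolute max-pooling always resolve
    to the first occurrence in row-major order.
    """

    n_units: int = 256
    kernel_size: int = 3
    stride: int = 1
    q_init: float = 0.1
    p_init: float = 1.0
    q_trainable: bool = True
    p_trainable: bool = True
    q_floor: float = 1e-6
    q_mode: str = "norm"  # "norm": (||v||+q); "componentwise": ||v+q||

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")
        if self.q_mode not in ("norm", "componentwise"):
            raise ValueError(f"unknown q_mode {self.q_mode!r}")


def _cos_core(w: np.ndarray, x: np.ndarray, q: float, q_mode: str) -> float:
    if q_mode == "componentwise":
        dw = float(np.linalg.norm(w + q))
        dx = float(np.linalg.norm(x + q))
    else:
        dw = float(np.linalg.norm(w)) + q
        dx = float(np.linalg.norm(x)) + q
    denom = dw * dx
    if denom == 0.0:
        raise ValueError(
            "undefined cosine: q = 0 with a zero-norm vector "
            "(increase q or exclude empty windows)"
        )
    return float(np.dot(w, x)) / denom


def scs_score(w: np.ndarray, x: np.ndarray, q: float = 0.0, p: float = 1.0,
              q_mode: str = "norm") -> float:
    """Sharpened cosine similarity between two equal-length vectors.

    Returns ``sign(c) * |c|**p`` with ``c`` the q-stabilized cosine. For
    ``q=0, p=1`` this is exactly cosine similarity; the result always lies in
    ``[-1, 1]`` for ``p >= 1`` and ``q >= 0``.
    """
    w = np.asarray(w, dtype=np.float64).ravel()
    x = np.asarray(x, dtype=np.float64).ravel()
    if w.shape != x.shape:
        raise ValueError(f"shape mismatch: w has {w.shape}, x has {x.shape}")
    if q < 0:
        raise ValueError(f"q must be >= 0, got {q}")
    if p < 1:
        raise ValueError(f"p must be >= 1, got {p}")
    c = _cos_core(w, x, q, q_mode)
    return float(np.sign(c) * np.abs(c) ** p)


def scs_score_grad(w: np.ndarray, x: np.ndarray, q: float, p: float
                   ) -> tuple[np.ndarray, float, float]:
    """Analytic gradients of ``scs_score`` w.r.t. ``w``, ``q`` and ``p``.

    Uses the norm-offset reading of the stabilizer. Let ``u = w.x``,
    ``d = (||w||+q)(||x||+q)`` and ``c = u/d``; then

        ds/dc = p |c|**(p-1)
        dc/dw = x/d - c * w / (||w|| (||w||+q))
        dc/dq = -c (||w|| + ||x|| + 2q) / d
        ds/dp = s * ln|c|            (0 at c = 0)

    Valid away from ``c = 0`` when ``p > 1`` (the |c|**(p-1) kink).
    """
    w = np.asarray(w, dtype=np.float64).ravel()
    x = np.asarray(x, dtype=np.float64).ravel()
    nw = float(np.linalg.norm(w))
    nx = float(np.linalg.norm(x))
    dw_ = nw + q
    dx_ = nx + q
    d = dw_ * dx_
    if d == 0.0 or nw == 0.0:
        raise ValueError("gradient undefined for zero-norm w with q = 0")
    u = float(np.dot(w, x))
    c = u / d
    s = np.sign(c) * np.abs(c) ** p
    ds_dc = p * np.abs(c) ** (p - 1) if c != 0 else (p if p == 1 else 0.0)
    dc_dw = x / d - c * w / (nw * dw_)
    dc_dq = -c * (nw + nx + 2 * q) / d
    ds_dp = s * np.log(np.abs(c)) if c != 0 else 0.0
    return ds_dc * dc_dw, float(ds_dc * dc_dq), float(ds_dp)


def _sliding_windows(arr: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(h', w', k, k, D) view of all k x k spatial windows at the stride."""
    win = np.lib.stride_tricks.sliding_window_view(arr, (k, k), axis=(0, 1))
    return win[::stride, ::stride].transpose(0, 1, 3, 4, 2)


def scs_layer_forward(window_stack: np.ndarray, config: SCSLayerConfig,
                      kernels: list[SCSKernel]) -> np.ndarray:
    """Slide every kernel over a (h, w, D) input; return (h', w', n_units).

    Output spatial dims follow valid-convolution arithmetic,
    ``h' = (h - k) // stride + 1``. There is no bias and no activation — the
    normalized score is the feature.
    """
    arr = np.asarray(window_stack, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError(f"input must be (h, w, D); got shape {arr.shape}")
    h, w, D = arr.shape
    k = config.kernel_size
    if k > min(h, w):
        raise ValueError(f"kernel_size {k} exceeds spatial dims {(h, w)}")
    expected = (k, k, D)
    for i, kern in enumerate(kernels):
        if kern.w.shape != expected:
            raise ValueError(
                f"kernel {i} has shape {kern.w.shape}, expected {expected}"
            )
    wins = _sliding_windows(arr, k, config.stride)  # (h', w', k, k, D)
    hp, wp = wins.shape[:2]
    flat = wins.reshape(hp, wp, -1)
    out = np.empty((hp, wp, len(kernels)))
    xnorm = np.linalg.norm(flat, axis=-1)
    for u, kern in enumerate(kernels):
        wv = kern.w.ravel()
        if config.q_mode == "componentwise":
            dn = np.linalg.norm(flat + kern.q, axis=-1) * np.linalg.norm(wv + kern.q)
        else:
            dn = (xnorm + kern.q) * (np.linalg.norm(wv) + kern.q)
        if np.any(dn == 0):
            raise ValueError("undefined cosine in layer: zero-norm window with q = 0")
        c = flat @ wv / dn
        out[:, :, u] = np.sign(c) * np.abs(c) ** kern.p
    return out


def abs_max_pool(feature_map: np.ndarray, window: int,
                 stride: int | None = None) -> np.ndarray:
    """Pool by keeping the signed entry of largest |value| per window.

    Works on (h, w) or (h, w, C) maps; channels pool independently. Ties go to
    the first element in row-major window order.
    """
    fm = np.asarray(feature_map, dtype=np.float64)
    squeeze = fm.ndim == 2
    if squeeze:
        fm = fm[:, :, None]
    if fm.ndim != 3:
        raise ValueError(f"feature map must be 2-D or 3-D; got {fm.shape}")
    h, w, C = fm.shape
    if window > min(h, w):
        raise ValueError(f"pool window {window} exceeds spatial dims {(h, w)}")
    stride = window if stride is None else stride
    wins = _sliding_windows(fm, window, stride)  # (h', w', win, win, C)
    hp, wp = wins.shape[:2]
    flat = wins.reshape(hp, wp, window * window, C)
    idx = np.argmax(np.abs(flat), axis=2)  # first max in row-major order
    pooled = np.take_along_axis(flat, idx[:, :, None, :], axis=2)[:, :, 0, :]
    return pooled[:, :, 0] if squeeze else pooled
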