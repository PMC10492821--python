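"""Reference image-similarity metrics: MSE, PSNR and SSIM.

These are the classical fidelity measures against which the
information-based MSR scores are benchmarked.  PSNR is a monotone
transform of the mean-squared error; SSIM compares local luminance,
contrast and structure over Gaussian-weighted patches.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, Optional

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["MetricResult", "mse", "psnr", "ssim", "default_delta"]


@dataclass(frozen=True)
class MetricResult:
    name: str
    value: float
    params: Dict = dc_field(default_factory=dict)


def _check_pair(x, y) -> tuple:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"image shapes differ: {x.shape} vs {y.shape}")
    return x, y


def default_delta(image) -> float:
    """Dynamic range: 255 for 8-bit integers, 65535 for 16-bit, 1.0 for floats."""
    arr = np.asarray(image)
    if np.issubdtype(arr.dtype, np.integer):
        return float(np.iinfo(arr.dtype).max)
    return 1.0


def mse(x, y) -> float:
    """Mean squared pixel difference on the native intensity scale."""
    x, y = _check_pair(x, y)
    return float(np.mean((x - y) ** 2))


def psnr(x, y, delta: Optional[float] = None) -> float:
    """Peak signal-to-noise ratio, 10 log10(delta^2 / MSE), in dB.

    ``delta`` is the signal range (255 for 8-bit by default); identical
    images return the +inf sentinel.
    """
    if delta is None:
        delta = default_delta(x)
    if delta <= 0:
        raise ValueError("dynamic range delta must be positive")
    err = mse(x, y)
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(delta ** 2 / err))


def ssim(
    x,
    y,
    window_size: int = 11,
    window_sigma: float = 1.5,
    K1: float = 0.01,
    K2: float = 0.03,
    delta: Optional[float] = None,
) -> float:
    """Mean structural similarity with Gaussian-weighted 11x11 windows.

    Standard stabilizers C1 = (K1*delta)^2, C2 = (K2*delta)^2; result in
    [-1, 1] with 1 iff the images are identical.
    """
    x, y = _check_pair(x, y)
    if delta is None:
        delta = default_delta(np.asarray(x))
    if min(x.shape) < window_size:
        raise ValueError(f"images smaller than the {window_size}x{window_size} window")
    return float(
        structural_similarity(
            x, y,
            win_size=window_size,
            gaussian_weights=True,
            sigma=window_sigma,
            use_sample_covariance=False,
            K1=K1, K2=K2,
            data_range=delta,
        )
    )
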