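"""Image compression into discrete samples: segmentation and coarse-graining.

A grayscale image ``h(r)`` on an ``N_X x N_Y`` lattice is a sample of
``N = N_X * N_Y`` unique (position, intensity) points — full
undersampling.  Two lossy steps make the sample's multiplicity structure
non-trivial:

1. **segmentation** — binarise at a quantile threshold ``a`` so that
   exactly ``round(a * N)`` of the darkest pixels become black;
2. **coarse-graining** — replace each pixel coordinate by the index of
   its cell on a square grid of step ``ell``.

The compressed sample ``S^ell_a = {(r^ell, color)}`` then has state
multiplicities ``k_(cell, black)`` and ``k_(cell, white)``, from which
resolution and relevance follow (:mod:`msrelevance.relevance`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np

from .relevance import CountVector, RRPoint, rr_entropies

__all__ = [
    "BinaryImage",
    "CompressedSample",
    "segment",
    "segmentation_ranks",
    "coarse_grain",
    "rr_point",
    "rr_curve",
]


class InvalidScaleError(ValueError):
    pass


def as_gray(image) -> np.ndarray:
    """Validate and return a 2-D finite grayscale lattice."""
    arr = np.asarray(image)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a non-empty 2-D grayscale image, got shape {arr.shape}")
    if not np.all(np.isfinite(arr.astype(float))):
        raise ValueError("image contains non-finite values")
    return arr


@dataclass(frozen=True)
class BinaryImage:
    """Binary (black/white) image; ``pixels`` is True where black.

    ``a`` is the *realized* black fraction, exactly
    ``round(a_requested * N) / N`` by the segmentation contract.
    """

    pixels: np.ndarray
    a: float

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    @property
    def N(self) -> int:
        return self.pixels.size


@dataclass(frozen=True)
class CompressedSample:
    """Per-(cell, color) multiplicities of a coarse-grained binary image."""

    scale: int
    black: np.ndarray  # black pixel count per cell (flat cell order)
    white: np.ndarray  # white pixel count per cell
    N: int

    @property
    def n_cells(self) -> int:
        return int(self.black.size)

    def counts(self) -> CountVector:
        """All positive (cell, color) multiplicities as one count vector."""
        k = np.concatenate([self.black[self.black > 0], self.white[self.white > 0]])
        return CountVector(k)

    def as_dict(self) -> Dict[Tuple[int, str], int]:
        d: Dict[Tuple[int, str], int] = {}
        for i, (b, w) in enumerate(zip(self.black, self.white)):
            if b:
                d[(i, "b")] = int(b)
            if w:
                d[(i, "w")] = int(w)
        return d


def segmentation_ranks(image, tie_seed: int = 0) -> np.ndarray:
    """Darkness rank of every pixel, ties broken by a seeded shuffle.

    Returns a flat array ``rank`` such that the black set at threshold
    ``a`` is exactly ``rank < round(a * N)``.  Ranks are stable across
    thresholds, so black sets are nested in ``a``.
    """
    arr = as_gray(image)
    flat = arr.ravel().astype(float)
    rng = np.random.default_rng(tie_seed)
    jitter = rng.random(flat.size)
    order = np.lexsort((jitter, flat))  # ascending intensity, seeded ties
    rank = np.empty(flat.size, dtype=np.int64)
    rank[order] = np.arange(flat.size)
    return rank


def segment(image, a: float, tie_seed: int = 0) -> BinaryImage:
    """Binarise ``image`` so exactly ``round(a*N)`` darkest pixels are black.

    Ties at the cut intensity are resolved by a seeded uniform choice
    among the tied pixels, so the realized black fraction is exact even
    on quantized histograms with large flat regions.  Deterministic
    given ``(image, a, tie_seed)``.
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"threshold a must lie in [0, 1], got {a}")
    arr = as_gray(image)
    n_black = int(round(a * arr.size))
    rank = segmentation_ranks(arr, tie_seed)
    pixels = (rank < n_black).reshape(arr.shape)
    return BinaryImage(pixels=pixels, a=n_black / arr.size)


def cell_index(shape: Tuple[int, int], ell: int) -> Tuple[np.ndarray, int]:
    """Flat cell id of every pixel for grid step ``ell`` (top-left anchored).

    Cell (i, j) covers rows ``[i*ell, (i+1)*ell)`` and columns likewise,
    0-based half-open; boundary cells may be partial.
    """
    ny, nx = shape
    if ell < 1:
        raise InvalidScaleError(f"grid step must be >= 1, got {ell}")
    rows = np.arange(ny) // ell
    cols = np.arange(nx) // ell
    ncols = cols[-1] + 1
    idx = (rows[:, None] * ncols + cols[None, :]).ravel()
    n_cells = int((rows[-1] + 1) * ncols)
    return idx, n_cells


def coarse_grain(binary: BinaryImage, ell: int) -> CompressedSample:
    """Count black/white pixels per grid cell of step ``ell``."""
    ell = int(ell)
    if ell < 1 or ell > max(binary.shape):
        raise InvalidScaleError(
            f"grid step {ell} outside [1, {max(binary.shape)}]"
        )
    idx, n_cells = cell_index(binary.shape, ell)
    flat = binary.pixels.ravel()
    black = np.bincount(idx[flat], minlength=n_cells)
    total = np.bincount(idx, minlength=n_cells)
    return CompressedSample(scale=ell, black=black, white=total - black, N=binary.N)


def rr_point(binary: BinaryImage, ell: int) -> RRPoint:
    """Resolution/relevance of the compressed sample at grid step ``ell``."""
    return rr_entropies(coarse_grain(binary, ell).counts())


def rr_curve(binary: BinaryImage, scales: Sequence[int]) -> "RRCurve":
    """Resolution/relevance trajectory over a set of grid steps.

    For nested (divisor-chain or dyadic) scale sets the resolution is
    monotonically non-increasing in ``ell``; arbitrary integer scales
    are accepted but need not be exactly monotone.
    """
    from .multiscale import RRCurve  # cyclic at type level only

    scales = [int(s) for s in scales]
    if not scales:
        raise ValueError("scale set must be non-empty")
    points = [(ell, rr_point(binary, ell)) for ell in scales]
    return RRCurve(points=points, N=binary.N)
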