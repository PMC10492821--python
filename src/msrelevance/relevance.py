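"""Resolution and relevance entropies of a compressed sample.

A compressed sample of ``N`` data points is summarised by its state
multiplicities ``k_s`` (how many points fall in each occupied state).
Two Shannon entropies, both in bits, characterise it:

* **resolution** ``H[s]`` — entropy of the empirical state distribution
  ``{k_s / N}``; the average number of bits needed to code a state label.
* **relevance** ``H[k]`` — entropy of ``{k * m_k / N}`` where ``m_k`` is
  the number of states observed exactly ``k`` times (the frequency of
  frequencies); the information carried by the histogram heights alone,
  once state labels are dropped.

Relevance can never exceed resolution: the multiplicity distribution is a
lossy compression of the state distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable

import numpy as np

__all__ = [
    "CountVector",
    "RRPoint",
    "degeneracy",
    "resolution",
    "relevance",
    "rr_entropies",
]

# entropies within this distance of zero are snapped to exactly 0.0
_ZERO_SNAP = 1e-15


class InvalidSampleError(ValueError):
    """Raised when a count vector is empty or otherwise not a valid sample."""


@dataclass(frozen=True)
class CountVector:
    """Multiset of positive state multiplicities ``{k_s}``.

    Zero counts are dropped at construction: an unoccupied state
    contributes to neither entropy.
    """

    counts: np.ndarray
    N: int = field(init=False)

    def __init__(self, counts: Iterable[int]):
        arr = np.asarray(list(counts) if not isinstance(counts, np.ndarray) else counts)
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise InvalidSampleError("counts must be integers")
            arr = np.round(arr).astype(np.int64)
        arr = arr.astype(np.int64, copy=False)
        if np.any(arr < 0):
            raise InvalidSampleError("counts must be non-negative")
        arr = arr[arr > 0]
        if arr.size == 0:
            raise InvalidSampleError("empty sample: no positive counts")
        object.__setattr__(self, "counts", arr)
        object.__setattr__(self, "N", int(arr.sum()))

    def __len__(self) -> int:  # number of occupied states
        return int(self.counts.size)


@dataclass(frozen=True)
class RRPoint:
    """One (resolution, relevance) pair, in bits, at a given scale."""

    resolution: float
    relevance: float

    def __post_init__(self):
        if self.relevance > self.resolution + 1e-9:
            raise ValueError(
                f"relevance {self.relevance} exceeds resolution {self.resolution}"
            )


def _as_countvector(counts) -> CountVector:
    return counts if isinstance(counts, CountVector) else CountVector(counts)


def degeneracy(counts) -> Dict[int, int]:
    """Frequency-of-frequencies table ``{k: m_k}``.

    ``m_k`` is the number of states whose multiplicity equals ``k``;
    keys are restricted to ``k >= 1`` (zero-count states are entropy
    neutral and never stored).
    """
    cv = _as_countvector(counts)
    ks, ms = np.unique(cv.counts, return_counts=True)
    return {int(k): int(m) for k, m in zip(ks, ms)}


def _entropy_bits(weights: np.ndarray, N: int) -> float:
    """Shannon entropy (bits) of the distribution weights/N; 0 log 0 := 0."""
    w = weights[weights > 0].astype(float)
    p = w / N
    h = float(-(p * np.log2(p)).sum())
    if abs(h) < _ZERO_SNAP:
        h = 0.0
    return h


def resolution(counts) -> float:
    """Resolution ``H[s] = -sum_s (k_s/N) log2 (k_s/N)`` in bits."""
    cv = _as_countvector(counts)
    return _entropy_bits(cv.counts, cv.N)


def relevance(counts) -> float:
    """Relevance ``H[k] = -sum_k (k m_k/N) log2 (k m_k/N)`` in bits."""
    cv = _as_countvector(counts)
    ks, ms = np.unique(cv.counts, return_counts=True)
    return _entropy_bits(ks * ms, cv.N)


def rr_entropies(counts) -> RRPoint:
    """Both entropies of a count vector as an :class:`RRPoint`."""
    cv = _as_countvector(counts)
    ks, ms = np.unique(cv.counts, return_counts=True)
    res = _entropy_bits(cv.counts, cv.N)
    rel = _entropy_bits(ks * ms, cv.N)
    # numerically rel <= res always holds analytically; guard rounding
    if rel > res:
        rel = res
    return RRPoint(resolution=res, relevance=rel)
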