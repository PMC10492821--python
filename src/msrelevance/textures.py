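"""Synthetic 1/f^alpha Gaussian random textures.

Fields are synthesised by spectral filtering: seeded Gaussian white noise
is transformed to Fourier space, multiplied by the radial power-law
filter ``f^(-alpha)``, and transformed back.  The power spectrum then
decays as ``1/f^(2*alpha)``.  Roughness is parametrised by the Hurst
exponent ``H = alpha - d/2`` (d = 2 here, so ``alpha = 1 + H``):

* ``H < 0``  — stationary field, correlations ``C(dr) ~ dr^(2H)``;
  ``H = -1`` is unfiltered white noise.
* ``H > 0``  — non-stationary with stationary increments,
  ``<[h(r+dr) - h(r)]^2> ~ dr^(2H)`` (fractional-Brownian-like).

Synthesis is periodic on the lattice; no correction is applied for the
finite-size non-stationarity at H > 0.  Fields sharing a seed share the
underlying white-noise draw across H values, so roughness families can
be compared realisation by realisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Tuple

import numpy as np
import pandas as pd

__all__ = [
    "FieldSpec",
    "Field",
    "generate_field",
    "azimuthal_spectrum",
    "fit_spectral_exponent",
    "quantile_map",
]


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of a 1/f^alpha Gaussian field: roughness H, lattice size, seed."""

    H: float
    size: Tuple[int, int] = (256, 256)
    seed: int = 0

    @property
    def alpha(self) -> float:
        """Spectral filter exponent, alpha = H + d/2 with d = 2."""
        return self.H + 1.0

    def __post_init__(self):
        ny, nx = self.size
        if ny < 16 or nx < 16:
            raise ValueError(f"lattice must be at least 16x16, got {self.size}")
        if not np.isfinite(self.H):
            raise ValueError("H must be finite")


@dataclass(frozen=True)
class Field:
    """A generated real-valued lattice, centered to zero mean."""

    values: np.ndarray
    spec: FieldSpec


def _radial_frequency(shape: Tuple[int, int]) -> np.ndarray:
    """Euclidean modulus of the integer frequency vector (periodic convention)."""
    ny, nx = shape
    fy = np.fft.fftfreq(ny) * ny
    fx = np.fft.fftfreq(nx) * nx
    return np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)


def generate_field(spec: FieldSpec) -> Field:
    """Synthesise a 1/f^alpha Gaussian field from seeded white noise.

    The white-noise draw depends only on ``(seed, size)``, never on H:
    fields of different roughness from one seed are filtered versions of
    the same underlying noise.  The zero-frequency mode is removed, so
    the output has (numerically) zero mean.
    """
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal(spec.size)
    F = np.fft.fft2(noise)
    f = _radial_frequency(spec.size)
    with np.errstate(divide="ignore"):
        filt = np.where(f > 0, f ** (-spec.alpha), 0.0)
    out = np.fft.ifft2(F * filt).real
    out = out - out.mean()
    return Field(values=out, spec=spec)


def power_spectrum(values: np.ndarray) -> np.ndarray:
    """2-D power spectrum |FT h|^2 / N (Parseval: sums to sum h^2)."""
    F = np.fft.fft2(values)
    return (F * F.conj()).real / values.size


def azimuthal_spectrum(field) -> pd.DataFrame:
    """Azimuthally averaged power spectrum.

    |FT|^2/N is binned into unit-width radial annuli (nearest-integer
    frequency modulus) and averaged per annulus; the zero mode is
    excluded.  Returns a table with columns ``f``, ``S_mean``,
    ``n_modes``.
    """
    values = field.values if isinstance(field, Field) else np.asarray(field)
    S = power_spectrum(values)
    f = _radial_frequency(values.shape)
    annulus = np.round(f).astype(int).ravel()
    s = S.ravel()
    mask = f.ravel() > 0  # drop the DC mode only
    annulus, s = annulus[mask], s[mask]
    n = np.bincount(annulus)
    tot = np.bincount(annulus, weights=s)
    fs = np.flatnonzero(n)
    return pd.DataFrame({"f": fs, "S_mean": tot[fs] / n[fs], "n_modes": n[fs]})


def fit_spectral_exponent(spectrum: pd.DataFrame, f_band: Tuple[float, float]) -> float:
    """Least-squares slope of log S_mean vs log f inside ``f_band``.

    For a 1/f^alpha field the expected slope is -2*alpha = -2*(1 + H).
    """
    lo, hi = f_band
    sel = spectrum[(spectrum["f"] >= lo) & (spectrum["f"] <= hi)]
    sel = sel[sel["S_mean"] > 0]
    if len(sel) < 8:
        raise ValueError(f"frequency band {f_band} contains fewer than 8 annuli")
    slope, _ = np.polyfit(np.log(sel["f"].to_numpy()), np.log(sel["S_mean"].to_numpy()), 1)
    return float(slope)


def quantile_map(field, levels: int = 255) -> np.ndarray:
    """Rank-transform a real field onto equal-population integer levels.

    Each of the ``levels`` output values 0..levels-1 receives N/levels
    pixels (within one); ties are broken by stable scan order, so any
    strictly increasing remapping of the field gives an identical image.
    """
    if levels < 2:
        raise ValueError("need at least 2 levels")
    values = field.values if isinstance(field, Field) else np.asarray(field)
    flat = values.ravel()
    if float(np.ptp(flat)) == 0.0:
        warnings.warn("constant field: quantile map is degenerate (all mid-level)")
        return np.full(values.shape, (levels - 1) // 2, dtype=np.uint16)
    order = np.argsort(flat, kind="stable")
    rank = np.empty(flat.size, dtype=np.int64)
    rank[order] = np.arange(flat.size)
    out = (rank * levels) // flat.size
    return out.reshape(values.shape).astype(np.uint16)
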