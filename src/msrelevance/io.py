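"""Image and table I/O, provenance-carrying exports, and fixture generation."""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Dict, List, Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .compression import BinaryImage, cell_index
from .multiscale import MSRProfile, RRCurve
from .processing import CalibrationResult, add_gaussian_noise
from .textures import Field, FieldSpec, generate_field, quantile_map

__all__ = [
    "read_image",
    "write_image",
    "curve_to_frame",
    "write_curve",
    "write_profile",
    "write_calibration",
    "read_calibration",
    "make_fixtures",
]


class ImageIOError(IOError):
    pass


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF image as a 2-D grayscale lattice.

    Multi-channel input is converted by averaging the color channels
    (luminance average) with a warning; bit depth is preserved via the
    array dtype.
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such image file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # unreadable or unsupported format
        raise ImageIOError(f"cannot read {path} ({path.suffix or 'unknown format'}): {exc}")
    if arr.ndim == 3:
        warnings.warn(f"{path.name}: multi-channel image converted by luminance average")
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2:
        raise ImageIOError(f"{path}: expected a 2-D grayscale image, got shape {arr.shape}")
    return arr


def write_image(path, image: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        iio.imwrite(path, np.asarray(image))
    except Exception as exc:
        raise ImageIOError(f"cannot write {path}: {exc}")


def curve_to_frame(curve: RRCurve, shape=None) -> pd.DataFrame:
    """RR curve as a table: ell, n_cells, raw and normalized entropies."""
    res, rel = curve.arrays(normalized=False)
    hmax = np.log2(curve.N)
    n_cells: List[Optional[int]] = []
    for ell in curve.scales:
        if shape is not None:
            n_cells.append(cell_index(shape, int(ell))[1])
        else:
            n_cells.append(None)
    return pd.DataFrame({
        "ell": curve.scales,
        "n_cells": n_cells,
        "resolution_bits": res,
        "relevance_bits": rel,
        "resolution_norm": res / hmax,
        "relevance_norm": rel / hmax,
    })


def write_curve(path, curve: RRCurve, shape=None, config: Optional[Dict] = None) -> None:
    df = curve_to_frame(curve, shape=shape)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    if config is not None:
        Path(path).with_suffix(".json").write_text(json.dumps(config, indent=2))


def write_profile(path, profile: MSRProfile, config: Optional[Dict] = None) -> None:
    """MSR(a) profile as CSV (a, msr, is_max) plus a JSON sidecar with metadata."""
    is_max = np.isin(np.round(profile.a_grid, 10), np.round(profile.maxima, 10))
    df = pd.DataFrame({"a": profile.a_grid, "msr": profile.msr_values, "is_max": is_max})
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    meta = {"maxima": profile.maxima, "flat": profile.flat, **profile.meta}
    if config is not None:
        meta["config"] = config
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def write_calibration(path, result: CalibrationResult) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(result.to_dict(), indent=2))


def read_calibration(path) -> CalibrationResult:
    return CalibrationResult.from_dict(json.loads(Path(path).read_text()))


def _write_field(outdir: Path, name: str, field: Field) -> None:
    img = quantile_map(field, levels=65535)
    write_image(outdir / f"{name}.tiff", img.astype(np.uint16))
    sidecar = {"H": field.spec.H, "size": list(field.spec.size),
               "seed": field.spec.seed, "alpha": field.spec.alpha,
               "levels": 65535}
    (outdir / f"{name}.json").write_text(json.dumps(sidecar, indent=2))


def make_fixtures(kind: str, seed: int = 0, outdir="fixtures", size=(256, 256)) -> List[Path]:
    """Deterministic reference inputs used across examples and tests.

    kinds: ``texture-set`` (three fields, H in {-0.5, 0, 0.5}, one shared
    noise seed), ``checkerboard`` (4x4 parity lattice), ``step-edge``
    (half black, half white), ``noisy-texture`` (clean + sigma=100
    8-bit Gaussian-noise pair).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    if kind == "texture-set":
        for H in (-0.5, 0.0, 0.5):
            field = generate_field(FieldSpec(H=H, size=size, seed=seed))
            name = f"texture_H{H:+.1f}_seed{seed}"
            _write_field(outdir, name, field)
            written += [outdir / f"{name}.tiff", outdir / f"{name}.json"]
    elif kind == "checkerboard":
        board = (np.add.outer(np.arange(4), np.arange(4)) % 2 * 255).astype(np.uint8)
        p = outdir / "checkerboard4.png"
        write_image(p, board)
        written.append(p)
    elif kind == "step-edge":
        ny, nx = size
        edge = np.zeros((ny, nx), dtype=np.uint8)
        edge[:, nx // 2:] = 255
        p = outdir / "step_edge.png"
        write_image(p, edge)
        written.append(p)
    elif kind == "noisy-texture":
        field = generate_field(FieldSpec(H=0.0, size=size, seed=seed))
        clean = (quantile_map(field, levels=256)).astype(np.uint8)
        noisy = add_gaussian_noise(clean, sigma=100.0, seed=seed).astype(np.uint8)
        p_clean, p_noisy = outdir / "texture_clean.png", outdir / "texture_noisy.png"
        write_image(p_clean, clean)
        write_image(p_noisy, noisy)
        written += [p_clean, p_noisy]
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return written
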