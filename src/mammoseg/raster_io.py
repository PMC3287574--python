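"""Grayscale raster I/O, quantization and downsampling.

Grid conventions used throughout the package:

* images are 2-D :class:`numpy.ndarray` in ``(row, col)`` order, 0-based,
  row-major, with pixel ``(0, 0)`` at the top-left;
* 8-bit unsigned integers at the I/O boundary, floats during processing;
* binary masks are 2-D ``uint8`` arrays of {0, 1}, written to disk as
  {0, 255} PNG so they are viewable.

Rounding convention for every float -> 8-bit conversion in the package is
half-away-from-zero (so 127.5 -> 128), stated here once and reused by the
metrics report.
"""

from __future__ import annotations

import os

import imageio.v3 as iio
import numpy as np

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "quantize_to_256",
    "downsample",
    "downsample_mask",
    "round_half_away",
]


def round_half_away(values: np.ndarray | float, decimals: int = 0) -> np.ndarray | float:
    """Round half-away-from-zero (0.5 -> 1, -0.5 -> -1), elementwise."""
    arr = np.asarray(values, dtype=float)
    scale = 10.0 ** decimals
    out = np.sign(arr) * np.floor(np.abs(arr) * scale + 0.5) / scale
    if np.isscalar(values) or np.ndim(values) == 0:
        return float(out)
    return out


def _to_uint8(image: np.ndarray) -> np.ndarray:
    return np.clip(round_half_away(image), 0, 255).astype(np.uint8)


def read_image(path: str | os.PathLike) -> np.ndarray:
    """Read a raster file as an 8-bit grayscale image.

    Single-channel rasters are returned as-is (16-bit inputs are linearly
    requantized to 256 gray levels); RGB(A) inputs are collapsed by the
    unweighted mean of the first three channels.

    Raises
    ------
    OSError
        If the file is missing or cannot be decoded.
    ValueError
        If the decoded image has no pixels.
    """
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder errors vary by plugin
        raise OSError(f"cannot read image file {os.fspath(path)!r}: {exc}") from exc
    raw = np.asarray(raw)
    if raw.ndim == 3:
        raw = raw[..., :3].mean(axis=2)
    if raw.ndim != 2:
        raise ValueError(f"{os.fspath(path)!r}: expected a 2-D grayscale or RGB image, "
                         f"got shape {raw.shape}")
    if raw.size == 0:
        raise ValueError(f"{os.fspath(path)!r}: image has no pixels")
    arr = raw.astype(float)
    if arr.min() < 0 or arr.max() > 255:
        return quantize_to_256(arr)
    return _to_uint8(arr)


def write_image(path: str | os.PathLike, image: np.ndarray) -> None:
    """Write a grayscale image as 8-bit PNG/TIFF/PGM (chosen by extension)."""
    arr = np.asarray(image)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("image must be a nonempty 2-D array")
    iio.imwrite(path, _to_uint8(arr))


def read_mask(path: str | os.PathLike) -> np.ndarray:
    """Read a binary mask stored as an image; any nonzero pixel counts as 1."""
    return (read_image(path) > 0).astype(np.uint8)


def write_mask(path: str | os.PathLike, mask: np.ndarray) -> None:
    """Write a {0,1} mask as a {0,255} image."""
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError("mask must be a 2-D array")
    iio.imwrite(path, ((arr > 0) * np.uint8(255)))


def quantize_to_256(image: np.ndarray) -> np.ndarray:
    """Linearly map an arbitrary intensity range onto the 256 gray levels.

    ``[min, max]`` maps to ``[0, 255]`` with half-away-from-zero rounding; a
    constant image maps to all zeros.
    """
    arr = np.asarray(image, dtype=float)
    if arr.size == 0:
        raise ValueError("image has no pixels")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite intensities")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    return _to_uint8((arr - lo) * (255.0 / (hi - lo)))


def downsample(image: np.ndarray, factor: int = 4) -> np.ndarray:
    """Block-mean downsample by an integer factor.

    Each output pixel is the mean over a ``factor x factor`` tile; trailing
    partial tiles are averaged over the pixels they actually contain.
    ``factor=1`` is the identity. Integer input comes back rounded
    half-away-from-zero as ``uint8``; float input stays float.
    """
    arr = np.asarray(image)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("image must be a nonempty 2-D array")
    if int(factor) != factor or factor < 1:
        raise ValueError(f"downsample factor must be an integer >= 1, got {factor!r}")
    factor = int(factor)
    if factor == 1:
        return arr.copy()
    h, w = arr.shape
    rows = np.arange(0, h, factor)
    cols = np.arange(0, w, factor)
    sums = np.add.reduceat(np.add.reduceat(arr.astype(float), rows, axis=0), cols, axis=1)
    rcount = np.minimum(rows + factor, h) - rows
    ccount = np.minimum(cols + factor, w) - cols
    means = sums / np.outer(rcount, ccount)
    if np.issubdtype(arr.dtype, np.integer):
        return _to_uint8(means)
    return means


def downsample_mask(mask: np.ndarray, factor: int = 4) -> np.ndarray:
    """Majority-vote downsample of a {0,1} mask (ties go to foreground)."""
    arr = (np.asarray(mask) > 0).astype(float)
    frac = downsample(arr, factor)
    return (frac >= 0.5).astype(np.uint8)
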