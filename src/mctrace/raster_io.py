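"""Section image I/O, maximum-intensity projection, and the mean-pyramid representation.

A whole-brain dataset is an ordered stack of coronal sections imaged as
grayscale rasters (8- or 16-bit).  Slide scanners acquire several virtual
Z-planes per section which are collapsed to a single maximum-intensity
projection before any analysis.  For viewing and coarse-scale processing each
section also carries a multi-resolution pyramid: level 0 is the raw raster and
each subsequent level is the non-overlapping 2x2 block mean of the previous
one (window M x N = 2 x 2, stride 2), so pixel size doubles per level.

Coordinates are 0-based ``(row, col)`` with row 0 at the image top; a pixel's
physical position is ``index * pixel_size`` micrometers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile


class FormatError(ValueError):
    """Raised for unreadable or inconsistent image inputs."""


@dataclass
class SectionImage:
    """One coronal section: intensity raster plus physical metadata.

    Parameters
    ----------
    pixels : ndarray
        2D grayscale raster, non-negative, values within the bit depth.
    bit_depth : int
        8 or 16.
    pixel_size : float
        Micrometers per pixel (isotropic), > 0.
    thickness : float
        Section thickness in micrometers (typically 100), > 0.
    rc_index : int
        0-based rostro-caudal position (rostral = 0).
    """

    pixels: np.ndarray
    bit_depth: int = 8
    pixel_size: float = 4.0
    thickness: float = 100.0
    rc_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise FormatError(f"section raster must be 2D, got {self.pixels.ndim}D")
        if self.bit_depth not in (8, 16):
            raise FormatError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.thickness <= 0:
            raise ValueError("thickness must be > 0")
        if self.pixels.size and self.pixels.min() < 0:
            raise ValueError("pixel intensities must be non-negative")
        if self.pixels.size and self.pixels.max() > self.max_gray:
            raise ValueError(
                f"pixel intensities exceed 2^{self.bit_depth} - 1 = {self.max_gray}"
            )

    @property
    def max_gray(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class PyramidRepresentation:
    """Mean pyramid of a section: levels[0] is the source raster."""

    levels: list[np.ndarray]
    factor_m: int = 2
    factor_n: int = 2
    pixel_size: float = 4.0

    @property
    def max_level(self) -> int:
        return len(self.levels) - 1

    def pixel_size_at(self, level: int) -> float:
        """Physical pixel size (um) at a pyramid level; doubles per level."""
        return self.pixel_size * (self.factor_m ** level)


def max_project(planes: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Collapse equally-shaped Z-planes to a per-pixel maximum-intensity projection."""
    planes = [np.asarray(p) for p in planes]
    if len(planes) == 0:
        raise ValueError("need at least one plane")
    shape = planes[0].shape
    for p in planes[1:]:
        if p.shape != shape:
            raise FormatError(f"plane shape mismatch: {p.shape} != {shape}")
    out = planes[0].copy()
    for p in planes[1:]:
        np.maximum(out, p, out=out)
    return out


def _bit_depth_of(arr: np.ndarray, path: str) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    raise FormatError(f"{path}: unsupported dtype {arr.dtype} (need uint8/uint16)")


def read_section_stack(
    paths: list,
    pixel_size: float = 4.0,
    thickness: float = 100.0,
) -> list[SectionImage]:
    """Read an ordered list of TIFF files into SectionImages.

    Files holding several pages/planes (a virtual Z-stack) are collapsed to a
    maximum-intensity projection.  ``rc_index`` is assigned in list order,
    rostral first.  All files must share one bit depth.
    """
    sections: list[SectionImage] = []
    depth: int | None = None
    for idx, path in enumerate(paths):
        try:
            arr = tifffile.imread(str(path))
        except (OSError, ValueError) as exc:
            raise IOError(f"cannot read section image {path!s}: {exc}") from exc
        d = _bit_depth_of(np.asarray(arr), str(path))
        if depth is None:
            depth = d
        elif d != depth:
            raise FormatError(
                f"mixed bit depths in stack: {path!s} is {d}-bit, expected {depth}-bit"
            )
        arr = np.asarray(arr)
        if arr.ndim == 3:
            arr = max_project(list(arr))
        elif arr.ndim != 2:
            raise FormatError(f"{path!s}: expected 2D or 3D raster, got {arr.ndim}D")
        sections.append(
            SectionImage(arr, bit_depth=d, pixel_size=pixel_size,
                         thickness=thickness, rc_index=idx)
        )
    return sections


def write_section(path, section: SectionImage) -> None:
    """Write a section raster as TIFF at its native bit depth."""
    dtype = np.uint8 if section.bit_depth == 8 else np.uint16
    tifffile.imwrite(str(path), np.clip(np.rint(section.pixels), 0,
                                        section.max_gray).astype(dtype))


def _block_mean(level: np.ndarray, m: int = 2, n: int = 2) -> np.ndarray:
    # Edge-replicate pad odd dimensions so the trailing row/col participates.
    h, w = level.shape
    ph, pw = (-h) % m, (-w) % n
    if ph or pw:
        level = np.pad(level, ((0, ph), (0, pw)), mode="edge")
    h, w = level.shape
    return level.reshape(h // m, m, w // n, n).mean(axis=(1, 3))


def build_pyramid(section: SectionImage, max_level: int) -> PyramidRepresentation:
    """Build the mean pyramid: level 0 is the source, each level the stride-2
    2x2 block mean of the previous.  Levels stop early once a 1x1 raster is
    reached.  Values are kept at floating precision; quantize only on export.
    """
    if max_level < 0:
        raise ValueError(f"max_level must be >= 0, got {max_level}")
    levels = [np.asarray(section.pixels)]
    for _ in range(max_level):
        prev = levels[-1]
        if prev.shape == (1, 1):
            break
        levels.append(_block_mean(prev.astype(float)))
    return PyramidRepresentation(levels, pixel_size=section.pixel_size)


def write_pyramid(path_prefix, pyramid: PyramidRepresentation, bit_depth: int = 8) -> list:
    """Write each pyramid level as ``<prefix>_l{level}.tif``; returns the paths."""
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    hi = (1 << bit_depth) - 1
    paths = []
    for lvl, arr in enumerate(pyramid.levels):
        p = f"{path_prefix}_l{lvl}.tif"
        tifffile.imwrite(p, np.clip(np.rint(arr), 0, hi).astype(dtype))
        paths.append(p)
    return paths
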