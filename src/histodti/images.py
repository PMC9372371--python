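"""Micrograph container and image I/O helpers."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["Micrograph", "read_micrograph", "write_micrograph", "read_mask", "write_mask"]


@dataclass
class Micrograph:
    """A single-channel 8-bit micrograph with its pixel size in micrometres."""

    pixels: np.ndarray  # 2D uint8
    pixel_size: float  # um / pixel

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"micrograph must be 2D single-channel, got ndim={self.pixels.ndim}")
        if self.pixels.dtype != np.uint8:
            raise ValueError(f"micrograph must be 8-bit, got dtype={self.pixels.dtype}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def pixel_area_um2(self) -> float:
        return self.pixel_size ** 2


def read_micrograph(path: str | Path, pixel_size: float) -> Micrograph:
    """Read a TIFF/PNG micrograph; multi-channel input is rejected."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        from imageio.v3 import imread

        arr = imread(path)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected single-channel image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit image, got {arr.dtype}")
    return Micrograph(arr, pixel_size)


def write_micrograph(path: str | Path, img: Micrograph) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img.pixels)
    else:
        from imageio.v3 import imwrite

        imwrite(path, img.pixels)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary/label mask image as a boolean array (nonzero = inside)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        from imageio.v3 import imread

        arr = imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: mask must be 2D, got shape {arr.shape}")
    return arr != 0


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))
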