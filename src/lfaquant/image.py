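"""Raster containers and PNG I/O.

A :class:`StripImage` is the raw unit of input: an H x W x 3 float array in
[0, 1] tagged with its color space ("srgb" for camera output, "linear"
after gamma decoding). A :class:`RectifiedStrip` is the strip resampled
into the canonical layout frame, always linear, carrying the homography
that produced it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

MIN_SIDE = 32


@dataclass
class StripImage:
    """RGB raster in [0, 1] with a color-space tag."""

    pixels: np.ndarray
    color_space: str = "srgb"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected H x W x 3 pixels, got shape {self.pixels.shape}")
        h, w = self.pixels.shape[:2]
        if h < MIN_SIDE or w < MIN_SIDE:
            raise ValueError(f"image too small ({h} x {w}); need at least {MIN_SIDE} px per side")
        if self.color_space not in ("srgb", "linear"):
            raise ValueError(f"unknown color space {self.color_space!r}")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < -1e-9 or hi > 1 + 1e-9:
            raise ValueError(f"pixel values outside [0, 1]: min {lo:.4g}, max {hi:.4g}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class RectifiedStrip:
    """Strip resampled to the canonical frame, in linear light.

    ``homography`` is the 3x3 source->canonical projective matrix acting on
    homogeneous (x, y, 1) = (col, row, 1) coordinates.
    """

    pixels: np.ndarray
    homography: np.ndarray
    color_space: str = "linear"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.homography = np.asarray(self.homography, dtype=float)
        if self.homography.shape != (3, 3):
            raise ValueError("homography must be 3 x 3")
        if abs(np.linalg.det(self.homography)) < 1e-12:
            raise ValueError("homography is singular")


def write_png(path: str | Path, img: StripImage) -> None:
    """Write an 8-bit RGB PNG (values are rounded to the nearest code)."""
    data = np.clip(np.round(img.pixels * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), data, extension=".png")


def read_png(path: str | Path, color_space: str = "srgb") -> StripImage:
    """Read a PNG/JPEG into a [0, 1] float raster (camera output is sRGB)."""
    data = np.asarray(iio.imread(Path(path)))
    if data.ndim == 2:
        data = np.repeat(data[:, :, None], 3, axis=2)
    data = data[:, :, :3]
    return StripImage(pixels=data.astype(float) / 255.0, color_space=color_space)


def write_sidecar(path: str | Path, payload: dict) -> None:
    """Write a ground-truth / record JSON sidecar with stable key order."""
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=2, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
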