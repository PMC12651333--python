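"""Canonical strip geometry and the physical models behind the synthetic renderer.

The cassette carries, along its long axis: a control line (C), a test line
(T) whose color develops with analyte concentration, and five printed
reference lines of known nominal signal R_k used for per-image multi-point
intensity calibration. A neutral (blank substrate) zone between T and the
ladder serves white-balance estimation.

All longitudinal positions are stored as fractions of the canonical strip
length so a layout is resolution independent; pixel windows are derived on
demand. Coordinates are 0-based (row, col) with the origin at top-left;
the strip's long axis runs along columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import DegeneratePoseError

LINE_IDS = ("C", "T", "ref1", "ref2", "ref3", "ref4", "ref5")
REF_IDS = LINE_IDS[2:]

_DEFAULT_CENTERS = {
    "C": 0.15,
    "T": 0.30,
    "ref1": 0.50,
    "ref2": 0.60,
    "ref3": 0.70,
    "ref4": 0.80,
    "ref5": 0.90,
}


@dataclass(frozen=True)
class StripLayout:
    """Geometry of the canonical strip and the nominal reference ladder.

    Parameters
    ----------
    canonical_width_px, canonical_height_px
        Size of the canonical (rectified) frame; width is the long axis.
    line_centers
        Longitudinal line centers as fractions of the length, keyed by
        line id ``C, T, ref1..ref5``.
    line_width_frac
        Width of every line window as a fraction of the length; must be
        smaller than the smallest gap between adjacent centers.
    neutral_zone
        Blank substrate rectangle ``(row0, row1, col0, col1)`` in fractions
        of height/length; must not overlap any line window.
    nominal_signals
        The ladder's nominal signals ``R_k``, strictly increasing,
        in arbitrary signal units.
    """

    canonical_width_px: int = 600
    canonical_height_px: int = 120
    line_centers: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_CENTERS))
    line_width_frac: float = 0.04
    neutral_zone: tuple[float, float, float, float] = (0.10, 0.90, 0.37, 0.47)
    nominal_signals: tuple[float, ...] = (10.0, 20.0, 40.0, 60.0, 80.0)

    def __post_init__(self) -> None:
        if set(self.line_centers) != set(LINE_IDS):
            raise ValueError(f"line_centers must have exactly the keys {LINE_IDS}")
        centers = sorted(self.line_centers.values())
        gaps = np.diff(centers)
        if not 0 < self.line_width_frac < gaps.min():
            raise ValueError("line_width_frac must be positive and below the minimum center gap")
        if len(self.nominal_signals) != len(REF_IDS):
            raise ValueError("need one nominal signal per reference line")
        if np.any(np.diff(self.nominal_signals) <= 0):
            raise ValueError("nominal signals R_k must be strictly increasing")
        r0, r1, c0, c1 = self.neutral_zone
        if not (0 <= r0 < r1 <= 1 and 0 <= c0 < c1 <= 1):
            raise ValueError("neutral_zone fractions out of order")
        half = self.line_width_frac / 2
        for lid, c in self.line_centers.items():
            if max(c0, c - half) < min(c1, c + half):
                raise ValueError(f"neutral zone overlaps line window {lid!r}")

    # -- pixel-space geometry -------------------------------------------------

    def line_center_px(self, line_id: str) -> int:
        return int(round(self.line_centers[line_id] * self.canonical_width_px))

    def line_width_px(self) -> int:
        return max(2, int(round(self.line_width_frac * self.canonical_width_px)))

    def line_window(self, line_id: str) -> tuple[int, int]:
        """Half-open column range ``[lo, hi)`` of the line's window."""
        c = self.line_center_px(line_id)
        half = self.line_width_px() // 2
        return c - half, c - half + self.line_width_px()

    def neutral_zone_px(self) -> tuple[int, int, int, int]:
        r0, r1, c0, c1 = self.neutral_zone
        h, w = self.canonical_height_px, self.canonical_width_px
        return int(r0 * h), int(r1 * h), int(c0 * w), int(c1 * w)

    def canonical_corners(self) -> np.ndarray:
        """Corners of the canonical frame (row, col), ordered TL, TR, BR, BL."""
        h, w = self.canonical_height_px, self.canonical_width_px
        return np.array([[0, 0], [0, w - 1], [h - 1, w - 1], [h - 1, 0]], dtype=float)


@dataclass(frozen=True)
class DoseResponse:
    """Saturating (Langmuir-form) optical-density response of the test line.

    ``density(c) = floor + d_max * c / (k_half + c)`` — the simplest
    monotone saturating curve consistent with a one-site gold-nanoparticle
    binding band. ``floor`` models trace nonspecific binding at zero analyte.

    Defaults put the half-saturation point well above the 5–100 ng/mL
    measurement range, so the response is near-linear in range (matching the
    near-unity linear correlation such readers report) while still bending
    over at high analyte.
    """

    d_max: float = 1.2
    k_half: float = 250.0
    floor: float = 0.0024

    def __post_init__(self) -> None:
        if self.d_max <= 0 or self.k_half <= 0 or self.floor < 0:
            raise ValueError("require d_max > 0, k_half > 0, floor >= 0")

    def density(self, c) -> np.ndarray | float:
        c = np.asarray(c, dtype=float)
        if np.any(c < 0):
            raise ValueError("concentration must be non-negative")
        out = self.floor + self.d_max * c / (self.k_half + c)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DeviceModel:
    """Photometric distortions a capture device imprints on the scene.

    Applied in the fixed order: multiplicative shading field, 3x3 channel
    mixing, global intensity scale, white-balance tint, sRGB gamma
    encoding, additive Gaussian noise. ``shading_coeffs`` are the six
    coefficients of a degree-2 2-D polynomial in normalized (x, y) in
    [-1, 1]^2, term order ``1, x, y, x^2, x*y, y^2``.
    """

    wb_gains: tuple[float, float, float] = (1.0, 1.0, 1.0)
    shading_coeffs: tuple[float, ...] = (1.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    color_matrix: tuple = ((1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0))
    intensity_scale: float = 1.0
    gamma: str = "srgb"
    noise_sd: float = 0.004

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.wb_gains) <= 0):
            raise ValueError("white-balance gains must be positive")
        if self.intensity_scale <= 0:
            raise ValueError("intensity_scale must be positive")
        if self.gamma not in ("srgb", "none"):
            raise ValueError("gamma must be 'srgb' or 'none'")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        m = np.asarray(self.color_matrix, dtype=float)
        if m.shape != (3, 3) or abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("color_matrix must be an invertible 3 x 3 matrix")
        if np.any(self.shading_field((8, 8)) <= 0):
            raise ValueError("shading field must be positive over the frame")

    @classmethod
    def identity(cls) -> "DeviceModel":
        """A pass-through device: no distortion, no gamma, no noise."""
        return cls(gamma="none", noise_sd=0.0)

    def shading_field(self, shape: tuple[int, int]) -> np.ndarray:
        return eval_shading(np.asarray(self.shading_coeffs, dtype=float), shape)


def eval_shading(coeffs: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Evaluate a degree-2 2-D polynomial field over an H x W grid.

    Terms ``1, x, y, x^2, x*y, y^2`` with x (columns) and y (rows)
    normalized to [-1, 1].
    """
    h, w = shape
    y = np.linspace(-1, 1, h)[:, None]
    x = np.linspace(-1, 1, w)[None, :]
    c = np.asarray(coeffs, dtype=float)
    return c[0] + c[1] * x + c[2] * y + c[3] * x**2 + c[4] * x * y + c[5] * y**2


def _polygon_area(corners: np.ndarray) -> float:
    r, c = corners[:, 0], corners[:, 1]
    return 0.5 * float(np.abs(np.dot(c, np.roll(r, 1)) - np.dot(r, np.roll(c, 1))))


def check_convex_quadrilateral(corners: np.ndarray, min_area: float = 1.0) -> None:
    """Raise :class:`DegeneratePoseError` unless corners form a convex,
    non-degenerate quadrilateral."""
    corners = np.asarray(corners, dtype=float)
    if corners.shape != (4, 2):
        raise DegeneratePoseError("need exactly four (row, col) corners")
    if _polygon_area(corners) < min_area:
        raise DegeneratePoseError("corners are (nearly) collinear")
    crosses = []
    for i in range(4):
        a = corners[(i + 1) % 4] - corners[i]
        b = corners[(i + 2) % 4] - corners[(i + 1) % 4]
        crosses.append(a[0] * b[1] - a[1] * b[0])
    crosses = np.array(crosses)
    if np.any(crosses == 0) or not (np.all(crosses > 0) or np.all(crosses < 0)):
        raise DegeneratePoseError("corners do not form a convex quadrilateral")


@dataclass(frozen=True)
class Pose:
    """Placement of the canonical strip inside a photograph.

    ``corners`` are (row, col) positions of the canonical corners
    TL, TR, BR, BL in the canvas; ``canvas_shape`` is (H, W) of the
    photograph.
    """

    corners: tuple
    canvas_shape: tuple[int, int]

    def __post_init__(self) -> None:
        c = self.corners_array()
        check_convex_quadrilateral(c)
        h, w = self.canvas_shape
        if c[:, 0].min() < 0 or c[:, 1].min() < 0 or c[:, 0].max() > h - 1 or c[:, 1].max() > w - 1:
            raise DegeneratePoseError("pose corners fall outside the canvas")

    def corners_array(self) -> np.ndarray:
        return np.asarray(self.corners, dtype=float).reshape(4, 2)

    @classmethod
    def identity(cls, layout: StripLayout) -> "Pose":
        """The strip exactly fills the canvas: warping is a no-op."""
        c = layout.canonical_corners()
        return cls(tuple(map(tuple, c)), (layout.canonical_height_px, layout.canonical_width_px))

    @classmethod
    def framed(
        cls,
        layout: StripLayout,
        canvas_shape: tuple[int, int] = (260, 720),
        rotation_deg: float = 0.0,
        perspective: float = 0.0,
        scale: float = 0.9,
    ) -> "Pose":
        """Strip centered in a larger canvas, optionally rotated and with a
        symmetric perspective tilt (``perspective`` shrinks the top edge and
        widens the bottom edge by the given fraction)."""
        h, w = layout.canonical_height_px, layout.canonical_width_px
        half = np.array([[-h / 2, -w / 2], [-h / 2, w / 2], [h / 2, w / 2], [h / 2, -w / 2]])
        half = half * scale
        half[0, 1] *= 1 - perspective
        half[1, 1] *= 1 - perspective
        half[2, 1] *= 1 + perspective
        half[3, 1] *= 1 + perspective
        th = np.deg2rad(rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        placed = half @ rot.T + np.array(canvas_shape, dtype=float) / 2
        return cls(tuple(map(tuple, placed)), canvas_shape)


@dataclass
class GroundTruth:
    """Sidecar truth emitted with every synthetic strip image."""

    corners_px: np.ndarray
    true_concentration: float
    line_densities: dict[str, float]
    device: DeviceModel
    seed: int

    def to_dict(self) -> dict:
        return {
            "corners_px": np.asarray(self.corners_px).tolist(),
            "true_concentration": float(self.true_concentration),
            "line_densities": {k: float(v) for k, v in self.line_densities.items()},
            "device": {
                "wb_gains": list(self.device.wb_gains),
                "shading_coeffs": list(self.device.shading_coeffs),
                "color_matrix": np.asarray(self.device.color_matrix).tolist(),
                "intensity_scale": self.device.intensity_scale,
                "gamma": self.device.gamma,
                "noise_sd": self.device.noise_sd,
            },
            "seed": int(self.seed),
        }
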