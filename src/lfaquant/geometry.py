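"""Strip localization, perspective rectification, and quality control.

The classical-CV front end: the strip is a bright rectangle on a darker
background, so edge detection (gradient magnitude thresholded at the Otsu
level) followed by contour tracing and polygonal simplification yields its
quadrilateral; a four-point direct linear transform then maps it onto the
canonical layout frame. Images are gamma-decoded at rectification so that
all downstream math runs in linear intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import sobel, threshold_otsu
from skimage.measure import approximate_polygon, find_contours, label, regionprops
from skimage.morphology import closing, footprint_rectangle
from skimage.transform import ProjectiveTransform, warp

from ._color import luminance, srgb_decode, srgb_encode
from .errors import StripNotFoundError
from .image import RectifiedStrip, StripImage
from .layout import StripLayout, check_convex_quadrilateral
from .signals import extract_profile, measure_line

MIN_AREA_FRAC = 0.05
DEFAULT_C_MIN_CONTRAST = 0.05
DEFAULT_OVEREXPOSURE_FRAC_MAX = 0.05
SATURATION_LEVEL = 0.99


@dataclass
class QCReport:
    """Per-image quality flags raised before any concentration is reported."""

    overexposed_frac: float
    c_line_present: bool
    flags: tuple[str, ...]


def _order_corners(pts: np.ndarray) -> np.ndarray:
    """Order corners clockwise (in image coordinates) starting at top-left,
    sorted by angle from the centroid."""
    pts = np.asarray(pts, dtype=float)
    centroid = pts.mean(axis=0)
    ang = np.arctan2(pts[:, 0] - centroid[0], pts[:, 1] - centroid[1])
    pts = pts[np.argsort(ang)]
    start = int(np.argmin(pts.sum(axis=1)))  # top-left has minimal row+col
    return np.roll(pts, -start, axis=0)


def _largest_region_mask(binary: np.ndarray) -> np.ndarray | None:
    lab = label(binary)
    props = regionprops(lab)
    if not props:
        return None
    best = max(props, key=lambda p: p.area)
    if best.area < MIN_AREA_FRAC * binary.size:
        return None
    return lab == best.label


def _quad_from_contour(contour: np.ndarray) -> np.ndarray | None:
    for tol in np.geomspace(0.5, 60.0, 60):
        approx = approximate_polygon(contour, tolerance=tol)
        n = len(approx) - 1 if np.allclose(approx[0], approx[-1]) else len(approx)
        if n == 4:
            return approx[:4]
        if n < 4:
            break
    return None


def _refine_corners(contour: np.ndarray, corners: np.ndarray) -> np.ndarray:
    """Subpixel corner refinement: fit a total-least-squares line to the
    contour run along each quadrilateral edge (trimming the ends near the
    corners) and intersect consecutive edge lines."""
    # indices of the rough corners along the contour
    idx = sorted(int(np.argmin(np.sum((contour - c) ** 2, axis=1))) for c in corners)
    lines = []
    for a, b in zip(idx, idx[1:] + [idx[0] + len(contour)]):
        seg = contour[np.arange(a, b + 1) % len(contour)]
        trim = max(2, len(seg) // 10)
        seg = seg[trim:-trim] if len(seg) > 3 * trim else seg
        if len(seg) < 2:
            return corners
        centroid = seg.mean(axis=0)
        _, _, vt = np.linalg.svd(seg - centroid)
        direction = vt[0]
        normal = np.array([-direction[1], direction[0]])
        lines.append((normal, float(normal @ centroid)))  # n . p = d
    refined = []
    for (n1, d1), (n2, d2) in zip(lines, lines[1:] + lines[:1]):
        mat = np.array([n1, n2])
        if abs(np.linalg.det(mat)) < 1e-9:
            return corners
        refined.append(np.linalg.solve(mat, [d1, d2]))
    return np.asarray(refined)


def detect_strip(img: StripImage) -> np.ndarray:
    """Locate the strip quadrilateral.

    Edge detection (Sobel gradient magnitude at the Otsu level) is
    combined with a brightness threshold — the strip's own dark line
    bands would otherwise split the bright region — then a morphological
    closing wider than a line band, hole filling, contour tracing,
    polygonal simplification to a 4-gon, and line-fit corner refinement.

    Returns the four corner coordinates (row, col), ordered TL, TR, BR, BL.
    Raises :class:`StripNotFoundError` when no 4-gon region covering at
    least 5% of the image is found.
    """
    gray = luminance(img.pixels)
    edges = sobel(gray)
    if np.ptp(gray) < 1e-6:
        raise StripNotFoundError("strip not found: image is featureless")
    mask = (gray > threshold_otsu(gray)) | (edges > threshold_otsu(edges))
    mask = closing(mask, footprint_rectangle((5, 41)))
    region = _largest_region_mask(ndimage.binary_fill_holes(mask))
    if region is None:
        raise StripNotFoundError("strip not found: no region covers 5% of the image")
    contours = find_contours(region.astype(float), 0.5)
    if not contours:
        raise StripNotFoundError("strip not found: region has no traceable boundary")
    contour = max(contours, key=len)
    quad = _quad_from_contour(contour)
    if quad is None:
        raise StripNotFoundError("strip not found: largest region is not a quadrilateral")
    corners = _order_corners(_refine_corners(contour, _order_corners(quad)))
    check_convex_quadrilateral(corners)
    return corners


def rectify(img: StripImage, corners: np.ndarray, layout: StripLayout) -> RectifiedStrip:
    """Warp the detected quadrilateral onto the canonical frame.

    The homography is estimated by a 4-point direct linear transform;
    resampling is bilinear; the output is gamma-decoded to linear light.
    """
    corners = np.asarray(corners, dtype=float)
    check_convex_quadrilateral(corners)
    src_xy = corners[:, ::-1]
    dst_xy = layout.canonical_corners()[:, ::-1]
    t = ProjectiveTransform.from_estimate(src_xy, dst_xy)
    if not t:
        raise ValueError("could not estimate rectifying homography")
    out = warp(
        img.pixels,
        inverse_map=t.inverse,
        output_shape=(layout.canonical_height_px, layout.canonical_width_px),
        order=1,
        mode="edge",
    )
    if img.color_space == "srgb":
        out = srgb_decode(out)
    return RectifiedStrip(pixels=np.clip(out, 0.0, 1.0), homography=t.params)


def qc_check(
    rs: RectifiedStrip,
    layout: StripLayout,
    c_min_contrast: float = DEFAULT_C_MIN_CONTRAST,
    overexposure_frac_max: float = DEFAULT_OVEREXPOSURE_FRAC_MAX,
    raw: StripImage | None = None,
) -> QCReport:
    """Raise overexposure / insufficient-reaction flags.

    Saturation is assessed on the camera-encoded pixels (``raw`` when the
    original photograph is available, otherwise the rectified strip
    re-encoded); control-line presence requires the background-corrected
    C-window absorbance to reach ``c_min_contrast``.
    """
    if raw is not None:
        enc = raw.pixels if raw.color_space == "srgb" else srgb_encode(raw.pixels)
    else:
        enc = srgb_encode(rs.pixels)
    overexposed = float(np.mean(np.any(enc >= SATURATION_LEVEL, axis=-1)))
    profile = extract_profile(rs, layout)
    c_meas = measure_line(profile, layout, "C")
    c_present = bool(c_meas.intensity >= c_min_contrast)
    flags: list[str] = []
    if overexposed > overexposure_frac_max:
        flags.append("overexposure")
    if not c_present:
        flags.append("insufficient reaction")
    return QCReport(overexposed_frac=overexposed, c_line_present=c_present, flags=tuple(flags))
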