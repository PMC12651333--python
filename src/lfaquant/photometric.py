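"""Cross-device photometric alignment.

One capture platform is designated the color reference; images from the
other are mapped into its linear RGB space before quantification. The
transform is learned from paired captures of the same strips and
comprises, in order:

(i)   sRGB gamma linearization,
(ii)  white-balance normalization from the cassette's neutral zone,
(iii) polynomial shading (vignetting) correction, and
(iv)  a 3x3 color correction matrix with a separate intensity scale.

Each sub-fit is linear and fitted sequentially; the CCM is fitted on
patch means (the reference-line windows, C/T windows and neutral zone)
rather than raw pixels, which keeps it robust to pixel noise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._color import luminance, srgb_decode, srgb_encode
from .image import RectifiedStrip, StripImage
from .layout import LINE_IDS, StripLayout, eval_shading
from .signals import TRANSVERSE_KEEP

MIN_NEUTRAL_PIXELS = 100
MIN_CHANNEL_MEDIAN = 0.01
_SHADING_TERMS = 6  # 1, x, y, x^2, xy, y^2


def srgb_linearize(img: StripImage) -> StripImage:
    """Step (i): decode the sRGB transfer function to linear light.

    A no-op (with a warning) on images already tagged linear.
    """
    if img.color_space == "linear":
        warnings.warn("image is already linear; sRGB linearization skipped", stacklevel=2)
        return StripImage(img.pixels.copy(), "linear")
    return StripImage(srgb_decode(img.pixels), "linear")


def srgb_encode_image(img: StripImage) -> StripImage:
    """Inverse of :func:`srgb_linearize` (exact round-trip)."""
    if img.color_space == "srgb":
        warnings.warn("image is already sRGB-encoded", stacklevel=2)
        return StripImage(img.pixels.copy(), "srgb")
    return StripImage(srgb_encode(img.pixels), "srgb")


def white_balance_from_neutral(
    pixels: np.ndarray, neutral_zone_px: tuple[int, int, int, int]
) -> np.ndarray:
    """Step (ii): per-channel gains from the neutral zone of a linear image.

    Gains are ``mean(medians) / median`` per channel, so applying them
    equalizes the zone's channel medians.
    """
    r0, r1, c0, c1 = neutral_zone_px
    zone = np.asarray(pixels, dtype=float)[r0:r1, c0:c1, :]
    if zone.shape[0] * zone.shape[1] < MIN_NEUTRAL_PIXELS:
        raise ValueError(f"neutral zone smaller than {MIN_NEUTRAL_PIXELS} pixels")
    med = np.median(zone.reshape(-1, 3), axis=0)
    if np.any(med <= MIN_CHANNEL_MEDIAN):
        raise ValueError("neutral zone too dark for white-balance estimation")
    return med.mean() / med


def fit_shading(pixels: np.ndarray, mask: np.ndarray, degree: int = 2) -> np.ndarray:
    """Step (iii): least-squares degree-2 polynomial fit of luminance over
    the background mask. Returns the 6 field coefficients
    (terms 1, x, y, x^2, xy, y^2 in [-1, 1]-normalized coordinates)."""
    if degree != 2:
        raise ValueError("only degree 2 is supported")
    h, w = mask.shape
    rows, cols = np.nonzero(mask)
    if rows.size < _SHADING_TERMS:
        raise ValueError("background mask too small for a shading fit")
    y = rows / (h - 1) * 2 - 1
    x = cols / (w - 1) * 2 - 1
    design = np.column_stack([np.ones_like(x), x, y, x**2, x * y, y**2])
    arr = np.asarray(pixels, dtype=float)
    lum = (arr if arr.ndim == 2 else luminance(arr))[rows, cols]
    coef, _, rank, _ = np.linalg.lstsq(design, lum, rcond=None)
    if rank < _SHADING_TERMS:
        raise ValueError("shading design matrix is rank deficient")
    return coef


def apply_shading_correction(pixels: np.ndarray, coeffs: np.ndarray) -> np.ndarray:
    """Divide by the fitted field normalized to mean 1 (flat-fielding)."""
    field = eval_shading(coeffs, pixels.shape[:2])
    if np.any(field <= 0):
        raise ValueError("fitted shading field is not positive over the frame")
    return pixels / (field / field.mean())[:, :, None]


def fit_ccm(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Step (iv): least squares for M minimizing ``sum ||s*M*x - y||^2``
    over paired patch colors, with the intensity scale s factored out as
    the mean luminance ratio so M stays near luminance-preserving.

    Returns ``(ccm, intensity_scale, residual_rms)``.
    """
    x = np.asarray(source, dtype=float).reshape(-1, 3)
    y = np.asarray(target, dtype=float).reshape(-1, 3)
    if x.shape[0] < 4 or x.shape != y.shape:
        raise ValueError("need at least 4 paired colors")
    if np.linalg.matrix_rank(x, tol=1e-9) < 3:
        raise ValueError("paired colors are degenerate (coplanar through the origin)")
    composite, *_ = np.linalg.lstsq(x, y, rcond=None)  # y ~ x @ composite
    composite = composite.T  # y ~ composite @ x
    scale = float(np.mean(luminance(y)) / np.mean(luminance(x)))
    ccm = composite / scale
    resid = x @ composite.T - y
    return ccm, scale, float(np.sqrt(np.mean(resid**2)))


@dataclass
class PhotometricTransform:
    """A fitted device-to-reference photometric map, applied in the order
    linearize -> white balance -> shading correction -> scaled CCM."""

    wb_gains: np.ndarray
    shading_coeffs: np.ndarray
    ccm: np.ndarray
    intensity_scale: float
    gamma: str = "srgb"

    def __post_init__(self) -> None:
        self.wb_gains = np.asarray(self.wb_gains, dtype=float)
        self.shading_coeffs = np.asarray(self.shading_coeffs, dtype=float)
        self.ccm = np.asarray(self.ccm, dtype=float)
        if np.any(self.wb_gains <= 0) or self.intensity_scale <= 0:
            raise ValueError("gains and intensity scale must be positive")
        if abs(np.linalg.det(self.ccm)) < 1e-12:
            raise ValueError("color correction matrix must be invertible")

    @classmethod
    def identity(cls) -> "PhotometricTransform":
        return cls(np.ones(3), np.array([1.0, 0, 0, 0, 0, 0]), np.eye(3), 1.0)

    def apply(self, img: StripImage) -> StripImage:
        """Map a capture into the reference linear space."""
        if img.color_space == "srgb":
            pixels = srgb_decode(img.pixels)
        else:
            pixels = np.asarray(img.pixels, dtype=float)
        pixels = pixels * self.wb_gains
        pixels = apply_shading_correction(pixels, self.shading_coeffs)
        pixels = self.intensity_scale * (pixels @ self.ccm.T)
        return StripImage(np.clip(pixels, 0.0, 1.0), "linear")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gamma": self.gamma,
            "wb_gains": self.wb_gains.tolist(),
            "shading_coeffs": self.shading_coeffs.tolist(),
            "ccm": self.ccm.tolist(),
            "intensity_scale": self.intensity_scale,
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PhotometricTransform":
        p = json.loads(Path(path).read_text())
        return cls(p["wb_gains"], p["shading_coeffs"], p["ccm"], p["intensity_scale"], p["gamma"])


def background_mask(layout: StripLayout, border_px: int = 4, pad_px: int = 4) -> np.ndarray:
    """Substrate pixels away from every line window (and the frame border)."""
    h, w = layout.canonical_height_px, layout.canonical_width_px
    mask = np.ones((h, w), dtype=bool)
    for lid in LINE_IDS:
        lo, hi = layout.line_window(lid)
        mask[:, max(0, lo - pad_px) : min(w, hi + pad_px)] = False
    mask[:border_px, :] = False
    mask[-border_px:, :] = False
    mask[:, :border_px] = False
    mask[:, -border_px:] = False
    return mask


def _patch_means(pixels: np.ndarray, layout: StripLayout) -> np.ndarray:
    """Mean linear RGB over the C/T windows, the five reference windows
    (transverse central band only) and the neutral zone."""
    h = layout.canonical_height_px
    margin = int(round(h * (1 - TRANSVERSE_KEEP) / 2))
    patches = []
    for lid in LINE_IDS:
        lo, hi = layout.line_window(lid)
        patches.append(pixels[margin : h - margin, lo:hi, :].reshape(-1, 3).mean(axis=0))
    r0, r1, c0, c1 = layout.neutral_zone_px()
    patches.append(pixels[r0:r1, c0:c1, :].reshape(-1, 3).mean(axis=0))
    return np.asarray(patches)


class PhotometricAligner(TransformerMixin, BaseEstimator):
    """Learn a device-to-reference photometric transform from paired
    captures of the same strips (in the canonical frame).

    ``fit`` takes a list of ``(source_image, reference_image)`` pairs; the
    white balance, shading field and CCM are fitted sequentially, each on
    the output of the previous step. ``transform`` then maps further
    source-device captures into the reference linear space.

    Attributes
    ----------
    transform_ : PhotometricTransform
        The fitted composite map.
    ccm_residual_rms_ : float
        RMS residual of the CCM patch fit (reference linear units).
    """

    def __init__(self, layout: StripLayout | None = None, shading_degree: int = 2):
        self.layout = layout
        self.shading_degree = shading_degree

    def _layout(self) -> StripLayout:
        return self.layout if self.layout is not None else StripLayout()

    @staticmethod
    def _linear_pixels(img: StripImage | RectifiedStrip) -> np.ndarray:
        if isinstance(img, RectifiedStrip):
            return np.asarray(img.pixels, dtype=float)
        return srgb_decode(img.pixels) if img.color_space == "srgb" else np.asarray(img.pixels, dtype=float)

    def fit(self, X, y=None) -> "PhotometricAligner":
        """``X``: list of (source, reference) image pairs in the canonical frame."""
        layout = self._layout()
        pairs = [(self._linear_pixels(a), self._linear_pixels(b)) for a, b in X]
        if not pairs:
            raise ValueError("need at least one image pair")
        zone = layout.neutral_zone_px()
        r0, r1, c0, c1 = zone
        pooled = np.concatenate([a[r0:r1, c0:c1, :].reshape(-1, 3) for a, _ in pairs])
        med = np.median(pooled, axis=0)
        if np.any(med <= MIN_CHANNEL_MEDIAN):
            raise ValueError("neutral zone too dark for white-balance estimation")
        gains = med.mean() / med
        mask = background_mask(layout)
        lum_stack = np.mean([luminance(a * gains) for a, _ in pairs], axis=0)
        coeffs = fit_shading(lum_stack, mask, degree=self.shading_degree)
        src_patches, tgt_patches = [], []
        for a, b in pairs:
            corrected = apply_shading_correction(a * gains, coeffs)
            src_patches.append(_patch_means(corrected, layout))
            tgt_patches.append(_patch_means(b, layout))
        ccm, scale, rms = fit_ccm(np.concatenate(src_patches), np.concatenate(tgt_patches))
        self.transform_ = PhotometricTransform(gains, coeffs, ccm, scale)
        self.ccm_residual_rms_ = rms
        return self

    def transform(self, X):
        """Align one image or a list of images into the reference space."""
        if isinstance(X, (StripImage, RectifiedStrip)):
            return self._apply_one(X)
        return [self._apply_one(img) for img in X]

    def _apply_one(self, img: StripImage | RectifiedStrip):
        if isinstance(img, RectifiedStrip):
            aligned = self.transform_.apply(StripImage(img.pixels, "linear"))
            return RectifiedStrip(aligned.pixels, img.homography)
        return self.transform_.apply(img)


def align(img: StripImage, t: PhotometricTransform) -> StripImage:
    """Apply a fitted photometric transform (steps i–iv) to a capture."""
    return t.apply(img)
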