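"""Line-intensity extraction from a rectified strip.

The rectified strip is reduced to a longitudinal absorbance profile
(green-channel, since the gold-nanoparticle band is red and green is the
maximally absorbed complement), lines are located as profile peaks inside
their expected windows, and each line intensity is the window mean minus a
local flanking background — which makes the measurement exactly invariant
to any global additive offset of the profile, and hence to global
illumination gain (a gain multiplies transmittance, i.e. adds a constant
in absorbance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import theilslopes, trim_mean

from .errors import ConfigurationError, LadderUnusableError
from .image import RectifiedStrip
from .layout import LINE_IDS, REF_IDS, StripLayout

PROFILE_EPS = 1e-4
TRANSVERSE_KEEP = 0.60  # central fraction of the strip height used
TRIM_FRACTION = 0.20  # trimmed-mean cut on each side, resists dust/glare
DEFAULT_FLANK_GAP = 8


@dataclass
class LineProfile:
    """Longitudinal absorbance proxy, one value per canonical column."""

    values: np.ndarray
    channel: str = "green"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or not np.all(np.isfinite(self.values)):
            raise ValueError("profile must be a finite 1-D array")


@dataclass
class LineMeasurement:
    """Background-corrected intensity of one line."""

    line_id: str
    peak_pos: int
    intensity: float
    background: float


@dataclass
class ReferenceLadder:
    """(I_k, R_k) calibration points with an outlier mask (True = keep)."""

    intensities: np.ndarray
    nominal_signals: np.ndarray
    inlier_mask: np.ndarray

    def surviving(self) -> tuple[np.ndarray, np.ndarray]:
        return self.intensities[self.inlier_mask], self.nominal_signals[self.inlier_mask]


def extract_profile(rs: RectifiedStrip, layout: StripLayout) -> LineProfile:
    """Absorbance profile: per column, ``-log10(max(eps, trimmed mean of
    the green channel over the transverse central 60%))``."""
    h = layout.canonical_height_px
    margin = int(round(h * (1 - TRANSVERSE_KEEP) / 2))
    band = rs.pixels[margin : h - margin, :, 1]
    means = trim_mean(band, TRIM_FRACTION, axis=0)
    return LineProfile(-np.log10(np.maximum(PROFILE_EPS, means)))


def locate_line(profile: LineProfile, window: tuple[int, int]) -> int:
    """Position of the profile maximum within the inclusive window
    ``[lo, hi]``; ties are broken toward the window center.

    A line band has a flat top, so the raw argmax wanders across the
    plateau under pixel noise; the position returned is the center of the
    near-maximum plateau (within 5% of the peak's height above the window
    minimum), which degrades gracefully to the exact argmax for a sharp
    peak and to the window center for a flat window.
    """
    lo, hi = int(window[0]), int(window[1])
    if not 0 <= lo <= hi < len(profile.values):
        raise ValueError("window outside profile")
    seg = profile.values[lo : hi + 1]
    peak = seg.max()
    tol = 0.05 * (peak - seg.min()) + 1e-12
    candidates = np.flatnonzero(seg >= peak - tol) + lo
    return int(round(float(candidates.mean())))


def measure_intensity(
    profile: LineProfile,
    peak_pos: int,
    line_width: int,
    flank_gap: int = DEFAULT_FLANK_GAP,
    forbidden_windows: list[tuple[int, int]] | None = None,
) -> tuple[float, float]:
    """Background-corrected line intensity.

    Background is the median over two flanking windows (each ``line_width``
    wide, offset by ``flank_gap`` from the line window on both sides);
    intensity is ``max(0, mean(line window) - background)``. Returns
    ``(intensity, background)``.
    """
    half = line_width // 2
    lo, hi = peak_pos - half, peak_pos - half + line_width
    left = (lo - flank_gap - line_width, lo - flank_gap)
    right = (hi + flank_gap, hi + flank_gap + line_width)
    n = len(profile.values)
    if left[0] < 0 or right[1] > n:
        raise ConfigurationError("flank windows fall outside the profile")
    for flank in (left, right):
        for fw in forbidden_windows or []:
            if max(flank[0], fw[0]) < min(flank[1], fw[1]):
                raise ConfigurationError(
                    f"background flank {flank} overlaps another line window {tuple(fw)}"
                )
    background = float(np.median(np.concatenate([profile.values[slice(*left)], profile.values[slice(*right)]])))
    intensity = max(0.0, float(np.mean(profile.values[lo:hi])) - background)
    return intensity, background


def measure_line(
    rs_profile: LineProfile,
    layout: StripLayout,
    line_id: str,
    flank_gap: int = DEFAULT_FLANK_GAP,
    shift: int = 0,
) -> LineMeasurement:
    """Locate and measure one line using the layout's expected window
    (optionally translated by a common registration ``shift``), validating
    that the background flanks avoid every other line window."""
    lo, hi = layout.line_window(line_id)
    peak = locate_line(rs_profile, (lo, hi - 1))
    center = layout.line_center_px(line_id) + shift
    others = [
        (w[0] + shift, w[1] + shift)
        for w in (layout.line_window(l) for l in LINE_IDS if l != line_id)
    ]
    intensity, background = measure_intensity(
        rs_profile, center, layout.line_width_px(), flank_gap, forbidden_windows=others
    )
    return LineMeasurement(line_id, peak, intensity, background)


def registration_shift(profile: LineProfile, layout: StripLayout) -> int:
    """Common longitudinal offset of the line pattern relative to the
    nominal layout: the median displacement of every located peak from its
    expected center. Absorbs small residual rectification misalignment
    while preserving the layout's relative window geometry."""
    shifts = []
    for lid in LINE_IDS:
        lo, hi = layout.line_window(lid)
        shifts.append(locate_line(profile, (lo, hi - 1)) - layout.line_center_px(lid))
    return int(round(float(np.median(shifts))))


def measure_all_lines(
    profile: LineProfile, layout: StripLayout, flank_gap: int = DEFAULT_FLANK_GAP
) -> dict[str, LineMeasurement]:
    shift = registration_shift(profile, layout)
    return {lid: measure_line(profile, layout, lid, flank_gap, shift) for lid in LINE_IDS}


def build_ladder(
    measurements: list[LineMeasurement], nominal_signals: np.ndarray | tuple
) -> ReferenceLadder:
    """Assemble the (I_k, R_k) ladder, masking outliers.

    A provisional robust line of R on I (Theil–Sen slope with a median
    pointwise intercept, so a single gross outlier cannot drag the
    provisional fit itself) is put through all five points; points whose
    absolute residual exceeds 3x the median absolute residual are masked.
    At least two points must survive.
    """
    if len(measurements) != len(REF_IDS):
        raise ValueError(f"need {len(REF_IDS)} reference-line measurements")
    intens = np.array([m.intensity for m in measurements], dtype=float)
    nominal = np.asarray(nominal_signals, dtype=float)
    if np.any(np.diff(nominal) <= 0):
        raise ValueError("nominal signals must be strictly increasing")
    if np.ptp(intens) == 0:
        raise LadderUnusableError("ladder unusable: all reference intensities identical")
    slope = theilslopes(nominal, intens).slope
    intercept = float(np.median(nominal - slope * intens))
    resid = nominal - (slope * intens + intercept)
    # floor keeps an exactly linear ladder from flagging numerically tiny residuals
    cutoff = max(3.0 * float(np.median(np.abs(resid))), 1e-8 * max(1.0, float(np.abs(nominal).max())))
    mask = np.abs(resid) <= cutoff
    if mask.sum() < 2:
        raise LadderUnusableError("ladder unusable: fewer than two inlier points")
    return ReferenceLadder(intens, nominal, mask)
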