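"""Synthetic strip-image generator with exhaustively known ground truth.

Every downstream stage (detection, rectification, line measurement,
calibration, photometric alignment, detection-limit studies) is testable
against images rendered here, because the sidecar records the exact pose,
line optical densities, and device model used.

Rendering model
---------------
The canonical strip is an off-white substrate (linear reflectance
``SUBSTRATE_LEVEL`` in all channels). A line of optical density ``d``
multiplies each channel by ``10**(-a_ch * d)`` where ``a_ch`` is the
per-channel absorption ratio of the red gold-nanoparticle band: green is
the complementary, maximally absorbed channel (ratio 1), blue partially
absorbed, red barely. Reference line k has density ``SIGNAL_TO_DENSITY *
R_k`` (a fixed linear signal->density map); the control line has a fixed
high density; the test line follows the dose-response curve.

The canonical strip is then warped to the requested pose by homography
over a darker background, and the device model is applied in the order
shading -> color mixing -> intensity scale -> white-balance tint -> gamma
encoding -> additive noise. All randomness is a pure function of
``(inputs, seed)``.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
from skimage.transform import ProjectiveTransform, warp

from ._color import srgb_encode
from .image import StripImage, write_png, write_sidecar
from .layout import REF_IDS, DeviceModel, DoseResponse, GroundTruth, Pose, StripLayout

SUBSTRATE_LEVEL = 0.75
BACKGROUND_LEVEL = 0.25
SIGNAL_TO_DENSITY = 0.006
C_LINE_DENSITY = 0.6
CHANNEL_ABSORPTION = (0.15, 1.0, 0.55)  # R, G, B absorption relative to green
DEFAULT_DENSITY_JITTER_SD = 0.001


def dose_response_density(c: float, dr: DoseResponse) -> float:
    """Test-line optical density at analyte concentration ``c`` (ng/mL)."""
    return dr.density(c)


def line_densities(layout: StripLayout, c: float, dr: DoseResponse) -> dict[str, float]:
    """True optical density of every line at concentration ``c``."""
    d = {"C": C_LINE_DENSITY, "T": float(dr.density(c))}
    for rid, r in zip(REF_IDS, layout.nominal_signals):
        d[rid] = SIGNAL_TO_DENSITY * r
    return d


def render_canonical(layout: StripLayout, densities: dict[str, float]) -> np.ndarray:
    """Noise-free canonical strip (linear light) from per-line densities."""
    h, w = layout.canonical_height_px, layout.canonical_width_px
    img = np.full((h, w, 3), SUBSTRATE_LEVEL, dtype=float)
    for lid, dens in densities.items():
        lo, hi = layout.line_window(lid)
        for ch, a in enumerate(CHANNEL_ABSORPTION):
            img[:, lo:hi, ch] = SUBSTRATE_LEVEL * 10.0 ** (-a * dens)
    return img


def pose_transform(layout: StripLayout, pose: Pose) -> ProjectiveTransform:
    """Projective map canonical -> canvas, acting on (x, y) = (col, row)."""
    src = layout.canonical_corners()[:, ::-1]  # to (x, y)
    dst = pose.corners_array()[:, ::-1]
    t = ProjectiveTransform.from_estimate(src, dst)
    if not t:
        raise ValueError("could not estimate pose homography")
    return t


def apply_device(pixels: np.ndarray, device: DeviceModel, rng: np.random.Generator) -> np.ndarray:
    """Imprint device distortions on a linear-light canvas."""
    out = pixels * device.shading_field(pixels.shape[:2])[:, :, None]
    out = out @ np.asarray(device.color_matrix, dtype=float).T
    out = out * device.intensity_scale
    out = out * np.asarray(device.wb_gains, dtype=float)
    out = np.clip(out, 0.0, 1.0)
    if device.gamma == "srgb":
        out = srgb_encode(out)
    if device.noise_sd > 0:
        out = out + rng.normal(0.0, device.noise_sd, size=out.shape)
    return np.clip(out, 0.0, 1.0)


def _render_scene(layout: StripLayout, densities: dict[str, float], pose: Pose) -> np.ndarray:
    canonical = render_canonical(layout, densities)
    if pose.canvas_shape == (layout.canonical_height_px, layout.canonical_width_px) and np.allclose(
        pose.corners_array(), layout.canonical_corners()
    ):
        return canonical
    t = pose_transform(layout, pose)
    return warp(
        canonical,
        inverse_map=t.inverse,
        output_shape=pose.canvas_shape,
        order=1,
        cval=BACKGROUND_LEVEL,
        mode="constant",
    )


def render_strip(
    layout: StripLayout,
    c: float,
    dr: DoseResponse,
    device: DeviceModel | None = None,
    pose: Pose | None = None,
    seed: int = 0,
    density_jitter_sd: float = 0.0,
    density_overrides: dict[str, float] | None = None,
) -> tuple[StripImage, GroundTruth]:
    """Render one strip photograph plus its ground-truth sidecar.

    ``density_jitter_sd`` adds a per-strip Gaussian perturbation to the
    test-line density (truncated at zero), emulating replicate-to-replicate
    assay chemistry variability on top of pixel noise.
    ``density_overrides`` forces specific line densities (e.g. a failed
    run with no control line).
    """
    device = device or DeviceModel.identity()
    pose = pose or Pose.identity(layout)
    rng = np.random.default_rng(seed)
    dens = line_densities(layout, c, dr)
    if density_jitter_sd > 0:
        dens["T"] = max(0.0, dens["T"] + rng.normal(0.0, density_jitter_sd))
    if density_overrides:
        dens.update(density_overrides)
    canvas = _render_scene(layout, dens, pose)
    out = apply_device(canvas, device, rng)
    img = StripImage(out, color_space="srgb" if device.gamma == "srgb" else "linear")
    truth = GroundTruth(
        corners_px=pose.corners_array(),
        true_concentration=float(c),
        line_densities=dens,
        device=device,
        seed=seed,
    )
    return img, truth


def make_paired_captures(
    layout: StripLayout,
    c: float,
    dr: DoseResponse,
    device_a: DeviceModel,
    device_b: DeviceModel,
    seed: int = 0,
    pose: Pose | None = None,
    density_jitter_sd: float = 0.0,
) -> tuple[StripImage, StripImage, GroundTruth]:
    """Photograph the *same* physical strip with two devices.

    The canonical strip (densities, jitter) is shared; only the device
    pipelines — including their independent noise draws — differ.
    """
    pose = pose or Pose.identity(layout)
    rng = np.random.default_rng(seed)
    dens = line_densities(layout, c, dr)
    if density_jitter_sd > 0:
        dens["T"] = max(0.0, dens["T"] + rng.normal(0.0, density_jitter_sd))
    canvas = _render_scene(layout, dens, pose)
    img_a = apply_device(canvas, device_a, np.random.default_rng((seed, 1)))
    img_b = apply_device(canvas, device_b, np.random.default_rng((seed, 2)))
    truth = GroundTruth(pose.corners_array(), float(c), dens, device_a, seed)
    return (
        StripImage(img_a, "srgb" if device_a.gamma == "srgb" else "linear"),
        StripImage(img_b, "srgb" if device_b.gamma == "srgb" else "linear"),
        truth,
    )


def generate_validation_panel(
    levels: list[tuple[float, int]],
    seed: int = 0,
    layout: StripLayout | None = None,
    dr: DoseResponse | None = None,
    device: DeviceModel | None = None,
    pose: Pose | None = None,
    density_jitter_sd: float = DEFAULT_DENSITY_JITTER_SD,
    out_dir: str | Path | None = None,
) -> list[tuple[StripImage, GroundTruth]]:
    """Replicate panel across dilution levels, emulating an LoD / dynamic
    range study: ``levels`` is a list of (concentration, n_replicates).

    With ``out_dir`` set, writes 8-bit PNGs, ``*.truth.json`` sidecars and
    a ``manifest.csv`` (path, concentration_ng_ml, seed, device_id).

    Without an explicit ``pose`` the strips are framed like photographs
    (strip centered on a darker background) so the panel exercises
    detection and rectification too.
    """
    layout = layout or StripLayout()
    dr = dr or DoseResponse()
    device = device or DeviceModel()
    pose = pose or Pose.framed(layout)
    panel: list[tuple[StripImage, GroundTruth]] = []
    rows = []
    for i, (c, n) in enumerate(levels):
        if c < 0 or n < 1:
            raise ValueError("levels require concentration >= 0 and n >= 1")
        for rep in range(n):
            strip_seed = int(np.random.SeedSequence((seed, i, rep)).generate_state(1)[0] % (2**31))
            img, truth = render_strip(
                layout, c, dr, device, pose, seed=strip_seed, density_jitter_sd=density_jitter_sd
            )
            panel.append((img, truth))
            rows.append((f"strip_{i:02d}_{rep:02d}.png", c, strip_seed, "default"))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for (img, truth), (name, *_rest) in zip(panel, rows):
            write_png(out / name, img)
            write_sidecar(out / (Path(name).stem + ".truth.json"), truth.to_dict())
        with open(out / "manifest.csv", "w", newline="") as fh:
            wtr = csv.writer(fh)
            wtr.writerow(["path", "concentration_ng_ml", "seed", "device_id"])
            wtr.writerows(rows)
    return panel
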