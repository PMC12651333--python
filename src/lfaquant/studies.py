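"""Desk-scale analogues of the assay's validation studies, run entirely on
synthetic strips.

Each study generates its own inputs from the synthetic renderer, pushes
them through the full reading pipeline, and summarizes the result. They
are shared by the test suite and the acceptance script so both exercise
exactly the same code paths.
"""

from __future__ import annotations

import numpy as np

from .calibration import ConcentrationRegressor
from .image import RectifiedStrip, StripImage
from .layout import DeviceModel, DoseResponse, Pose, StripLayout
from .photometric import PhotometricAligner
from .pipeline import analyze_image, fit_concentration_model, measure_rectified
from .stats import detection_limits, pearson_r2
from .synthetic import (
    C_LINE_DENSITY,
    DEFAULT_DENSITY_JITTER_SD,
    make_paired_captures,
    render_strip,
)
from ._color import srgb_decode


def study_device_models() -> list[DeviceModel]:
    """Five plausible capture devices: pass-through, neutral sRGB camera,
    warm white-balance tint, vignetting with reduced exposure, and mild
    channel crosstalk with a cool tint. All noise-free, for ground-truth
    classification studies."""
    return [
        DeviceModel.identity(),
        DeviceModel(noise_sd=0.0),
        DeviceModel(wb_gains=(1.2, 1.0, 0.9), noise_sd=0.0),
        DeviceModel(
            shading_coeffs=(1.0, 0.0, 0.0, -0.10, 0.0, -0.06),
            intensity_scale=0.95,
            noise_sd=0.0,
        ),
        DeviceModel(
            color_matrix=((0.96, 0.03, 0.01), (0.02, 0.96, 0.02), (0.01, 0.04, 0.95)),
            wb_gains=(0.95, 1.0, 1.08),
            noise_sd=0.0,
        ),
    ]


def _true_level(c: float) -> int:
    return 1 if c < 20 else (2 if c <= 30 else 3)


def classification_accuracy_study(
    concentrations: tuple[float, ...] = (10.0, 25.0, 50.0),
    seed: int = 0,
    layout: StripLayout | None = None,
    dr: DoseResponse | None = None,
) -> dict:
    """End-to-end three-level classification on noise-free strips across
    the five study devices, including detection and rectification
    (each strip is photographed at a slightly different pose)."""
    layout = layout or StripLayout()
    dr = dr or DoseResponse()
    model = fit_concentration_model(seed=seed, layout=layout, dr=dr, photographed=True)
    devices = study_device_models()
    n_correct = n_total = 0
    calls = []
    for di, device in enumerate(devices):
        for ci, c in enumerate(concentrations):
            pose = Pose.framed(layout, rotation_deg=(-8 + 4 * di + ci), perspective=0.02)
            img, _ = render_strip(layout, c, dr, device, pose, seed=seed + 97 * di + ci)
            rec = analyze_image(img, model, layout=layout)
            ok = rec.result is not None and rec.result.level == _true_level(c)
            calls.append((di, c, None if rec.result is None else rec.result.level, ok))
            n_correct += ok
            n_total += 1
    return {
        "accuracy_pct": 100.0 * n_correct / n_total,
        "n": n_total,
        "calls": calls,
    }


def illumination_invariance_study(
    gains: tuple[float, ...] = (0.7, 0.85, 1.0, 1.15, 1.3),
    concentrations: tuple[float, ...] = (10.0, 25.0, 50.0),
    seed: int = 0,
    layout: StripLayout | None = None,
    dr: DoseResponse | None = None,
) -> dict:
    """Re-photograph the same strips under global illumination gains of
    0.7–1.3x and count classification changes relative to unit gain.

    Because line intensity is a background-corrected absorbance, a global
    gain adds a constant to the whole profile and cancels exactly.
    """
    layout = layout or StripLayout()
    dr = dr or DoseResponse()
    model = fit_concentration_model(seed=seed, layout=layout, dr=dr, photographed=True)
    pose = Pose.framed(layout, rotation_deg=3.0)
    changed = total = 0
    for ci, c in enumerate(concentrations):
        levels = {}
        for g in gains:
            device = DeviceModel(intensity_scale=g, noise_sd=0.0)
            img, _ = render_strip(layout, c, dr, device, pose, seed=seed + ci)
            rec = analyze_image(img, model, layout=layout)
            levels[g] = None if rec.result is None else rec.result.level
        for g in gains:
            total += 1
            changed += levels[g] != levels[1.0]
    return {
        "unchanged_pct": 100.0 * (total - changed) / total,
        "n": total,
        "n_changed": changed,
    }


def reference_device() -> DeviceModel:
    """The designated color-reference capture platform (neutral camera)."""
    return DeviceModel(noise_sd=0.004)


def distorted_device() -> DeviceModel:
    """A second platform with tint, vignetting, crosstalk and exposure
    differences — the device to be aligned onto the reference."""
    return DeviceModel(
        wb_gains=(1.15, 1.0, 0.9),
        shading_coeffs=(1.0, 0.02, -0.01, -0.08, 0.01, -0.05),
        color_matrix=((0.95, 0.04, 0.01), (0.03, 0.94, 0.03), (0.02, 0.05, 0.93)),
        intensity_scale=0.95,
        noise_sd=0.004,
    )


def cross_device_study(
    n_strips: int = 12,
    seed: int = 0,
    n_fit_pairs: int = 3,
    layout: StripLayout | None = None,
    dr: DoseResponse | None = None,
) -> dict:
    """Paired-capture panel spanning the measurement range: learn the
    device-to-reference photometric transform on a few strips, then
    compare category calls and concentration estimates between aligned
    source-device images and reference-device images on a held-out panel."""
    layout = layout or StripLayout()
    dr = dr or DoseResponse()
    dev_a, dev_b = distorted_device(), reference_device()
    model = fit_concentration_model(seed=seed, layout=layout, dr=dr)

    fit_concs = np.linspace(15.0, 90.0, n_fit_pairs)
    fit_pairs = [
        make_paired_captures(layout, c, dr, dev_a, dev_b, seed=seed + 1000 + i)[:2]
        for i, c in enumerate(fit_concs)
    ]
    aligner = PhotometricAligner(layout=layout).fit(fit_pairs)

    concs = np.linspace(5.0, 100.0, n_strips)
    agree = 0
    conc_a, conc_b = [], []
    for i, c in enumerate(concs):
        img_a, img_b, _ = make_paired_captures(
            layout, float(c), dr, dev_a, dev_b, seed=seed + i
        )
        aligned = aligner.transform(img_a)
        rs_a = RectifiedStrip(aligned.pixels, np.eye(3))
        rs_b = RectifiedStrip(srgb_decode(img_b.pixels), np.eye(3))
        sig_a = measure_rectified(rs_a, layout)
        sig_b = measure_rectified(rs_b, layout)
        res_a, res_b = model.classify(sig_a), model.classify(sig_b)
        agree += res_a.level == res_b.level
        conc_a.append(model.predict(sig_a)[0])
        conc_b.append(model.predict(sig_b)[0])
    r, r2 = pearson_r2(conc_a, conc_b)
    return {
        "agreement_pct": 100.0 * agree / n_strips,
        "n": n_strips,
        "pearson_r": r,
        "r_squared": r2,
        "concentrations_a": conc_a,
        "concentrations_b": conc_b,
    }


def expected_lod(
    model: ConcentrationRegressor,
    dr: DoseResponse,
    density_jitter_sd: float,
) -> float:
    """The configured (analytic) detection limit implied by the generator.

    Density jitter with SD sigma_d on the test line propagates through the
    linear readout chain to a concentration SD of
    ``alpha * sigma_d / C_LINE_DENSITY`` (the ladder maps density 1:1 into
    intensity and S_T/C divides by the control density), so the EP17
    construction predicts
    ``LoD = c_hat(blank) + 2 * 1.645 * alpha * sigma_d / C_LINE_DENSITY``.
    """
    blank_pred = model.alpha_ * dr.density(0.0) / C_LINE_DENSITY + model.beta_
    sigma_c = model.alpha_ * density_jitter_sd / C_LINE_DENSITY
    return float(blank_pred + 2 * 1.645 * sigma_c)


def synthetic_lod_study(
    seed: int = 0,
    n_replicates: int = 20,
    low_level: float = 5.0,
    density_jitter_sd: float = DEFAULT_DENSITY_JITTER_SD,
    layout: StripLayout | None = None,
    dr: DoseResponse | None = None,
) -> dict:
    """EP17 blank/low-level study through the full image pipeline.

    Blank and low-level replicates carry test-line density jitter
    (replicate chemistry variability) plus pixel noise; their raw
    (uncensored) concentration estimates feed the LoB/LoD formulas. The
    recovered LoD is compared with the analytically configured limit.
    """
    layout = layout or StripLayout()
    dr = dr or DoseResponse()
    model = fit_concentration_model(seed=seed, layout=layout, dr=dr)
    device = DeviceModel()  # neutral sRGB camera with default pixel noise

    def replicate_estimates(c: float, tag: int) -> list[float]:
        out = []
        for rep in range(n_replicates):
            img, _ = render_strip(
                layout,
                c,
                dr,
                device,
                seed=int(np.random.SeedSequence((seed, tag, rep)).generate_state(1)[0] % 2**31),
                density_jitter_sd=density_jitter_sd,
            )
            rs = RectifiedStrip(srgb_decode(img.pixels), np.eye(3))
            out.append(float(model.predict(measure_rectified(rs, layout))[0]))
        return out

    blanks = replicate_estimates(0.0, 1)
    lows = replicate_estimates(low_level, 2)
    limits = detection_limits(blanks, lows)
    configured = expected_lod(model, dr, density_jitter_sd)
    return {
        "mean_blank": limits.mean_blank,
        "sd_blank": limits.sd_blank,
        "sd_low": limits.sd_low,
        "lob": limits.lob,
        "lod": limits.lod,
        "configured_lod": configured,
        "lod_over_configured": limits.lod / configured,
        "n": n_replicates,
    }
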