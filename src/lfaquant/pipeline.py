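"""End-to-end orchestration: photograph -> classified result, and the
batch drivers behind the validation studies.

The per-image chain is: detect -> rectify -> (optional photometric
alignment) -> QC -> absorbance profile -> line measurements -> per-image
ladder calibration -> standardized signals -> pre-calibrated concentration
regression -> three-level call. QC failure on the control line
short-circuits: the record carries flags and no concentration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._color import srgb_decode
from .calibration import (
    MODEL_VERSION,
    ClassifiedResult,
    ConcentrationRegressor,
    ReferenceCalibrator,
    StandardizedSignals,
    standardize,
)
from .errors import LFAError
from .geometry import QCReport, detect_strip, qc_check, rectify
from .image import RectifiedStrip, StripImage, read_png
from .layout import REF_IDS, DeviceModel, DoseResponse, Pose, StripLayout
from .photometric import PhotometricTransform
from .signals import build_ladder, extract_profile, measure_all_lines
from .stats import AgreementReport, agreement_report, contingency_table
from .synthetic import generate_validation_panel

logger = logging.getLogger("lfaquant")

DEFAULT_PANEL_LEVELS = (5.0, 10.0, 20.0, 30.0, 45.0, 60.0, 80.0, 100.0)


@dataclass
class AnalysisRecord:
    """One strip's full traceable analysis output."""

    input_path: str
    qc: QCReport
    signals: StandardizedSignals | None
    result: ClassifiedResult | None
    model_version: str = MODEL_VERSION
    calibration_version: str = "panel-1"
    # deterministic by default so batch outputs are byte-stable; the app
    # layer stamps wall-clock time explicitly when provenance needs it
    timestamp: str = ""

    def to_dict(self) -> dict:
        return {
            "input_path": self.input_path,
            "qc": {
                "overexposed_frac": self.qc.overexposed_frac,
                "c_line_present": self.qc.c_line_present,
                "flags": list(self.qc.flags),
            },
            "signals": None
            if self.signals is None
            else {"s_t": self.signals.s_t, "s_c": self.signals.s_c, "s_tc": self.signals.s_tc},
            "result": None
            if self.result is None
            else {
                "concentration": self.result.concentration,
                "censored": self.result.censored,
                "level": self.result.level,
                "label": self.result.label,
                "display": self.result.display,
            },
            "model_version": self.model_version,
            "calibration_version": self.calibration_version,
            "timestamp": self.timestamp,
        }


def measure_rectified(
    rs: RectifiedStrip, layout: StripLayout, degree: int = 1
) -> StandardizedSignals:
    """Rectified strip -> standardized signals via the per-image ladder."""
    profile = extract_profile(rs, layout)
    meas = measure_all_lines(profile, layout)
    ladder = build_ladder([meas[r] for r in REF_IDS], layout.nominal_signals)
    curve = ReferenceCalibrator(degree=degree).fit(ladder)
    return standardize(curve, meas["T"].intensity, meas["C"].intensity)


def analyze_image(
    source: str | Path | StripImage,
    model: ConcentrationRegressor,
    layout: StripLayout | None = None,
    transform: PhotometricTransform | None = None,
    degree: int = 1,
    c_min_contrast: float = 0.05,
    overexposure_frac_max: float = 0.05,
    calibration_version: str = "panel-1",
) -> AnalysisRecord:
    """Run the full chain on a photograph (path or in-memory image).

    QC 'insufficient reaction' short-circuits with flags and no result;
    other per-stage errors propagate, prefixed with the stage name.
    """
    layout = layout or StripLayout()
    if isinstance(source, (str, Path)):
        img = read_png(source)
        path = str(source)
    else:
        img, path = source, "<memory>"

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except LFAError as exc:
            raise type(exc)(f"[{name}] {exc}") from exc

    corners = stage("detect", detect_strip, img)
    rs = stage("rectify", rectify, img, corners, layout)
    if transform is not None:
        aligned = transform.apply(StripImage(rs.pixels, "linear"))
        rs = RectifiedStrip(aligned.pixels, rs.homography)
    qc = stage("qc", qc_check, rs, layout, c_min_contrast, overexposure_frac_max, raw=img)
    if "insufficient reaction" in qc.flags:
        return AnalysisRecord(path, qc, None, None, calibration_version=calibration_version)
    signals = stage("measure", measure_rectified, rs, layout, degree)
    result = model.classify(signals)
    return AnalysisRecord(path, qc, signals, result, calibration_version=calibration_version)


def fit_concentration_model(
    levels: tuple[float, ...] = DEFAULT_PANEL_LEVELS,
    replicates: int = 3,
    seed: int = 0,
    layout: StripLayout | None = None,
    dr: DoseResponse | None = None,
    device: DeviceModel | None = None,
    mode: str = "ST_over_SC",
    degree: int = 1,
    density_jitter_sd: float = 0.0,
    photographed: bool = False,
) -> ConcentrationRegressor:
    """Calibrate the concentration regression on a synthetic reference
    dilution panel run through the full measurement path (the analogue of
    fitting alpha/beta on reference standards).

    With ``photographed=True`` the panel is rendered as framed photographs
    and measured through detection and rectification, so the calibration
    shares the optical path — including resampling blur — of the images
    it will later be applied to. The default measures canonical
    (identity-pose) captures, the reference path for ROI-level studies.
    """
    layout = layout or StripLayout()
    dr = dr or DoseResponse()
    device = device or DeviceModel.identity()
    panel = generate_validation_panel(
        [(c, replicates) for c in levels],
        seed=seed,
        layout=layout,
        dr=dr,
        device=device,
        pose=None if photographed else Pose.identity(layout),
        density_jitter_sd=density_jitter_sd,
    )
    sig, conc = [], []
    for img, truth in panel:
        if photographed:
            rs = rectify(img, detect_strip(img), layout)
        else:
            # identity pose: the image is already canonical, only gamma-decode
            pixels = img.pixels if img.color_space == "linear" else srgb_decode(img.pixels)
            rs = RectifiedStrip(pixels, np.eye(3))
        sig.append(measure_rectified(rs, layout, degree))
        conc.append(truth.true_concentration)
    return ConcentrationRegressor(mode=mode).fit(sig, conc)


def run_method_comparison(records: pd.DataFrame | str | Path, k: int = 3) -> AgreementReport:
    """Paired (candidate_level, reference_conc) records -> agreement report.

    Reference concentrations are binned with the same 20/30 ng/mL
    thresholds as the candidate calls. Malformed rows are skipped and
    counted in the log.
    """
    if isinstance(records, (str, Path)):
        records = pd.read_csv(records)
    needed = {"candidate_level", "reference_conc"}
    if not needed.issubset(records.columns):
        raise ValueError(f"records need columns {sorted(needed)}")
    cand, ref = [], []
    skipped = 0
    for _, row in records.iterrows():
        try:
            lvl = int(row["candidate_level"])
            conc = float(row["reference_conc"])
            if not (1 <= lvl <= k) or not np.isfinite(conc) or conc < 0:
                raise ValueError
        except (TypeError, ValueError):
            skipped += 1
            continue
        cand.append(lvl)
        ref.append(1 if conc < 20 else (2 if conc <= 30 else 3))
    if skipped:
        logger.warning("skipped %d malformed rows", skipped)
    if not cand:
        raise ValueError("no valid pairs")
    return agreement_report(contingency_table(cand, ref, k))
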