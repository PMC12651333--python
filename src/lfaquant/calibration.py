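"""Per-image signal standardization and concentration regression.

Two estimators implement the readout chain:

* :class:`ReferenceCalibrator` — least-squares fit of the nominal ladder
  signals R_k on a polynomial in the measured intensities I_k, giving the
  per-image calibration function ``S = g(I) = a0 + a1*I (+ a2*I^2)``. Raw
  T/C intensities are mapped through g to standardized signals
  ``S_T = g(I_T)``, ``S_C = g(I_C)`` and the control-normalized ratio
  ``S_T/S_C``, which removes residual device and illumination effects.

* :class:`ConcentrationRegressor` — the pre-calibrated linear model
  ``25(OH)D (ng/mL) = alpha * S + beta`` (S is S_T or S_T/S_C), fitted
  once on a reference dilution panel, plus censoring at the 5–100 ng/mL
  measurement range and the clinical three-level call: deficient
  (<20 ng/mL), insufficient (20–30 ng/mL), sufficient (>30 ng/mL).

Both follow scikit-learn conventions (``fit`` / ``transform`` or
``predict``, ``get_params``, fitted attributes with a trailing
underscore) and compose with sklearn pipelines.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin

from .errors import CalibrationError, ControlSignalError, LadderUnusableError
from .signals import ReferenceLadder

MODEL_VERSION = "lfaquant-0.1"

RANGE_LOW = 5.0
RANGE_HIGH = 100.0
LEVEL_THRESHOLDS = (20.0, 30.0)
LEVEL_LABELS = {1: "deficient", 2: "insufficient", 3: "sufficient"}


@dataclass
class StandardizedSignals:
    """Standardized T/C signals of one strip."""

    s_t: float
    s_c: float

    @property
    def s_tc(self) -> float:
        return self.s_t / self.s_c


@dataclass
class ClassifiedResult:
    """Semi-quantitative readout: a concentration (possibly censored at the
    measurement range) and the clinical three-level call."""

    concentration: float
    censored: str | None  # None, "<5" or ">100"
    level: int
    label: str

    @property
    def display(self) -> str:
        if self.censored:
            return self.censored
        return f"{self.concentration:.1f}"


class ReferenceCalibrator(TransformerMixin, BaseEstimator):
    """Per-image multi-point calibration curve ``S = g(I)``.

    Parameters
    ----------
    degree : 1 or 2
        Polynomial degree of g. Degree 1 is the default; the quadratic
        term accommodates mild nonlinearity of the intensity response.

    Attributes
    ----------
    a0_, a1_, a2_ : float
        Coefficients of g (``a2_`` is 0 when degree is 1).
    rms_ : float
        Root-mean-square fit residual over the surviving ladder points.
    i_range_ : (float, float)
        Observed intensity range of the ladder; g is validated to be
        strictly increasing over it.
    """

    def __init__(self, degree: int = 1):
        self.degree = degree

    def fit(self, X, y=None) -> "ReferenceCalibrator":
        """Fit from a :class:`ReferenceLadder`, or from intensities ``X``
        and nominal signals ``y``."""
        if self.degree not in (1, 2):
            raise ValueError("degree must be 1 or 2")
        if isinstance(X, ReferenceLadder):
            intens, nominal = X.surviving()
        else:
            intens = np.asarray(X, dtype=float).ravel()
            nominal = np.asarray(y, dtype=float).ravel()
        if intens.size < self.degree + 1:
            raise LadderUnusableError(
                f"need at least {self.degree + 1} ladder points, got {intens.size}"
            )
        design = np.vander(intens, self.degree + 1, increasing=True)
        coef, _, rank, _ = np.linalg.lstsq(design, nominal, rcond=None)
        if rank < self.degree + 1:
            raise LadderUnusableError("ladder unusable: rank-deficient design matrix")
        self.a0_ = float(coef[0])
        self.a1_ = float(coef[1])
        self.a2_ = float(coef[2]) if self.degree == 2 else 0.0
        self.rms_ = float(np.sqrt(np.mean((design @ coef - nominal) ** 2)))
        self.i_range_ = (float(intens.min()), float(intens.max()))
        self._check_monotone()
        return self

    def _check_monotone(self) -> None:
        lo, hi = self.i_range_
        # derivative a1 + 2*a2*I is linear in I: checking the ends suffices
        d_lo, d_hi = self.a1_ + 2 * self.a2_ * lo, self.a1_ + 2 * self.a2_ * hi
        if d_lo <= 0 or d_hi <= 0:
            raise CalibrationError("calibration curve is not strictly increasing over the ladder")

    def transform(self, X):
        """Evaluate ``g(I)``; accepts scalars or arrays, preserving shape."""
        I = np.asarray(X, dtype=float)
        out = self.a0_ + self.a1_ * I + self.a2_ * I**2
        return float(out) if out.ndim == 0 else out

    __call__ = transform


def standardize(curve: ReferenceCalibrator, i_t: float, i_c: float) -> StandardizedSignals:
    """Map raw T/C intensities through the calibration curve.

    Raises :class:`ControlSignalError` when the control signal is
    non-positive (the run is invalid; maps to the 'insufficient reaction'
    QC condition).
    """
    if i_t < 0 or i_c < 0:
        raise ValueError("intensities must be non-negative")
    s_t, s_c = float(curve.transform(i_t)), float(curve.transform(i_c))
    if s_c <= 0:
        raise ControlSignalError("control signal invalid: S_C <= 0")
    return StandardizedSignals(s_t=s_t, s_c=s_c)


def classify_value(
    raw: float,
    range_low: float = RANGE_LOW,
    range_high: float = RANGE_HIGH,
    thresholds: tuple[float, float] = LEVEL_THRESHOLDS,
) -> ClassifiedResult:
    """Censor at the measurement range and assign the clinical level.

    The middle class is the closed interval [20, 30]; values below the
    range report "<5" (level 1), above it ">100" (level 3) — censoring is
    explicit, never a silent clamp.
    """
    t_lo, t_hi = thresholds
    if raw < range_low:
        return ClassifiedResult(float(raw), f"<{range_low:g}", 1, LEVEL_LABELS[1])
    if raw > range_high:
        return ClassifiedResult(float(raw), f">{range_high:g}", 3, LEVEL_LABELS[3])
    level = 1 if raw < t_lo else (2 if raw <= t_hi else 3)
    return ClassifiedResult(float(raw), None, level, LEVEL_LABELS[level])


class ConcentrationRegressor(RegressorMixin, BaseEstimator):
    """Linear concentration model ``c = alpha * S + beta``.

    Parameters
    ----------
    mode : "ST_over_SC" (default) or "ST"
        Predictor: the control-normalized ratio S_T/S_C, or S_T alone.
    range_low, range_high : float
        Measurement range (ng/mL); predictions outside are censored.
    thresholds : (float, float)
        Clinical level cut-points (deficient/insufficient/sufficient).

    Attributes
    ----------
    alpha_, beta_ : float
        Fitted regression coefficients.
    """

    def __init__(
        self,
        mode: str = "ST_over_SC",
        range_low: float = RANGE_LOW,
        range_high: float = RANGE_HIGH,
        thresholds: tuple[float, float] = LEVEL_THRESHOLDS,
    ):
        self.mode = mode
        self.range_low = range_low
        self.range_high = range_high
        self.thresholds = thresholds

    def _predictor(self, X) -> np.ndarray:
        if isinstance(X, StandardizedSignals):
            X = [X]
        if isinstance(X, (list, tuple)) and len(X) and isinstance(X[0], StandardizedSignals):
            vals = [s.s_tc if self.mode == "ST_over_SC" else s.s_t for s in X]
            return np.asarray(vals, dtype=float)
        return np.asarray(X, dtype=float).ravel()

    def fit(self, X, y) -> "ConcentrationRegressor":
        """Least squares of known concentrations ``y`` on the predictor.

        ``X`` may be a list of :class:`StandardizedSignals` or an array of
        predictor values.
        """
        if self.mode not in ("ST", "ST_over_SC"):
            raise ValueError("mode must be 'ST' or 'ST_over_SC'")
        s = self._predictor(X)
        y = np.asarray(y, dtype=float).ravel()
        if s.size != y.size:
            raise ValueError("X and y must have the same length")
        if s.size < 3 or np.unique(y).size < 2:
            raise ValueError("need at least 3 samples spanning at least 2 concentrations")
        if np.ptp(s) == 0:
            raise ValueError("zero variance in the predictor")
        design = np.column_stack([s, np.ones_like(s)])
        (alpha, beta), *_ = np.linalg.lstsq(design, y, rcond=None)
        self.alpha_ = float(alpha)
        self.beta_ = float(beta)
        return self

    def predict(self, X) -> np.ndarray:
        """Raw (uncensored) concentration estimates in ng/mL."""
        return self.alpha_ * self._predictor(X) + self.beta_

    def classify(self, X) -> ClassifiedResult | list[ClassifiedResult]:
        """Censored, level-classified results."""
        single = isinstance(X, StandardizedSignals) or np.isscalar(X)
        raw = np.atleast_1d(self.predict(X))
        results = [
            classify_value(r, self.range_low, self.range_high, self.thresholds) for r in raw
        ]
        return results[0] if single else results


def estimate_concentration(model: ConcentrationRegressor, signals: StandardizedSignals) -> ClassifiedResult:
    """Convenience wrapper: one strip's signals -> classified result."""
    return model.classify(signals)


def save_model(path: str | Path, model: ConcentrationRegressor, calibration_version: str = "panel-1") -> None:
    """Serialize a fitted concentration model with version tags."""
    payload = {
        "model_version": MODEL_VERSION,
        "calibration_version": calibration_version,
        "mode": model.mode,
        "alpha": model.alpha_,
        "beta": model.beta_,
        "range_low": model.range_low,
        "range_high": model.range_high,
        "thresholds": list(model.thresholds),
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")


def load_model(path: str | Path) -> tuple[ConcentrationRegressor, dict]:
    payload = json.loads(Path(path).read_text())
    model = ConcentrationRegressor(
        mode=payload["mode"],
        range_low=payload["range_low"],
        range_high=payload["range_high"],
        thresholds=tuple(payload["thresholds"]),
    )
    model.alpha_ = payload["alpha"]
    model.beta_ = payload["beta"]
    return model, payload
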