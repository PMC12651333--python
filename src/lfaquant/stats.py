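"""Analytical-validation statistics.

Detection limits follow the CLSI EP17-A2 constructions
``LoB = mean_blank + 1.645 * SD_blank`` and ``LoD = LoB + 1.645 * SD_low``
(sample SDs with the n-1 denominator). Method agreement on the ordinal
three-level scale uses overall and per-category percent agreement with
Wilson score intervals (z = 1.959964) and Cohen's kappa, optionally
weighted for ordinal near-misses with ``w_ij = 1 - (|i-j|/(K-1))^q``
(q = 1 linear, q = 2 quadratic). Continuous comparisons use Pearson
r / R^2 and Welch's t confidence interval for a mean difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

EP17_MULTIPLIER = 1.645


@dataclass
class DetectionLimits:
    """EP17-style blank/low-level summary and the derived limits (ng/mL)."""

    mean_blank: float
    sd_blank: float
    sd_low: float
    lob: float
    lod: float


def limit_of_blank(
    blanks=None, *, mean: float | None = None, sd: float | None = None
) -> float:
    """``LoB = mean_blank + 1.645 * SD_blank`` from raw blank replicates or
    from a (mean, sd) summary."""
    if blanks is not None:
        blanks = np.asarray(blanks, dtype=float)
        if blanks.size < 2:
            raise ValueError("need at least 2 blank replicates")
        mean, sd = float(blanks.mean()), float(blanks.std(ddof=1))
    if mean is None or sd is None:
        raise ValueError("provide blank replicates or mean and sd")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    return float(mean + EP17_MULTIPLIER * sd)


def limit_of_detection(lob: float, low_replicates=None, *, sd_low: float | None = None) -> float:
    """``LoD = LoB + 1.645 * SD_low`` from low-level replicates or their SD."""
    if low_replicates is not None:
        low = np.asarray(low_replicates, dtype=float)
        if low.size < 2:
            raise ValueError("need at least 2 low-level replicates")
        sd_low = float(low.std(ddof=1))
    if sd_low is None:
        raise ValueError("provide low-level replicates or sd_low")
    if sd_low < 0:
        raise ValueError("sd_low must be non-negative")
    return float(lob + EP17_MULTIPLIER * sd_low)


def detection_limits(blanks, low_replicates) -> DetectionLimits:
    """Full EP17 summary from raw blank and low-level measurements."""
    blanks = np.asarray(blanks, dtype=float)
    low = np.asarray(low_replicates, dtype=float)
    lob = limit_of_blank(blanks)
    return DetectionLimits(
        mean_blank=float(blanks.mean()),
        sd_blank=float(blanks.std(ddof=1)),
        sd_low=float(low.std(ddof=1)),
        lob=lob,
        lod=limit_of_detection(lob, low),
    )


def validate_table(table) -> np.ndarray:
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("contingency table must be square")
    if np.any(t < 0) or t.sum() == 0 or np.any(t != np.round(t)):
        raise ValueError("table entries must be non-negative integers with a positive total")
    return t.astype(float)


def contingency_table(candidate_levels, reference_levels, k: int = 3) -> np.ndarray:
    """K x K cross-classification: rows candidate, columns reference;
    levels are 1-based ordinal categories."""
    cand = np.asarray(candidate_levels, dtype=int)
    ref = np.asarray(reference_levels, dtype=int)
    if cand.shape != ref.shape or cand.size == 0:
        raise ValueError("need equal-length, non-empty level vectors")
    if np.any((cand < 1) | (cand > k) | (ref < 1) | (ref > k)):
        raise ValueError(f"levels must be in 1..{k}")
    table = np.zeros((k, k), dtype=int)
    np.add.at(table, (cand - 1, ref - 1), 1)
    return table


def percent_agreement(table) -> tuple[float, list[float | None]]:
    """Overall percent agreement (100 * trace / total) and per reference
    category (100 * diagonal / column total; ``None`` for empty columns)."""
    t = validate_table(table)
    overall = 100.0 * np.trace(t) / t.sum()
    per = []
    for j in range(t.shape[1]):
        colsum = t[:, j].sum()
        per.append(100.0 * t[j, j] / colsum if colsum > 0 else None)
    return float(overall), per


def wilson_ci(successes: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion (no continuity
    correction), returned as proportions in [0, 1]."""
    if n < 1 or not 0 <= successes <= n:
        raise ValueError("require n >= 1 and 0 <= successes <= n")
    lo, hi = proportion_confint(successes, n, alpha=1 - conf, method="wilson")
    return max(0.0, float(lo)), min(1.0, float(hi))


def cohen_kappa(table, weights: str = "none") -> float:
    """Chance-corrected agreement ``(P_o - P_e) / (1 - P_e)``.

    ``weights``: "none" (identity agreement), "linear" or "quadratic"
    ordinal weights ``w_ij = 1 - (|i-j|/(K-1))^q``.
    """
    t = validate_table(table)
    k = t.shape[0]
    p = t / t.sum()
    if weights == "none":
        w = np.eye(k)
    elif weights in ("linear", "quadratic"):
        q = 1 if weights == "linear" else 2
        i, j = np.indices((k, k))
        w = 1.0 - (np.abs(i - j) / (k - 1)) ** q
    else:
        raise ValueError("weights must be 'none', 'linear' or 'quadratic'")
    po = float(np.sum(w * p))
    pe = float(np.sum(w * np.outer(p.sum(axis=1), p.sum(axis=0))))
    if pe >= 1.0 - 1e-12:
        # all mass in a single agreeing category: perfect agreement by
        # convention; anything else with P_e = 1 is genuinely undefined
        if po >= 1.0 - 1e-12:
            return 1.0
        raise ValueError("kappa undefined: expected agreement is 1 (degenerate marginals)")
    return (po - pe) / (1.0 - pe)


def pearson_r2(x, y) -> tuple[float, float]:
    """Pearson correlation and its square."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    r = float(sps.pearsonr(x, y).statistic)
    return r, r * r


def welch_ci(x, y, conf: float = 0.95) -> tuple[float, float]:
    """Welch's t confidence interval for ``mean(x) - mean(y)``
    (Welch–Satterthwaite degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    res = sps.ttest_ind(x, y, equal_var=False)
    ci = res.confidence_interval(confidence_level=conf)
    return float(ci.low), float(ci.high)


@dataclass
class AgreementReport:
    """Categorical method-comparison summary on the ordinal level scale."""

    table: np.ndarray
    overall_pct: float
    per_category_pct: list[float | None]
    wilson_cis_pct: dict[str, tuple[float, float]]
    kappa: float
    kappa_weighted: float

    def to_dict(self) -> dict:
        return {
            "table": np.asarray(self.table).astype(int).tolist(),
            "overall_pct": self.overall_pct,
            "per_category_pct": self.per_category_pct,
            "wilson_cis_pct": {k: list(v) for k, v in self.wilson_cis_pct.items()},
            "kappa": self.kappa,
            "kappa_weighted": self.kappa_weighted,
        }

    def summary(self) -> str:
        lines = [f"overall agreement: {self.overall_pct:.1f}%"]
        lo, hi = self.wilson_cis_pct["overall"]
        lines[-1] += f" (95% CI {lo:.1f}-{hi:.1f}%)"
        for j, pct in enumerate(self.per_category_pct, start=1):
            if pct is None:
                lines.append(f"  level {j}: no reference samples")
            else:
                lo, hi = self.wilson_cis_pct[f"level{j}"]
                lines.append(f"  level {j}: {pct:.1f}% (95% CI {lo:.1f}-{hi:.1f}%)")
        lines.append(f"kappa (unweighted): {self.kappa:.3f}")
        lines.append(f"kappa (linear weights): {self.kappa_weighted:.3f}")
        return "\n".join(lines)


def agreement_report(table, conf: float = 0.95) -> AgreementReport:
    """Assemble the full agreement summary for a K x K table.

    The reported kappa is unweighted by default (the convention that
    reproduces published three-level validation results); a linear-weighted
    kappa is included alongside for the ordinal reading.
    """
    t = validate_table(table).astype(int)
    overall, per = percent_agreement(t)
    cis: dict[str, tuple[float, float]] = {}
    lo, hi = wilson_ci(int(np.trace(t)), int(t.sum()), conf)
    cis["overall"] = (100 * lo, 100 * hi)
    for j in range(t.shape[1]):
        colsum = int(t[:, j].sum())
        if colsum > 0:
            lo, hi = wilson_ci(int(t[j, j]), colsum, conf)
            cis[f"level{j + 1}"] = (100 * lo, 100 * hi)
    return AgreementReport(
        table=t,
        overall_pct=overall,
        per_category_pct=per,
        wilson_cis_pct=cis,
        kappa=cohen_kappa(t, "none"),
        kappa_weighted=cohen_kappa(t, "linear"),
    )
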