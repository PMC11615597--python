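"""Descriptive group summaries and agreement / repeatability statistics.

Group values are expressed as median (IQR); paired method comparison uses
Pearson correlation and Bland-Altman limits of agreement, with a
Shapiro-Wilk check that the differences are plausibly normal (a warning
flag, not a hard stop).  Test-retest-rescan repeatability is summarized as
the maximum across cardiac phases of the across-scan measurement range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .motion import MotionCurves

_METRICS = [c for c in MotionCurves.COLUMNS if c != "phase"]


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman bias and limits of agreement plus Pearson correlation.

    Differences are first-argument-minus-second; ``loa_low``/``loa_high``
    are bias -/+ 1.96 * SD(differences, ddof=1).  ``normality_warning`` is
    set when Shapiro-Wilk rejects normality of the differences at 0.05.
    """

    bias: float
    loa_low: float
    loa_high: float
    pearson_r: float
    shapiro_p: float
    n: int

    @property
    def normality_warning(self) -> bool:
        return self.shapiro_p < 0.05

    def to_dict(self) -> dict:
        return {
            "bias": self.bias,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "pearson_r": self.pearson_r,
            "shapiro_p": self.shapiro_p,
            "n": self.n,
            "normality_warning": self.normality_warning,
        }


@dataclass(frozen=True)
class VariabilityResult:
    """Across-scan measurement ranges per phase and their maximum."""

    metric: str
    per_phase_range: np.ndarray
    max_variability: float


@dataclass(frozen=True)
class AreaDiameter:
    """Cross-sectional area and its equivalent circular diameter DA = 2*sqrt(A/pi)."""

    area_mm2: float
    da_mm: float


def group_median_iqr(curves: list[MotionCurves]) -> pd.DataFrame:
    """Per-phase median and IQR curves over subjects, tidy one row per phase/metric.

    Quantiles use linear interpolation between order statistics; IQR is the
    width Q3 - Q1 (columns ``q1`` and ``q3`` carry the interval rendering).
    """
    if not curves:
        raise ValueError("need at least one curve set")
    n_phases = curves[0].n_phases
    if any(c.n_phases != n_phases for c in curves):
        raise ValueError("mixed phase counts across subjects")
    rows = []
    for metric in _METRICS:
        stack = np.stack([c.metric(metric) for c in curves])  # (subjects, phases)
        q1, med, q3 = np.quantile(stack, [0.25, 0.5, 0.75], axis=0)
        for t in range(n_phases):
            rows.append(
                {
                    "phase": t,
                    "metric": metric,
                    "median": med[t],
                    "q1": q1[t],
                    "q3": q3[t],
                    "iqr": q3[t] - q1[t],
                }
            )
    return pd.DataFrame(rows)


def agreement_stats(a: np.ndarray, b: np.ndarray) -> AgreementStats:
    """Pearson correlation and Bland-Altman analysis of paired measurements."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired measurements must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance: Pearson correlation undefined")
    r = float(sps.pearsonr(a, b).statistic)
    if np.ptp(diff) == 0:
        shapiro_p = 1.0  # constant differences: trivially no evidence against normality
    else:
        shapiro_p = float(sps.shapiro(diff).pvalue)
    result = AgreementStats(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        pearson_r=r,
        shapiro_p=shapiro_p,
        n=len(a),
    )
    if result.normality_warning:
        warnings.warn(
            f"Shapiro-Wilk p = {shapiro_p:.3g} < 0.05: differences look "
            "non-normal; Bland-Altman limits may be unreliable",
            stacklevel=2,
        )
    return result


def max_variability(curves: list[MotionCurves], metric: str) -> VariabilityResult:
    """Largest across-scan difference over all cardiac phases (test/retest/rescan)."""
    if len(curves) != 3:
        raise ValueError(f"expected exactly 3 scans (test, retest, rescan), got {len(curves)}")
    n_phases = curves[0].n_phases
    if any(c.n_phases != n_phases for c in curves):
        raise ValueError("mixed phase counts across scans")
    stack = np.stack([c.metric(metric) for c in curves])  # (3, phases)
    per_phase = stack.max(axis=0) - stack.min(axis=0)
    return VariabilityResult(metric, per_phase, float(per_phase.max()))


def diameter_from_area(area_mm2: float) -> AreaDiameter:
    """Equivalent circular diameter of a cross-sectional area, DA = 2*sqrt(A/pi)."""
    if area_mm2 < 0:
        raise ValueError("area must be non-negative")
    return AreaDiameter(area_mm2=float(area_mm2), da_mm=2.0 * math.sqrt(area_mm2 / math.pi))
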