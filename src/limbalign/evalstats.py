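"""Evaluation statistics for landmark detection and angle agreement.

Implements the metrics used to compare automatic against manual
measurements of lower-limb alignment:

* mean radial error (MRE): ``1/n * sum_i R_i`` over the Euclidean distances
  R_i between predicted and reference landmark positions;
* mean absolute difference (MAD) of angles, with the sample standard
  deviation of the absolute differences;
* angle-deviation (AD) rates: the fraction of limbs whose absolute angle
  difference is strictly below a clinical threshold (1 deg and 2 deg by
  default — differences above 2 deg are the conventional bar for clinical
  relevance);
* Bland-Altman bias and 95% limits of agreement (bias +/- 1.96 * sd of the
  signed differences, sample sd with n-1 denominator);
* Pearson chi-square on accuracy/inaccuracy contingency tables, without
  continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "LandmarkErrors",
    "AgreementReport",
    "ContingencyTable",
    "mre",
    "agreement",
    "pearson_chi_square",
    "uniform_prediction_mre",
]

CLINICAL_AD_THRESHOLDS_DEG = (1.0, 2.0)


@dataclass
class LandmarkErrors:
    """Radial (Euclidean) landmark errors with their unit."""

    radial_errors: np.ndarray
    unit: str = "px"  # "px" or "mm"

    def __post_init__(self) -> None:
        self.radial_errors = np.asarray(self.radial_errors, dtype=float).reshape(-1)
        if np.any(self.radial_errors < 0) or not np.all(np.isfinite(self.radial_errors)):
            raise ValueError("radial errors must be finite and non-negative")

    @property
    def n(self) -> int:
        return self.radial_errors.size

    def to_mm(self, spacing_mm: float) -> "LandmarkErrors":
        if self.unit == "mm":
            return self
        return LandmarkErrors(self.radial_errors * spacing_mm, unit="mm")


@dataclass
class AgreementReport:
    """Agreement between reference and predicted angles (degrees)."""

    n: int
    mad: float  # mean of |prediction - reference|
    mad_sd: float  # sample sd of the absolute differences
    ad_fractions: dict[float, float]  # threshold -> fraction strictly below
    bias: float  # mean signed difference
    loa_low: float  # bias - 1.96 * sd(differences)
    loa_high: float  # bias + 1.96 * sd(differences)

    @property
    def ad_lt_1(self) -> float:
        return self.ad_fractions[1.0]

    @property
    def ad_lt_2(self) -> float:
        return self.ad_fractions[2.0]


@dataclass
class ContingencyTable:
    """An r x c table of non-negative counts with optional labels."""

    counts: np.ndarray
    row_labels: tuple[str, ...] | None = None
    col_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("contingency table must be 2-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.counts.sum() <= 0:
            raise ValueError("contingency table total must be positive")


def mre(errors: LandmarkErrors) -> float:
    """Mean radial error: arithmetic mean of the radial errors.

    Undefined (raises) for an empty error list.
    """
    if errors.n == 0:
        raise ValueError("MRE undefined for zero detected landmarks")
    return float(errors.radial_errors.mean())


def agreement(
    reference,
    prediction,
    thresholds=CLINICAL_AD_THRESHOLDS_DEG,
) -> AgreementReport:
    """MAD, AD rates and Bland-Altman limits for paired angle measurements.

    ``differences = prediction - reference``; AD fractions use strict
    inequality (|difference| < threshold); the limits of agreement use the
    sample standard deviation (n-1).  At least two pairs are required so
    the limits are defined.
    """
    reference = np.asarray(reference, dtype=float).reshape(-1)
    prediction = np.asarray(prediction, dtype=float).reshape(-1)
    if reference.shape != prediction.shape:
        raise ValueError(
            f"length mismatch: {reference.size} reference vs {prediction.size} predicted"
        )
    if reference.size < 2:
        raise ValueError("at least two pairs required for limits of agreement")

    diff = prediction - reference
    abs_diff = np.abs(diff)
    sd = float(diff.std(ddof=1))
    bias = float(diff.mean())
    return AgreementReport(
        n=reference.size,
        mad=float(abs_diff.mean()),
        mad_sd=float(abs_diff.std(ddof=1)),
        ad_fractions={float(t): float(np.mean(abs_diff < t)) for t in thresholds},
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
    )


def pearson_chi_square(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square statistic, degrees of freedom and upper-tail p.

    No continuity correction is applied.  Requires at least a 2x2 table
    with all row and column marginals positive.
    """
    counts = table.counts
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("degenerate table: a row or column marginal is zero")
    statistic, p, dof, _ = stats.chi2_contingency(counts, correction=False)
    return float(statistic), int(dof), float(p)


def uniform_prediction_mre(frame_shape: tuple[int, int], points) -> float:
    """Expected MRE of a predictor that picks a uniformly random pixel.

    Computed exactly as the mean Euclidean distance from each true landmark
    to every pixel centre of the H x W frame; serves as the uninformed
    baseline against which a trained detector is judged.
    """
    H, W = frame_shape
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    return float(
        np.mean([np.hypot(xx - x, yy - y).mean() for x, y in points])
    )
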