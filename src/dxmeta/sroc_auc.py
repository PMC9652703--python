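"""Summary ROC curves and AUC comparison.

Two summary curves are implemented:

* the classical linear-model SROC: regress D = logit(TPR) - logit(FPR)
  (= ln DOR) on S = logit(TPR) + logit(FPR), a proxy for the implicit
  positivity threshold, then back-transform the fitted line to ROC space;

* the hierarchical summary ROC implied by a bivariate fit: the curve through
  the summary point with slope (d logit TPR / d logit FPR) equal to the square
  root of the ratio of the between-study logit-variances, the standard
  conversion between the bivariate and HSROC parameterisations.

AUC is the trapezoidal integral of TPR over the full FPR range [0, 1]; the
standard error of the HSROC AUC comes from seeded parametric resampling of the
summary point, since no closed form exists.  Subgroup AUCs are compared with a
two-sided Z-test, z = (AUC1 - AUC2) / sqrt(SE1^2 + SE2^2).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from scipy.special import expit, logit

from .meta_pool import BivariateFit
from .study_table import ContingencyTable

logger = logging.getLogger(__name__)

#: grid resolution for trapezoidal AUC integration
GRID_POINTS = 2001
_EDGE = 1e-6


@dataclass(frozen=True)
class SROCCurve:
    kind: str                 # "moses" | "hsroc"
    intercept_a: float        # ln DOR on the symmetric (S=0) axis
    slope_b: float            # slope of D on S ("moses"); 0 by construction for "hsroc"
    auc: float
    se_auc: float
    grid: np.ndarray          # (n, 2) array of (FPR, TPR)

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError(f"AUC {self.auc} outside [0,1]")
        if self.se_auc < 0:
            raise ValueError("negative se_auc")

    def tpr_at(self, fpr: np.ndarray) -> np.ndarray:
        return np.interp(fpr, self.grid[:, 0], self.grid[:, 1])


@dataclass(frozen=True)
class AUCComparison:
    auc1: float
    auc2: float
    se1: float
    se2: float
    z: float
    p_value: float


def _integrate(fpr: np.ndarray, tpr: np.ndarray) -> float:
    return float(np.trapezoid(tpr, fpr))


def moses_sroc(
    tables: Sequence[ContingencyTable],
    weighting: Literal["inverse_variance", "unweighted"] = "inverse_variance",
) -> SROCCurve:
    """Linear-model summary ROC from per-study (D, S) points.

    Weighted least squares with weights 1/var(D) by default (var(D) is the
    ln-DOR variance, the sum of reciprocal cells).  The fitted line
    D = a + b S back-transforms to
    TPR = expit( a/(1-b) + (1+b)/(1-b) * logit(FPR) ); for |b| >= 1 the
    back-transformation is not monotone over all of [0,1] and the curve is
    integrated over the part of the domain where it is a valid ROC, with a
    warning.
    """
    k = len(tables)
    if k < 3:
        raise ValueError("summary ROC regression needs at least 3 studies")
    u = np.array([logit(t.sen) for t in tables])
    v = np.array([logit(t.fpr) for t in tables])
    D = u - v
    S = u + v
    if weighting == "inverse_variance":
        w = np.array([1.0 / (1 / t.tp + 1 / t.fp + 1 / t.fn + 1 / t.tn) for t in tables])
    else:
        w = np.ones(k)
    X = np.column_stack([np.ones(k), S])
    WX = X * w[:, None]
    a, b = np.linalg.solve(X.T @ WX, WX.T @ D)

    fpr = np.linspace(_EDGE, 1 - _EDGE, GRID_POINTS)
    if abs(b) >= 1:
        warnings.warn(
            f"threshold slope |b|={abs(b):.3f} >= 1: SROC undefined on part of "
            "the FPR domain; integrating the valid range",
            RuntimeWarning,
            stacklevel=2,
        )
        slope = (1 + b) / (1 - b)
        tpr = expit(a / (1 - b) + slope * logit(fpr))
        valid = np.diff(tpr, prepend=tpr[0] - 1e-12) >= 0
        fpr, tpr = fpr[valid], tpr[valid]
    else:
        slope = (1 + b) / (1 - b)
        tpr = expit(a / (1 - b) + slope * logit(fpr))
        fpr, tpr = _close_grid(fpr, tpr, slope, a / (1 - b))
    auc = _integrate(fpr, tpr)
    return SROCCurve(
        kind="moses",
        intercept_a=float(a),
        slope_b=float(b),
        auc=auc,
        se_auc=0.0,
        grid=np.column_stack([fpr, tpr]),
    )


def _hsroc_slope(sigma: np.ndarray) -> float:
    """Slope of logit TPR on logit FPR implied by the between-study covariance.

    Equal to exp(-beta) of the hierarchical model, where exp(2 beta) is the
    ratio of the logit-FPR to logit-TPR between-study variances.
    """
    if sigma[1, 1] <= 1e-10:
        warnings.warn(
            "zero between-study FPR variance; falling back to the symmetric "
            "(unit-slope) summary curve",
            RuntimeWarning,
            stacklevel=3,
        )
        return 1.0
    return float(math.sqrt(sigma[0, 0] / sigma[1, 1]))


def _close_grid(
    fpr: np.ndarray, tpr: np.ndarray, slope: float, level: float
) -> tuple[np.ndarray, np.ndarray]:
    """Append the exact (0, TPR(0)) and (1, TPR(1)) limits to the open grid."""
    lo, hi = (0.0, 1.0) if slope > 0 else (expit(level), expit(level))
    return np.r_[0.0, fpr, 1.0], np.r_[lo, tpr, hi]


def _hsroc_grid(mu: np.ndarray, slope: float) -> tuple[np.ndarray, np.ndarray]:
    fpr = np.linspace(_EDGE, 1 - _EDGE, GRID_POINTS)
    tpr = expit(mu[0] + slope * (logit(fpr) + mu[1]))
    return _close_grid(fpr, tpr, slope, mu[0] + slope * mu[1])


def hsroc_from_bivariate(
    fit: BivariateFit,
    draws: int = 2000,
    seed: int = 0,
) -> SROCCurve:
    """Summary ROC implied by a bivariate fit, with resampled SE(AUC).

    The curve passes through the summary point (1-SPE, SEN) with the slope
    implied by the between-study covariance; AUC integrates it over the full
    FPR range.  SE(AUC) is the standard deviation of the AUC over ``draws``
    resamples of the summary means from their asymptotic normal distribution
    (the between-study covariance, hence the slope, held fixed).
    """
    slope = _hsroc_slope(fit.sigma)
    fpr, tpr = _hsroc_grid(fit.mu, slope)
    auc = _integrate(fpr, tpr)
    rng = np.random.default_rng(seed)
    d = rng.multivariate_normal(fit.mu, fit.fixed_vcov, size=draws)
    aucs = np.empty(draws)
    fpr_in = fpr[1:-1]  # interior grid; endpoint limits are draw-independent
    lf = logit(fpr_in)
    for i in range(draws):
        g = _close_grid(fpr_in, expit(d[i, 0] + slope * (lf + d[i, 1])),
                        slope, d[i, 0] + slope * d[i, 1])
        aucs[i] = _integrate(*g)
    # ln DOR at S=0 for the reporting fields: D at the symmetric point
    intercept = float(fit.mu[0] + slope * fit.mu[1]) if slope else float(fit.mu[0])
    return SROCCurve(
        kind="hsroc",
        intercept_a=intercept,
        slope_b=0.0,
        auc=auc,
        se_auc=float(np.std(aucs)),
        grid=np.column_stack([fpr, tpr]),
    )


def compare_auc(auc1: float, se1: float, auc2: float, se2: float) -> AUCComparison:
    """Two-sided Z-test for a difference between two independent AUCs."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (auc1 - auc2) / math.hypot(se1, se2)
    p = 2.0 * stats.norm.sf(abs(z))
    return AUCComparison(auc1=auc1, auc2=auc2, se1=se1, se2=se2, z=float(z), p_value=float(p))


def plot_sroc(curve: SROCCurve, tables: Sequence[ContingencyTable] | None = None, ax=None):
    """ROC-space plot of a summary curve, study points sized by total n."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ax.plot(curve.grid[:, 0], curve.grid[:, 1], lw=2,
            label=f"{curve.kind.upper()} (AUC={curve.auc:.2f})")
    if tables:
        x = [t.fpr for t in tables]
        y = [t.sen for t in tables]
        s = [t.n_case + t.n_control for t in tables]
        smax = max(s)
        ax.scatter(x, y, s=[120 * v / smax + 10 for v in s],
                   facecolors="none", edgecolors="tab:blue")
    ax.plot([0, 1], [0, 1], ls=":", color="grey", lw=1)
    ax.set_xlabel("False positive rate (1 - specificity)")
    ax.set_ylabel("True positive rate (sensitivity)")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.legend(loc="lower right")
    return ax
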