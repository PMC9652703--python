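"""Publication bias, clinical utility, and influence analysis.

* Deeks' funnel-plot asymmetry test — the regression-based test designed for
  diagnostic accuracy data: ln DOR regressed on 1/sqrt(ESS) with weights ESS,
  where ESS = 4 n1 n0 / (n1 + n0) is the effective (balanced-design) sample
  size.  A slope significantly different from zero indicates small-study
  effects.

* Fagan updating — Bayes' rule on the odds scale: post-test odds = pre-test
  odds x likelihood ratio.

* Leave-one-out influence — the bivariate model refitted k times, each time
  omitting one study; a study is flagged when its omission moves the pooled
  sensitivity or specificity outside the baseline 95% CI.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .meta_pool import BivariateFit, fit_bivariate, summarize_fit
from .sroc_auc import hsroc_from_bivariate
from .study_table import ContingencyTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeeksResult:
    slope: float
    se: float
    p_value: float
    k: int


@dataclass(frozen=True)
class FaganResult:
    pretest: float
    posttest_positive: float
    posttest_negative: float


@dataclass(frozen=True)
class InfluenceRow:
    omitted: str
    sen: float
    spe: float
    dor: float
    auc: float
    flagged: bool
    error: str | None = None


@dataclass(frozen=True)
class InfluenceTable:
    baseline: InfluenceRow
    rows: tuple[InfluenceRow, ...]

    @property
    def flagged(self) -> tuple[InfluenceRow, ...]:
        return tuple(r for r in self.rows if r.flagged)


def deeks_test(tables: Sequence[ContingencyTable]) -> DeeksResult:
    """Funnel-plot asymmetry test for diagnostic odds ratios.

    Two-sided t-test (k-2 df) on the slope of the ESS-weighted regression of
    ln DOR on 1/sqrt(ESS).
    """
    k = len(tables)
    if k < 3:
        raise ValueError("Deeks' test needs at least 3 studies")
    if k < 10:
        warnings.warn(
            f"Deeks' test with k={k} < 10 studies has very low power",
            RuntimeWarning,
            stacklevel=2,
        )
    ln_dor = np.array([math.log(t.dor) for t in tables])
    n1 = np.array([t.n_case for t in tables])
    n0 = np.array([t.n_control for t in tables])
    ess = 4.0 * n1 * n0 / (n1 + n0)
    x = 1.0 / np.sqrt(ess)
    if np.ptp(x) == 0 or np.ptp(ln_dor) == 0:
        # identical sizes (or identical effects): no asymmetry estimable
        return DeeksResult(slope=0.0, se=0.0, p_value=1.0, k=k)
    X = np.column_stack([np.ones(k), x])
    XtW = X.T * ess
    cov = np.linalg.inv(XtW @ X)
    beta = cov @ (XtW @ ln_dor)
    resid = ln_dor - X @ beta
    scale = float(resid @ (ess * resid)) / (k - 2)
    se = math.sqrt(scale * cov[1, 1])
    if se == 0.0:  # all studies identical
        return DeeksResult(slope=float(beta[1]), se=0.0, p_value=1.0, k=k)
    t = beta[1] / se
    p = 2.0 * stats.t.sf(abs(t), k - 2)
    return DeeksResult(slope=float(beta[1]), se=se, p_value=float(p), k=k)


def fagan(pretest: float, plr: float, nlr: float) -> FaganResult:
    """Post-test probabilities after a positive / negative test result."""
    if not (0.0 < pretest < 1.0):
        raise ValueError("pretest probability must lie strictly in (0,1)")
    if plr <= 0 or nlr <= 0:
        raise ValueError("likelihood ratios must be positive")
    odds = pretest / (1.0 - pretest)
    pos = odds * plr
    neg = odds * nlr
    return FaganResult(
        pretest=pretest,
        posttest_positive=pos / (1.0 + pos),
        posttest_negative=neg / (1.0 + neg),
    )


def leave_one_out(
    tables: Sequence[ContingencyTable],
    seed: int = 0,
) -> InfluenceTable:
    """Leave-one-out sweep of the bivariate fit.

    Each refit is warm-started at the full-data solution.  Per-study fit
    errors are recorded in the row and do not abort the sweep.
    """
    if len(tables) < 3:
        raise ValueError("leave-one-out needs at least 3 studies")
    base_fit = fit_bivariate(tables)
    base = _influence_row("(none)", base_fit, seed=seed)
    ests = {e.metric: e for e in summarize_fit(base_fit)}
    sen_lo, sen_hi = ests["sen"].ci_low, ests["sen"].ci_high
    spe_lo, spe_hi = ests["spe"].ci_low, ests["spe"].ci_high
    L = np.linalg.cholesky(base_fit.sigma)
    warm = np.array([base_fit.mu[0], base_fit.mu[1], L[0, 0], L[1, 0], L[1, 1]])
    rows: list[InfluenceRow] = []
    for i, t in enumerate(tables):
        rest = list(tables[:i]) + list(tables[i + 1 :])
        label = t.study_id or f"study_{i}"
        try:
            fit = fit_bivariate(rest, start=warm)
            flagged = not (sen_lo <= fit.sen <= sen_hi and spe_lo <= fit.spe <= spe_hi)
            row = _influence_row(label, fit, seed=seed + 1 + i, flagged=flagged)
        except Exception as exc:  # propagate per-row, keep sweeping
            logger.warning("leave-one-out refit failed for %s: %s", label, exc)
            row = InfluenceRow(label, math.nan, math.nan, math.nan, math.nan,
                               flagged=False, error=str(exc))
        rows.append(row)
    return InfluenceTable(baseline=base, rows=tuple(rows))


def _influence_row(
    label: str, fit: BivariateFit, seed: int, flagged: bool = False
) -> InfluenceRow:
    ests = {e.metric: e for e in summarize_fit(fit)}
    auc = hsroc_from_bivariate(fit, draws=200, seed=seed).auc
    return InfluenceRow(
        omitted=label,
        sen=ests["sen"].point,
        spe=ests["spe"].point,
        dor=ests["dor"].point,
        auc=auc,
        flagged=flagged,
    )


def plot_deeks_funnel(tables: Sequence[ContingencyTable], result: DeeksResult, ax=None):
    """Funnel plot: 1/sqrt(ESS) against ln DOR with the fitted regression line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    ln_dor = np.array([math.log(t.dor) for t in tables])
    n1 = np.array([t.n_case for t in tables])
    n0 = np.array([t.n_control for t in tables])
    x = 1.0 / np.sqrt(4.0 * n1 * n0 / (n1 + n0))
    ax.scatter(ln_dor, x, facecolors="none", edgecolors="tab:blue")
    ax.invert_yaxis()
    ax.set_xlabel("ln DOR")
    ax.set_ylabel(r"$1/\sqrt{\mathrm{ESS}}$")
    ax.set_title(f"Deeks' asymmetry test: p = {result.p_value:.2f}")
    return ax
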