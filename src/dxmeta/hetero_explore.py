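"""Heterogeneity exploration: threshold effect, subgroups, meta-regression.

A threshold effect — studies trading sensitivity against specificity because
they use different positivity cut-offs — shows up as a positive Spearman
correlation between logit TPR and logit FPR across studies.  Non-threshold
heterogeneity is explored by stratified re-analysis (subgroups) and by a
linear-model meta-regression of ln DOR on the threshold proxy S plus study
covariates, reported as relative diagnostic odds ratios (RDOR = exp(coeff)).

Covariate coding for the meta-regression is ordinal: reference category 1,
index category 2, and 0 where the covariate has no value for that row
(gastric-juice rows for sample type; intronic/bidirectional/unknown rows for
genomic location).  The missing rows therefore stay in the regression as a
distinct level while the contrast of interest remains one unit.  Subgroup
analyses instead *exclude* the out-of-contrast rows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import logit

from .meta_pool import (
    BivariateFit,
    HeterogeneityResult,
    PooledEstimate,
    fit_bivariate,
    pool_dsl,
    summarize_fit,
)
from .sroc_auc import AUCComparison, SROCCurve, compare_auc, hsroc_from_bivariate
from .study_table import (
    COVARIATE_NAMES,
    ContingencyTable,
    StudyRecord,
    metareg_design,
    reconstruct_all,
)

logger = logging.getLogger(__name__)

#: covariate p-value at or above which backward elimination drops a term
ELIMINATION_THRESHOLD = 0.05

Grouping = Literal["location", "sample_type", "sample_size", "quality"]

#: grouping -> ordered (label, predicate) pairs; first label is the index group
GROUP_DEFS: Mapping[str, tuple[tuple[str, object], ...]] = {
    "location": (
        ("intergenic", lambda r: r.location == "intergenic"),
        ("antisense", lambda r: r.location == "antisense"),
    ),
    "sample_type": (
        ("circulating", lambda r: r.sample_type == "circulating"),
        ("tissue", lambda r: r.sample_type == "tissue"),
    ),
    "sample_size": (
        (">200", lambda r: r.total > 200),
        ("<=200", lambda r: r.total <= 200),
    ),
    "quality": (
        ("NOS>=7", lambda r: r.nos >= 7),
        ("NOS<7", lambda r: r.nos < 7),
    ),
}


@dataclass(frozen=True)
class ThresholdTest:
    rho: float
    p_value: float
    k: int

    def __post_init__(self) -> None:
        if not (-1.0 <= self.rho <= 1.0):
            raise ValueError(f"rho {self.rho} outside [-1,1]")


@dataclass(frozen=True)
class MetaRegressionTerm:
    name: str
    coeff: float
    se: float
    p_value: float
    rdor: float | None = None          # covariate terms only
    rdor_ci_low: float | None = None
    rdor_ci_high: float | None = None


@dataclass(frozen=True)
class MetaRegressionResult:
    terms: tuple[MetaRegressionTerm, ...]
    tau2: float
    k: int

    def term(self, name: str) -> MetaRegressionTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def covariate_terms(self) -> tuple[MetaRegressionTerm, ...]:
        return tuple(t for t in self.terms if t.name not in ("intercept", "S"))


@dataclass(frozen=True)
class SubgroupResult:
    label: str
    k: int
    estimates: tuple[PooledEstimate, ...]
    heterogeneity: tuple[HeterogeneityResult, ...]
    fit: BivariateFit
    sroc: SROCCurve

    def estimate(self, metric: str) -> PooledEstimate:
        for e in self.estimates:
            if e.metric == metric:
                return e
        raise KeyError(metric)


@dataclass(frozen=True)
class SubgroupReport:
    grouping: str
    groups: tuple[SubgroupResult, ...]
    comparison: AUCComparison
    n_excluded: int


# ---------------------------------------------------------------------------


def threshold_spearman(tables: Sequence[ContingencyTable]) -> ThresholdTest:
    """Spearman rank correlation of logit TPR with logit FPR across studies.

    Average ranks for ties; two-sided p from the t approximation with k-2 df.
    A clearly positive correlation indicates accuracy differences driven by
    varying positivity thresholds rather than genuine between-study effects.
    """
    k = len(tables)
    if k < 3:
        raise ValueError("threshold test needs at least 3 studies")
    u = np.array([logit(t.sen) for t in tables])
    v = np.array([logit(t.fpr) for t in tables])
    if np.ptp(u) == 0 or np.ptp(v) == 0:
        raise ValueError("constant TPR or FPR: rank correlation undefined")
    rho, p = stats.spearmanr(u, v)
    return ThresholdTest(rho=float(rho), p_value=float(p), k=k)


# ---------------------------------------------------------------------------


def subgroup_analysis(
    records: Sequence[StudyRecord],
    tables: Sequence[ContingencyTable],
    grouping: Grouping,
    seed: int = 0,
    draws: int = 2000,
) -> SubgroupReport:
    """Stratified pooling: full bivariate + SROC pipeline per group.

    Rows outside the binary contrast (gastric juice for sample type;
    intronic, bidirectional and unknown locations) are excluded and counted in
    ``n_excluded``.  The two group AUCs are compared with the Z-test using
    resampled standard errors; the difference is taken index-group minus
    reference-group (first minus second in the report order).
    """
    if len(records) != len(tables):
        raise ValueError("records and tables must align")
    if grouping not in GROUP_DEFS:
        raise ValueError(f"unknown grouping {grouping!r}")
    groups: list[SubgroupResult] = []
    assigned = 0
    for gi, (label, pred) in enumerate(GROUP_DEFS[grouping]):
        idx = [i for i, r in enumerate(records) if pred(r)]
        assigned += len(idx)
        if len(idx) < 3:
            raise ValueError(f"grouping {grouping!r}: group {label!r} has k={len(idx)} < 3")
        sub_tabs = [tables[i] for i in idx]
        fit = fit_bivariate(sub_tabs)
        sroc = hsroc_from_bivariate(fit, draws=draws, seed=seed + gi)
        ests = tuple(summarize_fit(fit))
        hets = tuple(pool_dsl(sub_tabs, m)[1] for m in ("sen", "spe", "plr", "nlr", "dor"))
        groups.append(
            SubgroupResult(
                label=label, k=len(idx), estimates=ests,
                heterogeneity=hets, fit=fit, sroc=sroc,
            )
        )
    n_excluded = len(records) - assigned
    if n_excluded:
        logger.info(
            "grouping %s: %d rows outside the %s contrast excluded",
            grouping, n_excluded, "/".join(g.label for g in groups),
        )
    g1, g2 = groups
    comparison = compare_auc(g1.sroc.auc, g1.sroc.se_auc, g2.sroc.auc, g2.sroc.se_auc)
    return SubgroupReport(
        grouping=grouping,
        groups=tuple(groups),
        comparison=comparison,
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------


def _reml_tau2(y: np.ndarray, X: np.ndarray, v: np.ndarray) -> float:
    """REML between-study variance for the weighted linear model."""

    def nll(log_t2: float) -> float:
        t2 = math.exp(log_t2)
        w = 1.0 / (v + t2)
        XtW = X.T * w
        XtWX = XtW @ X
        beta = np.linalg.solve(XtWX, XtW @ y)
        e = y - X @ beta
        return 0.5 * (
            float(np.sum(np.log(v + t2)))
            + float(np.linalg.slogdet(XtWX)[1])
            + float(e @ (w * e))
        )

    res = optimize.minimize_scalar(
        nll, bounds=(-12.0, 5.0), method="bounded", options=dict(xatol=1e-12)
    )
    t2 = float(math.exp(res.x))
    return 0.0 if t2 < 1e-8 else t2


def _mom_tau2(y: np.ndarray, X: np.ndarray, v: np.ndarray) -> float:
    """Method-of-moments tau^2 (generalised DerSimonian-Laird) for the model."""
    w0 = 1.0 / v
    XtW = X.T * w0
    H = np.linalg.inv(XtW @ X)
    beta = H @ (XtW @ y)
    e = y - X @ beta
    q = float(e @ (w0 * e))
    p = X.shape[1]
    trace = float(np.trace(H @ ((X.T * w0**2) @ X)))
    c = float(w0.sum()) - trace
    if c <= 0:
        return 0.0
    return max(0.0, (q - (len(y) - p)) / c)


def moses_metaregression(
    tables: Sequence[ContingencyTable],
    covariates: Mapping[str, Sequence[float]],
    include: Sequence[str],
    tau2_method: Literal["reml", "mom"] = "reml",
    weighting: Literal["inverse_variance", "sample_size"] = "inverse_variance",
) -> MetaRegressionResult:
    """Random-effects meta-regression of ln DOR on S and study covariates.

    Weighted least squares with weights 1/(var_i + tau^2), var_i the ln-DOR
    variance (sum of reciprocal 2x2 cells) and tau^2 estimated by REML
    (default) or method of moments.  Standard errors from the weighted
    information matrix; two-sided t-tests with k - p degrees of freedom;
    RDOR = exp(coeff) with 95% t-based CIs for covariate terms.
    """
    k = len(tables)
    if not include:
        raise ValueError("no covariates requested")
    u = np.array([logit(t.sen) for t in tables])
    fv = np.array([logit(t.fpr) for t in tables])
    D = u - fv
    S = u + fv
    v = np.array([1 / t.tp + 1 / t.fp + 1 / t.fn + 1 / t.tn for t in tables])
    cols = [np.ones(k), S]
    names = ["intercept", "S"]
    for name in include:
        if name not in covariates:
            raise KeyError(f"covariate {name!r} not supplied")
        x = np.asarray(covariates[name], float)
        if x.shape != (k,):
            raise ValueError(f"covariate {name!r} has wrong length")
        cols.append(x)
        names.append(name)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        degenerate = [n for n, c in zip(names[2:], cols[2:]) if np.ptp(c) == 0]
        raise ValueError(
            "rank-deficient design"
            + (f": constant covariate(s) {degenerate}" if degenerate else "")
        )
    p = X.shape[1]
    if k <= p:
        raise ValueError(f"k={k} too small for {p} coefficients")

    if weighting == "sample_size":
        n_tot = np.array([t.n_case + t.n_control for t in tables])
        w = n_tot / n_tot.mean()
        tau2 = 0.0
        XtW = X.T * w
        cov = np.linalg.inv(XtW @ X)
        beta = cov @ (XtW @ D)
        e = D - X @ beta
        cov = cov * float(e @ (w * e)) / (k - p)  # scaled, as in classical WLS
    else:
        tau2 = (_reml_tau2 if tau2_method == "reml" else _mom_tau2)(D, X, v)
        w = 1.0 / (v + tau2)
        XtW = X.T * w
        cov = np.linalg.inv(XtW @ X)
        beta = cov @ (XtW @ D)
    se = np.sqrt(np.diag(cov))
    tval = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tval), k - p)
    tcrit = float(stats.t.ppf(0.975, k - p))
    terms = []
    for j, name in enumerate(names):
        if name in ("intercept", "S"):
            terms.append(
                MetaRegressionTerm(name, float(beta[j]), float(se[j]), float(pvals[j]))
            )
        else:
            terms.append(
                MetaRegressionTerm(
                    name,
                    float(beta[j]),
                    float(se[j]),
                    float(pvals[j]),
                    rdor=float(math.exp(beta[j])),
                    rdor_ci_low=float(math.exp(beta[j] - tcrit * se[j])),
                    rdor_ci_high=float(math.exp(beta[j] + tcrit * se[j])),
                )
            )
    return MetaRegressionResult(terms=tuple(terms), tau2=float(tau2), k=k)


def backward_eliminate(
    tables: Sequence[ContingencyTable],
    covariates: Mapping[str, Sequence[float]],
    start: Sequence[str] | None = None,
    threshold: float = ELIMINATION_THRESHOLD,
    tau2_method: Literal["reml", "mom"] = "reml",
) -> list[MetaRegressionResult]:
    """Backward covariate elimination on the meta-regression.

    Starting from ``start`` (default: all four covariates), repeatedly refits
    and drops the covariate with the largest p-value at or above ``threshold``
    until none qualifies; the full trajectory is returned.  When more than one
    covariate survives, the single-covariate model for each survivor is
    appended, mirroring the conventional final report.
    """
    current = list(start if start is not None else COVARIATE_NAMES)
    if not current:
        raise ValueError("empty starting covariate set")
    trajectory = [
        moses_metaregression(tables, covariates, current, tau2_method=tau2_method)
    ]
    while len(current) > 1:
        worst = max(trajectory[-1].covariate_terms, key=lambda t: t.p_value)
        if worst.p_value < threshold:
            break
        current.remove(worst.name)
        logger.info("eliminated %r (p=%.4f)", worst.name, worst.p_value)
        trajectory.append(
            moses_metaregression(tables, covariates, current, tau2_method=tau2_method)
        )
    if len(current) > 1:
        for name in current:
            trajectory.append(
                moses_metaregression(tables, covariates, [name], tau2_method=tau2_method)
            )
    return trajectory


def default_metareg_inputs(
    records: Sequence[StudyRecord],
) -> tuple[list[ContingencyTable], dict[str, list[float]]]:
    """Convenience: tables + ordinal covariate design from raw records."""
    return reconstruct_all(records), metareg_design(records)
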