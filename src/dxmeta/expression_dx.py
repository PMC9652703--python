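"""Expression-based diagnostic modelling.

The validation arm of the pipeline works on a genes x samples expression
matrix with case/control labels (and optional tumour-stage labels): TPM
normalisation, per-gene Mann-Whitney differential expression with
Benjamini-Hochberg FDR, single-marker empirical ROC with Youden-optimal
cut-offs, a multi-gene logistic combination model, and stage-stratified AUC
comparison of the combined score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from statsmodels.stats.multitest import multipletests

from .sroc_auc import AUCComparison, compare_auc

logger = logging.getLogger(__name__)

#: pseudo-expression added to group means before the log2 fold change
LOG_FC_EPS = 1.0
#: FDR threshold for the up/down direction call
DIRECTION_FDR = 0.05

STAGES = ("I", "II", "III", "IV")


class ExpressionError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Genes x samples non-negative expression with per-sample labels.

    ``values`` is a genes x samples DataFrame (index = gene identifiers,
    columns = sample identifiers); ``labels`` maps each sample to "case" or
    "control"; ``stage`` optionally maps case samples to tumour stage I-IV.
    """

    values: pd.DataFrame
    labels: pd.Series
    stage: pd.Series | None = None

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values)
        self.labels = pd.Series(self.labels)
        if not self.labels.index.equals(pd.Index(self.values.columns)):
            self.labels = self.labels.reindex(self.values.columns)
        if self.labels.isna().any():
            raise ExpressionError("labels must cover every sample")
        bad = set(self.labels.unique()) - {"case", "control"}
        if bad:
            raise ExpressionError(f"unknown labels {sorted(bad)}")
        if (self.values.to_numpy() < 0).any():
            raise ExpressionError("negative expression values")
        if (self.labels == "case").sum() == 0 or (self.labels == "control").sum() == 0:
            raise ExpressionError("need at least one case and one control")
        if self.stage is not None:
            self.stage = pd.Series(self.stage).reindex(self.values.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def case_mask(self) -> np.ndarray:
        return (self.labels == "case").to_numpy()


@dataclass(frozen=True)
class DiffExprRow:
    gene: str
    log_fc: float
    p_value: float
    fdr: float
    direction: str  # "up" | "down" | "no_difference"


@dataclass(frozen=True)
class ROCResult:
    auc: float
    se: float
    ci_low: float
    ci_high: float
    cutoff: float
    sen_at_cutoff: float
    spe_at_cutoff: float

    @property
    def youden(self) -> float:
        return self.sen_at_cutoff + self.spe_at_cutoff - 1.0


@dataclass(frozen=True)
class LogisticModel:
    intercept: float
    coefficients: Mapping[str, float]
    converged: bool = True
    separated: bool = False

    def score(self, expr: ExpressionMatrix) -> pd.Series:
        """P(case) for each sample under the fitted model."""
        eta = np.full(len(expr.samples), self.intercept)
        for gene, coef in self.coefficients.items():
            eta = eta + coef * expr.values.loc[gene].to_numpy(float)
        return pd.Series(expit(eta), index=expr.values.columns)

    def equation(self) -> str:
        parts = [f"{self.intercept:+.3f}"]
        parts += [f"{c:+.3f} x {g}" for g, c in self.coefficients.items()]
        return "logit(P) = " + " ".join(parts).lstrip("+")


# ---------------------------------------------------------------------------


def counts_to_tpm(
    counts: ExpressionMatrix, lengths: Mapping[str, float]
) -> ExpressionMatrix:
    """Convert raw read counts to transcripts per million.

    TPM_gs = (count_gs / length_g) / sum_g(count_gs / length_g) x 1e6, so each
    sample column sums to one million.
    """
    missing = [g for g in counts.genes if g not in lengths]
    if missing:
        raise ExpressionError(f"missing gene lengths: {missing[:5]}")
    length = np.array([float(lengths[g]) for g in counts.genes])
    if np.any(length <= 0):
        raise ExpressionError("gene lengths must be positive")
    rate = counts.values.to_numpy(float) / length[:, None]
    denom = rate.sum(axis=0)
    empty = denom <= 0
    if empty.any():
        bad = [s for s, e in zip(counts.samples, empty) if e]
        raise ExpressionError(f"zero library after length scaling: {bad}")
    tpm = rate / denom * 1e6
    return ExpressionMatrix(
        values=pd.DataFrame(tpm, index=counts.values.index, columns=counts.values.columns),
        labels=counts.labels.copy(),
        stage=None if counts.stage is None else counts.stage.copy(),
    )


def diff_expr(expr: ExpressionMatrix) -> list[DiffExprRow]:
    """Per-gene two-group Mann-Whitney U tests with BH-FDR correction.

    log_fc = log2((mean_case + eps)/(mean_control + eps)); the two-sided
    p-value is exact for small untied samples and otherwise uses the
    tie-corrected normal approximation; genes constant across all samples get
    p = 1.  Direction is called up/down at FDR < 0.05 by the sign of log_fc,
    else "no_difference".
    """
    case = expr.case_mask()
    if case.sum() < 2 or (~case).sum() < 2:
        raise ExpressionError("need >= 2 samples per group")
    X = expr.values.to_numpy(float)
    pvals = np.empty(X.shape[0])
    lfc = np.empty(X.shape[0])
    for i, row in enumerate(X):
        a, b = row[case], row[~case]
        lfc[i] = math.log2((a.mean() + LOG_FC_EPS) / (b.mean() + LOG_FC_EPS))
        if np.ptp(row) == 0:
            pvals[i] = 1.0
            logger.debug("gene %s constant across samples; p set to 1", expr.genes[i])
            continue
        pvals[i] = stats.mannwhitneyu(a, b, alternative="two-sided",
                                      method="auto").pvalue
    fdr = multipletests(pvals, method="fdr_bh")[1]
    rows = []
    for gene, l, p, q in zip(expr.genes, lfc, pvals, fdr):
        if q < DIRECTION_FDR and l > 0:
            direction = "up"
        elif q < DIRECTION_FDR and l < 0:
            direction = "down"
        else:
            direction = "no_difference"
        rows.append(DiffExprRow(gene=gene, log_fc=float(l), p_value=float(p),
                                fdr=float(q), direction=direction))
    return rows


def compare_directions(
    rows: Sequence[DiffExprRow], literature: Mapping[str, str]
) -> pd.DataFrame:
    """Concordance report of computed directions against literature calls."""
    rec = []
    for r in rows:
        lit = literature.get(r.gene)
        rec.append(
            {
                "gene": r.gene,
                "literature": lit,
                "computed": r.direction,
                "log_fc": r.log_fc,
                "fdr": r.fdr,
                "concordant": (lit == r.direction) if lit else None,
            }
        )
    return pd.DataFrame(rec)


# ---------------------------------------------------------------------------


def roc_curve(scores: Sequence[float], labels: Sequence[str]) -> ROCResult:
    """Empirical ROC of a continuous score (higher score = more case-like).

    AUC is the Mann-Whitney probability (ties counted one half); its standard
    error and 95% CI use the Hanley-McNeil formula.  The reported cut-off
    maximises Youden's index over all observed thresholds, ties broken toward
    higher specificity; a score >= cut-off is called positive.
    """
    s = np.asarray(scores, float)
    y = np.asarray([1 if l == "case" else 0 for l in labels])
    n1 = int(y.sum())
    n0 = int(len(y) - n1)
    if n1 == 0 or n0 == 0:
        raise ExpressionError("both classes must be present")
    # AUC via rank statistic (ties -> midranks give the half-count convention)
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    se = math.sqrt(max(var, 0.0))
    # Youden scan over observed thresholds
    order = np.argsort(-s, kind="mergesort")  # descending scores
    ys = y[order]
    ss = s[order]
    tps = np.cumsum(ys)
    fps = np.cumsum(1 - ys)
    # candidate cut-offs: last index of each distinct score value
    last = np.r_[np.nonzero(np.diff(ss))[0], len(ss) - 1]
    sen = tps[last] / n1
    spe = 1.0 - fps[last] / n0
    youden = sen + spe - 1.0
    best = np.flatnonzero(youden == youden.max())
    pick = best[np.argmax(spe[best])]  # ties -> higher specificity
    return ROCResult(
        auc=float(auc),
        se=se,
        ci_low=float(max(0.0, auc - 1.959963984540054 * se)),
        ci_high=float(min(1.0, auc + 1.959963984540054 * se)),
        cutoff=float(ss[last][pick]),
        sen_at_cutoff=float(sen[pick]),
        spe_at_cutoff=float(spe[pick]),
    )


def fit_logistic_combo(
    expr: ExpressionMatrix, genes: Sequence[str]
) -> LogisticModel:
    """Maximum-likelihood logistic regression of case status on gene expression.

    All requested genes enter simultaneously (no selection), fitted by
    iteratively reweighted least squares; perfect separation is flagged and
    the (diverging) coefficients are still reported with a warning.
    """
    import statsmodels.api as sm

    missing = [g for g in genes if g not in expr.values.index]
    if missing:
        raise ExpressionError(f"genes not in matrix: {missing}")
    y = expr.case_mask().astype(float)
    if y.sum() < 10 or (1 - y).sum() < 10:
        logger.warning("fewer than 10 samples in a class; estimates may be unstable")
    X = sm.add_constant(expr.values.loc[list(genes)].T.to_numpy(float))
    separated = False
    with np.errstate(all="ignore"):
        try:
            res = sm.Logit(y, X).fit(disp=False, gtol=1e-8, maxiter=200)
            params = res.params
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:  # PerfectSeparationError and kin
            separated = True
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
            params = res.params
            converged = False
    # heuristics for quasi-separation that converged numerically
    if not separated and np.max(np.abs(params[1:])) > 50:
        separated = True
    if separated:
        logger.warning("perfect or quasi-perfect separation detected")
    return LogisticModel(
        intercept=float(params[0]),
        coefficients={g: float(c) for g, c in zip(genes, params[1:])},
        converged=converged,
        separated=separated,
    )


def stage_stratified_auc(
    expr: ExpressionMatrix,
    model: LogisticModel,
    min_cases: int = 5,
) -> list[tuple[str, ROCResult, AUCComparison | None]]:
    """Per-stage ROC of the combined score, each stage compared to stage I.

    Controls are shared across stages; each stage's cases are scored against
    the full control pool, plus a pooled late-stage (II+III+IV) row.  AUC
    differences use the independent-samples Z-test with Hanley-McNeil SEs
    (the shared-control correlation is ignored, as in the conventional
    report).
    """
    if expr.stage is None:
        raise ExpressionError("stage labels required")
    scores = model.score(expr)
    case = expr.case_mask()
    ctrl_scores = scores[~case]
    stage = expr.stage
    out: list[tuple[str, ROCResult, AUCComparison | None]] = []
    stage_groups = [(s, [s]) for s in STAGES] + [("II+III+IV", ["II", "III", "IV"])]
    ref: ROCResult | None = None
    for label, members in stage_groups:
        mask = case & stage.isin(members).to_numpy()
        if mask.sum() < min_cases:
            raise ExpressionError(f"stage {label}: fewer than {min_cases} cases")
        s = np.r_[scores[mask].to_numpy(), ctrl_scores.to_numpy()]
        lab = ["case"] * int(mask.sum()) + ["control"] * len(ctrl_scores)
        roc = roc_curve(s, lab)
        if label == "I":
            ref = roc
            out.append((label, roc, None))
        else:
            assert ref is not None
            if ref.auc == roc.auc:
                comp = AUCComparison(ref.auc, roc.auc, ref.se, roc.se, 0.0, 1.0)
            elif ref.se == 0 or roc.se == 0:
                logger.warning(
                    "stage %s: zero AUC standard error (perfect separation); "
                    "Z-test undefined", label,
                )
                comp = None
            else:
                comp = compare_auc(ref.auc, ref.se, roc.auc, roc.se)
            out.append((label, roc, comp))
    return out


# ---------------------------------------------------------------------------


def read_expression(
    matrix_path, annotation_path
) -> ExpressionMatrix:
    """Read a genes x samples CSV/TSV matrix plus a sample annotation sidecar.

    The annotation file needs columns ``sample`` and ``label`` (case/control)
    and optionally ``stage``.
    """
    sep = "\t" if str(matrix_path).endswith((".tsv", ".txt")) else ","
    values = pd.read_csv(matrix_path, sep=sep, index_col=0)
    ann_sep = "\t" if str(annotation_path).endswith((".tsv", ".txt")) else ","
    ann = pd.read_csv(annotation_path, sep=ann_sep).set_index("sample")
    labels = ann["label"].reindex(values.columns)
    stage = ann["stage"].reindex(values.columns) if "stage" in ann.columns else None
    return ExpressionMatrix(values=values, labels=labels, stage=stage)
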