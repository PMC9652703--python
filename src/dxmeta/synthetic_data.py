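"""Synthetic data generators for both pipeline inputs.

Two generators make every stage testable without external downloads:

* :func:`simulate_meta_dataset` draws a study-level diagnostic-accuracy
  dataset from a known bivariate logit model — per study, (logit sen, logit
  spe) from a bivariate normal (optionally shifted along the ln-DOR axis by
  covariate effects, or correlated to mimic a threshold effect), then integer
  2x2 cells from binomial sampling so that within-study variation matches the
  pooling model's assumption.

* :func:`simulate_expression` builds a two-group lognormal expression matrix
  with planted per-gene log2 fold changes and optional per-stage multipliers.

Both are fully reproducible from their seed and emit the same containers the
analysis modules consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .expression_dx import ExpressionMatrix
from .study_table import ContingencyTable, StudyRecord

#: covariate prevalence used when a covariate effect is requested
_COVARIATE_PREVALENCE = 0.5


@dataclass(frozen=True)
class MetaSimConfig:
    """Configuration of the study-level generator.

    ``mu`` is (mean logit sensitivity, mean logit specificity); ``sigma`` the
    between-study covariance.  ``covariate_effects`` maps covariate name to a
    ln-DOR shift: studies with covariate value 1 get half the shift added to
    logit sen and half to logit spe (so the full shift lands on ln DOR).
    ``threshold_rho`` superimposes a negative sen/spe correlation (positive
    logit TPR / logit FPR correlation), emulating threshold-driven
    heterogeneity.
    """

    k: int
    mu: tuple[float, float] = (1.0, 1.0)
    sigma: Sequence[Sequence[float]] = ((0.3, 0.0), (0.0, 0.3))
    size_range: tuple[int, int] = (20, 200)
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    threshold_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be positive")
        if self.size_range[0] < 10 or self.size_range[1] < self.size_range[0]:
            raise ValueError("size_range must satisfy 10 <= min <= max")
        if not (-1.0 <= self.threshold_rho <= 1.0):
            raise ValueError("threshold_rho outside [-1,1]")
        s = np.asarray(self.sigma, float)
        if s.shape != (2, 2) or abs(s[0, 1] - s[1, 0]) > 1e-12:
            raise ValueError("sigma must be symmetric 2x2")
        if np.any(np.linalg.eigvalsh(s) < -1e-10):
            raise ValueError("sigma must be positive semi-definite")


@dataclass(frozen=True)
class ExprSimConfig:
    """Configuration of the expression generator.

    Control expression is lognormal around a per-gene baseline with
    log-scale spread ``noise``; cases are multiplied by 2**planted[gene]
    and, when ``stage_effect`` is given, by the stage multiplier of the
    sample's (uniformly assigned) stage.
    """

    n_genes: int = 20
    n_case: int = 50
    n_control: int = 50
    planted: Mapping[str, float] = field(default_factory=dict)
    noise: float = 0.5
    stage_effect: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need >= 2 samples per group")
        if self.noise <= 0:
            raise ValueError("noise must be positive")


@dataclass(frozen=True)
class MetaSimTruth:
    """Ground truth behind a simulated study-level dataset."""

    mu: np.ndarray
    sigma: np.ndarray
    logit_sen: np.ndarray
    logit_spe: np.ndarray
    covariates: dict[str, np.ndarray]


def simulate_meta_dataset(
    config: MetaSimConfig,
) -> tuple[list[StudyRecord], MetaSimTruth]:
    """Draw study records (and their ground truth) from the bivariate model."""
    rng = np.random.default_rng(config.seed)
    mu = np.asarray(config.mu, float)
    sigma = np.asarray(config.sigma, float)

    # threshold effect: a shared latent positivity-threshold component that
    # moves logit sen and logit fpr together (sen up, spe down).  Its variance
    # is r/(1-r) times the base between-study variance, so the induced
    # logit TPR / logit FPR correlation is r before binomial noise.
    if config.threshold_rho:
        r = min(abs(config.threshold_rho), 0.99)
        s_avg = math.sqrt(max(sigma[0, 0] * sigma[1, 1], 1e-12))
        extra = r / (1.0 - r) * s_avg
        thr = rng.normal(0.0, math.sqrt(extra), size=config.k)
    else:
        thr = np.zeros(config.k)

    eff = rng.multivariate_normal(mu, sigma, size=config.k)
    covariates: dict[str, np.ndarray] = {}
    for name, shift in config.covariate_effects.items():
        x = (rng.random(config.k) < _COVARIATE_PREVALENCE).astype(int)
        covariates[name] = x
        eff[:, 0] += 0.5 * shift * x
        eff[:, 1] += 0.5 * shift * x
    ls = eff[:, 0] + np.sign(config.threshold_rho) * thr
    lp = eff[:, 1] - np.sign(config.threshold_rho) * thr

    n1 = rng.integers(config.size_range[0], config.size_range[1] + 1, size=config.k)
    n0 = rng.integers(config.size_range[0], config.size_range[1] + 1, size=config.k)
    tp = rng.binomial(n1, expit(ls))
    tn = rng.binomial(n0, expit(lp))

    records = []
    for i in range(config.k):
        records.append(
            StudyRecord(
                study_id=f"sim_{i:04d}",
                author=f"sim_{i:04d}",
                year=2020,
                ethnicity="simulated",
                gene=f"G{i:04d}",
                regulation="up",
                location="intergenic" if covariates.get("location", np.zeros(config.k))[i] else "antisense",
                sample_type="circulating" if covariates.get("sample_type", np.zeros(config.k))[i] else "tissue",
                specimen="synthetic",
                sen=float(tp[i] / n1[i]),
                spe=float(tn[i] / n0[i]),
                n_case=int(n1[i]),
                n_control=int(n0[i]),
                nos=7,
            )
        )
    truth = MetaSimTruth(
        mu=mu, sigma=sigma, logit_sen=ls, logit_spe=lp, covariates=covariates
    )
    return records, truth


def simulate_tables(config: MetaSimConfig) -> tuple[list[ContingencyTable], MetaSimTruth]:
    """Like :func:`simulate_meta_dataset` but returning 2x2 tables directly.

    The realized integer cells are used as-is (no re-rounding through the
    reported proportions); zero cells receive the 0.5 continuity correction.
    """
    records, truth = simulate_meta_dataset(config)
    tables = []
    for r in records:
        tp = round(r.sen * r.n_case)
        tn = round(r.spe * r.n_control)
        fn, fp = r.n_case - tp, r.n_control - tn
        corrected = min(tp, fn, tn, fp) == 0
        off = 0.5 if corrected else 0.0
        tables.append(
            ContingencyTable(tp + off, fp + off, fn + off, tn + off,
                             corrected=corrected, study_id=r.study_id)
        )
    return tables, truth


def paper_like_meta_config(seed: int = 0) -> MetaSimConfig:
    """A preset mirroring the packaged study table's marginal structure:
    54 studies, arm sizes 20-280, moderate between-study heterogeneity, and a
    circulating-vs-tissue effect on ln DOR."""
    return MetaSimConfig(
        k=54,
        mu=(0.89, 1.13),
        sigma=((0.32, -0.14), (-0.14, 0.55)),
        size_range=(20, 280),
        covariate_effects={"sample_type": 0.6},
        seed=seed,
    )


def simulate_expression(config: ExprSimConfig) -> ExpressionMatrix:
    """Two-group lognormal expression with planted fold changes."""
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:03d}" for i in range(config.n_genes)]
    for g in config.planted:
        if g not in genes:
            raise ValueError(f"planted gene {g!r} outside the simulated gene set")
    base = rng.uniform(1.0, 4.0, size=config.n_genes)  # log2 baseline abundance
    n = config.n_case + config.n_control
    log2x = base[:, None] + rng.normal(0.0, config.noise, size=(config.n_genes, n))
    case_cols = np.arange(config.n_case)
    for gi, g in enumerate(genes):
        shift = config.planted.get(g, 0.0)
        log2x[gi, case_cols] += shift

    stage = None
    if config.stage_effect is not None:
        stages = list(config.stage_effect)
        assign = stages * (config.n_case // len(stages) + 1)
        assign = assign[: config.n_case]
        for gi, g in enumerate(genes):
            if g in config.planted:
                for ci, st in enumerate(assign):
                    log2x[gi, ci] += math.log2(config.stage_effect[st])
        stage = pd.Series(
            assign + [None] * config.n_control,
            index=[f"S{i:03d}" for i in range(n)],
            dtype=object,
        )

    samples = [f"S{i:03d}" for i in range(n)]
    labels = pd.Series(
        ["case"] * config.n_case + ["control"] * config.n_control, index=samples
    )
    values = pd.DataFrame(np.exp2(log2x), index=genes, columns=samples)
    return ExpressionMatrix(values=values, labels=labels, stage=stage)


def write_meta_csv(records: Sequence[StudyRecord], path) -> None:
    """Emit simulated records in the same CSV schema the parser consumes."""
    rows = []
    for r in records:
        rows.append(
            {
                "author": r.author,
                "year": r.year,
                "ethnicity": r.ethnicity,
                "gene": r.gene,
                "regulation": r.regulation.capitalize(),
                "location": r.location.capitalize(),
                "sample_type": {"tissue": "Tissue", "circulating": "Serum",
                                "gastric_juice": "Gastric juices"}[r.sample_type],
                "reported_auc": "",
                "cutoff": "",
                "sen": r.sen,
                "spe": r.spe,
                "total": r.total,
                "n_case": r.n_case,
                "n_control": r.n_control,
                "control_source": "synthetic",
                "nos": r.nos,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_expression_csv(expr: ExpressionMatrix, matrix_path, annotation_path) -> None:
    """Emit matrix + annotation sidecar in the schema read_expression consumes."""
    expr.values.to_csv(matrix_path)
    ann = pd.DataFrame({"sample": expr.samples, "label": expr.labels.to_numpy()})
    if expr.stage is not None:
        ann["stage"] = expr.stage.to_numpy()
    ann.to_csv(annotation_path, index=False)
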