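"""Pipeline assembly and command-line interface.

`run_meta` chains the study-level stages in the order of the original
analysis — pooling, heterogeneity, subgroups, meta-regression with backward
elimination, leave-one-out sensitivity, Deeks' test, Fagan updating — and
writes a self-describing JSON bundle plus CSV tables.  `run_expr` does the
same for the expression stage (differential expression, per-gene ROC,
combined logistic model, stage-stratified AUC).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import click
import numpy as np

from . import __version__
from .bias_utility import deeks_test, fagan, leave_one_out
from .expression_dx import (
    ExpressionMatrix,
    diff_expr,
    fit_logistic_combo,
    read_expression,
    roc_curve,
    stage_stratified_auc,
)
from .hetero_explore import (
    backward_eliminate,
    moses_metaregression,
    subgroup_analysis,
    threshold_spearman,
)
from .meta_pool import fit_bivariate, pool_dsl, summarize_fit
from .sroc_auc import hsroc_from_bivariate, moses_sroc
from .study_table import (
    COVARIATE_NAMES,
    load_packaged_table,
    metareg_design,
    parse_study_table,
    reconstruct_all,
    records_to_frame,
)
from .synthetic_data import (
    ExprSimConfig,
    MetaSimConfig,
    simulate_expression,
    simulate_meta_dataset,
    write_expression_csv,
    write_meta_csv,
)

logger = logging.getLogger(__name__)

METRICS = ("sen", "spe", "plr", "nlr", "dor")


@dataclass
class AnalysisConfig:
    """Options shared by the pipeline runners; serialized into every bundle."""

    study_table: str | None = None     # None -> packaged table
    outdir: str = "dxmeta_results"
    seed: int = 0
    draws: int = 2000
    likelihood: str = "binomial"
    method: str = "ml"
    elimination_threshold: float = 0.05
    subgroupings: Sequence[str] = ("location", "sample_type", "sample_size", "quality")
    pretest: float = 0.20
    run_loo: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["subgroupings"] = list(self.subgroupings)
        d["version"] = __version__
        return d


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_meta(config: AnalysisConfig) -> dict:
    """Execute the full study-level chain; write bundle; return it."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = (
        load_packaged_table()
        if config.study_table is None
        else parse_study_table(config.study_table)
    )
    tables = reconstruct_all(records)
    bundle: dict = {"config": config.to_dict(), "k": len(records)}

    # pooled indices: bivariate headline + univariate heterogeneity
    fit = fit_bivariate(tables, method=config.method, likelihood=config.likelihood)
    bundle["bivariate"] = {
        "mu": fit.mu.tolist(),
        "sigma": fit.sigma.tolist(),
        "converged": fit.converged,
        "loglik": fit.loglik,
        "estimates": [_jsonable(e) for e in summarize_fit(fit)],
    }
    bundle["univariate"] = {}
    for m in METRICS:
        est, het = pool_dsl(tables, m)
        bundle["univariate"][m] = {"estimate": _jsonable(est), "heterogeneity": _jsonable(het)}

    sroc = hsroc_from_bivariate(fit, draws=config.draws, seed=config.seed)
    bundle["sroc"] = {"auc": sroc.auc, "se_auc": sroc.se_auc, "kind": sroc.kind}
    try:
        moses = moses_sroc(tables)
        bundle["sroc_moses"] = {
            "auc": moses.auc, "intercept_a": moses.intercept_a, "slope_b": moses.slope_b,
        }
    except ValueError as exc:
        logger.warning("linear-model SROC skipped: %s", exc)
        bundle["sroc_moses"] = {"skipped": str(exc)}

    try:
        bundle["threshold"] = _jsonable(threshold_spearman(tables))
    except ValueError as exc:
        logger.warning("threshold test skipped: %s", exc)
        bundle["threshold"] = {"skipped": str(exc)}

    subgroups = {}
    for grouping in config.subgroupings:
        try:
            rep = subgroup_analysis(records, tables, grouping,
                                    seed=config.seed, draws=config.draws)
        except ValueError as exc:
            logger.warning("subgroup %s skipped: %s", grouping, exc)
            subgroups[grouping] = {"skipped": str(exc)}
            continue
        subgroups[grouping] = {
            "n_excluded": rep.n_excluded,
            "comparison": _jsonable(rep.comparison),
            "groups": [
                {
                    "label": g.label,
                    "k": g.k,
                    "auc": g.sroc.auc,
                    "se_auc": g.sroc.se_auc,
                    "estimates": [_jsonable(e) for e in g.estimates],
                    "i2": {h.metric: h.i2 for h in g.heterogeneity},
                }
                for g in rep.groups
            ],
        }
    bundle["subgroups"] = subgroups

    design = metareg_design(records)
    try:
        trajectory = backward_eliminate(
            tables, design, threshold=config.elimination_threshold
        )
        bundle["metaregression"] = [_jsonable(m) for m in trajectory]
    except ValueError as exc:
        logger.warning("metaregression skipped: %s", exc)
        bundle["metaregression"] = {"skipped": str(exc)}

    try:
        bundle["deeks"] = _jsonable(deeks_test(tables))
    except ValueError as exc:
        logger.warning("Deeks' test skipped: %s", exc)
        bundle["deeks"] = {"skipped": str(exc)}

    plr = next(e for e in summarize_fit(fit) if e.metric == "plr").point
    nlr = next(e for e in summarize_fit(fit) if e.metric == "nlr").point
    bundle["fagan"] = _jsonable(fagan(config.pretest, plr, nlr))

    if config.run_loo:
        try:
            loo = leave_one_out(tables, seed=config.seed)
            bundle["leave_one_out"] = {
                "n_flagged": len(loo.flagged),
                "flagged": [r.omitted for r in loo.flagged],
                "baseline": _jsonable(loo.baseline),
            }
        except ValueError as exc:
            logger.warning("leave-one-out skipped: %s", exc)
            bundle["leave_one_out"] = {"skipped": str(exc)}

    records_to_frame(records).to_csv(outdir / "studies.csv", index=False)
    _write_table2(bundle, outdir / "pooled_performance.csv")
    _write_table3(bundle, outdir / "metaregression.csv")
    with (outdir / "meta_results.json").open("w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
    logger.info("meta bundle written to %s", outdir)
    return bundle


def _write_table2(bundle: dict, path: Path) -> None:
    import pandas as pd

    rows = []

    def add(label, k, estimates, i2, auc, z=None, p=None):
        row = {"subgroup": label, "k": k}
        for e in estimates:
            m = e["metric"]
            row[m] = e["point"]
            row[f"{m}_ci_low"] = e["ci_low"]
            row[f"{m}_ci_high"] = e["ci_high"]
            row[f"{m}_i2"] = i2.get(m)
        row["auc"] = auc
        row["z_vs_other"] = z
        row["p_vs_other"] = p
        rows.append(row)

    i2_all = {m: bundle["univariate"][m]["heterogeneity"]["i2"] for m in METRICS}
    add("all_studies", bundle["k"], bundle["bivariate"]["estimates"], i2_all,
        bundle["sroc"]["auc"])
    for grouping, rep in bundle.get("subgroups", {}).items():
        if "skipped" in rep:
            continue
        comp = rep["comparison"]
        for gi, g in enumerate(rep["groups"]):
            add(f"{grouping}:{g['label']}", g["k"], g["estimates"], g["i2"],
                g["auc"], comp["z"] if gi == 0 else None,
                comp["p_value"] if gi == 0 else None)
    pd.DataFrame(rows).to_csv(path, index=False)


def _write_table3(bundle: dict, path: Path) -> None:
    import pandas as pd

    models = bundle.get("metaregression")
    if not isinstance(models, list):
        return
    rows = []
    for mi, model in enumerate(models):
        for t in model["terms"]:
            rows.append(
                {
                    "model": mi,
                    "tau2": model["tau2"],
                    "term": t["name"],
                    "coeff": t["coeff"],
                    "se": t["se"],
                    "p_value": t["p_value"],
                    "rdor": t["rdor"],
                    "rdor_ci_low": t["rdor_ci_low"],
                    "rdor_ci_high": t["rdor_ci_high"],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def run_expr(
    config: AnalysisConfig,
    expr: ExpressionMatrix,
    genes: Sequence[str] | None = None,
) -> dict:
    """Expression-stage chain: DE -> per-gene ROC -> combined model -> stages."""
    import pandas as pd

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config": config.to_dict(), "n_samples": len(expr.samples)}

    de = diff_expr(expr)
    bundle["diff_expr"] = [_jsonable(r) for r in de]
    significant = [r.gene for r in de if r.direction != "no_difference"]
    chosen = list(genes) if genes else significant
    bundle["model_genes"] = chosen

    rocs = {}
    for r in de:
        vals = expr.values.loc[r.gene].to_numpy(float)
        scores = vals if r.log_fc >= 0 else -vals  # orient: higher = case-like
        rocs[r.gene] = _jsonable(roc_curve(scores, expr.labels.to_numpy()))
    bundle["single_gene_roc"] = rocs

    if chosen:
        model = fit_logistic_combo(expr, chosen)
        score = model.score(expr)
        combo_roc = roc_curve(score.to_numpy(), expr.labels.to_numpy())
        bundle["combined_model"] = {
            "equation": model.equation(),
            "intercept": model.intercept,
            "coefficients": dict(model.coefficients),
            "separated": model.separated,
            "roc": _jsonable(combo_roc),
        }
        if expr.stage is not None and expr.stage.notna().any():
            try:
                stages = stage_stratified_auc(expr, model)
                bundle["stages"] = [
                    {
                        "stage": label,
                        "roc": _jsonable(roc),
                        "comparison_vs_I": _jsonable(comp) if comp else None,
                    }
                    for label, roc, comp in stages
                ]
            except Exception as exc:
                logger.warning("stage analysis skipped: %s", exc)
                bundle["stages"] = {"skipped": str(exc)}
        else:
            logger.warning("no stage labels; stage analysis skipped")

    pd.DataFrame(bundle["diff_expr"]).to_csv(outdir / "diff_expr.csv", index=False)
    pd.DataFrame(
        [{"gene": g, **r} for g, r in rocs.items()]
    ).to_csv(outdir / "single_gene_roc.csv", index=False)
    with (outdir / "expr_results.json").open("w") as fh:
        json.dump(bundle, fh, indent=2, sort_keys=True)
    return bundle


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


@click.group()
@click.option("-v", "--verbose", count=True, help="-v info, -vv debug")
def cli(verbose: int) -> None:
    """Diagnostic-accuracy meta-analysis toolkit."""
    level = logging.WARNING - 10 * min(verbose, 2)
    logging.basicConfig(stream=sys.stderr, level=level,
                        format="%(levelname)s %(name)s: %(message)s")


_common = [
    click.option("--table", type=click.Path(exists=True), default=None,
                 help="study CSV (default: packaged table)"),
    click.option("--outdir", default="dxmeta_results", show_default=True),
    click.option("--seed", default=0, show_default=True),
]


def _with(opts):
    def deco(f):
        for opt in reversed(opts):
            f = opt(f)
        return f
    return deco


@cli.command()
@_with(_common)
@click.option("--likelihood", type=click.Choice(["binomial", "normal"]),
              default="binomial", show_default=True)
@click.option("--no-loo", is_flag=True, help="skip the leave-one-out sweep")
def meta(table, outdir, seed, likelihood, no_loo):
    """Full study-level pipeline on a study table."""
    cfg = AnalysisConfig(study_table=table, outdir=outdir, seed=seed,
                         likelihood=likelihood, run_loo=not no_loo)
    bundle = run_meta(cfg)
    ests = {e["metric"]: e["point"] for e in bundle["bivariate"]["estimates"]}
    click.echo(
        f"k={bundle['k']}  SEN={ests['sen']:.2f}  SPE={ests['spe']:.2f}  "
        f"PLR={ests['plr']:.1f}  NLR={ests['nlr']:.2f}  DOR={ests['dor']:.0f}  "
        f"AUC={bundle['sroc']['auc']:.2f}"
    )


@cli.command()
@_with(_common)
@click.argument("grouping", type=click.Choice(
    ["location", "sample_type", "sample_size", "quality"]))
def subgroup(table, outdir, seed, grouping):
    """One stratified analysis with its AUC comparison."""
    records = load_packaged_table() if table is None else parse_study_table(table)
    rep = subgroup_analysis(records, reconstruct_all(records), grouping, seed=seed)
    for g in rep.groups:
        ests = {e.metric: e.point for e in g.estimates}
        click.echo(f"{g.label:12s} k={g.k:3d} SEN={ests['sen']:.2f} "
                   f"SPE={ests['spe']:.2f} DOR={ests['dor']:.1f} AUC={g.sroc.auc:.2f}")
    click.echo(f"z={rep.comparison.z:.3f}  p={rep.comparison.p_value:.3f}")


@cli.command()
@_with(_common)
def metareg(table, outdir, seed):
    """Meta-regression on ln DOR with backward elimination."""
    records = load_packaged_table() if table is None else parse_study_table(table)
    tables = reconstruct_all(records)
    trajectory = backward_eliminate(tables, metareg_design(records))
    for i, model in enumerate(trajectory):
        names = [t.name for t in model.covariate_terms]
        click.echo(f"model {i}: tau2={model.tau2:.4f} covariates={names}")
        for t in model.covariate_terms:
            click.echo(f"  {t.name:12s} coeff={t.coeff:+.3f} se={t.se:.4f} "
                       f"p={t.p_value:.4f} RDOR={t.rdor:.2f} "
                       f"({t.rdor_ci_low:.2f}, {t.rdor_ci_high:.2f})")


@cli.command()
@_with(_common)
def deeks(table, outdir, seed):
    """Deeks' funnel-plot asymmetry test."""
    records = load_packaged_table() if table is None else parse_study_table(table)
    res = deeks_test(reconstruct_all(records))
    click.echo(f"slope={res.slope:.3f}  se={res.se:.3f}  p={res.p_value:.2f}  k={res.k}")


@cli.command(name="fagan")
@_with(_common)
@click.option("--pretest", default=0.20, show_default=True)
def fagan_cmd(table, outdir, seed, pretest):
    """Fagan post-test probabilities from the pooled likelihood ratios."""
    records = load_packaged_table() if table is None else parse_study_table(table)
    fit = fit_bivariate(reconstruct_all(records))
    ests = {e.metric: e.point for e in summarize_fit(fit)}
    res = fagan(pretest, ests["plr"], ests["nlr"])
    click.echo(f"pretest={res.pretest:.2f}  post(+)={res.posttest_positive:.2f}  "
               f"post(-)={res.posttest_negative:.2f}")


@cli.command()
@_with(_common)
def loo(table, outdir, seed):
    """Leave-one-out influence sweep of the bivariate fit."""
    records = load_packaged_table() if table is None else parse_study_table(table)
    res = leave_one_out(reconstruct_all(records), seed=seed)
    click.echo(f"baseline SEN={res.baseline.sen:.3f} SPE={res.baseline.spe:.3f}")
    click.echo(f"flagged: {len(res.flagged)}")
    for r in res.flagged:
        click.echo(f"  {r.omitted}: SEN={r.sen:.3f} SPE={r.spe:.3f}")


@cli.command(name="simulate-meta")
@click.option("--k", default=54, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", type=click.Path(), required=True)
def simulate_meta_cmd(k, seed, out):
    """Write a synthetic study-level CSV drawn from the bivariate model."""
    records, _ = simulate_meta_dataset(MetaSimConfig(k=k, seed=seed))
    write_meta_csv(records, out)
    click.echo(f"wrote {k} synthetic study rows to {out}")


@cli.command(name="simulate-expr")
@click.option("--genes", default=20, show_default=True)
@click.option("--cases", default=50, show_default=True)
@click.option("--controls", default=50, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--matrix", type=click.Path(), required=True)
@click.option("--annotation", type=click.Path(), required=True)
def simulate_expr_cmd(genes, cases, controls, seed, matrix, annotation):
    """Write a synthetic expression matrix + annotation sidecar."""
    expr = simulate_expression(
        ExprSimConfig(n_genes=genes, n_case=cases, n_control=controls, seed=seed)
    )
    write_expression_csv(expr, matrix, annotation)
    click.echo(f"wrote {genes}x{cases + controls} matrix to {matrix}")


@cli.command(name="expr-dx")
@click.option("--matrix", type=click.Path(exists=True), required=True)
@click.option("--annotation", type=click.Path(exists=True), required=True)
@click.option("--genes", default=None, help="comma-separated model genes")
@click.option("--outdir", default="dxmeta_results", show_default=True)
@click.option("--seed", default=0, show_default=True)
def expr_dx_cmd(matrix, annotation, genes, outdir, seed):
    """Expression-stage pipeline on a matrix + annotation."""
    expr = read_expression(matrix, annotation)
    cfg = AnalysisConfig(outdir=outdir, seed=seed)
    bundle = run_expr(cfg, expr, genes.split(",") if genes else None)
    if "combined_model" in bundle:
        click.echo(bundle["combined_model"]["equation"])
        click.echo(f"combined AUC={bundle['combined_model']['roc']['auc']:.3f}")


if __name__ == "__main__":
    cli()
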