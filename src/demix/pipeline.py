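"""End-to-end orchestration of the two-stage DE analysis.

Stages run in order: read or simulate the expression dataset, fit the
crossed random-effects model by REML, extract the gene-by-population BLUPs,
fit the per-population scale mixture, call DE genes and their FDRs, form
exclusive up/down sets, cluster DE profiles, and (when an annotation map is
supplied) run over-representation analysis on each derived gene set. Every
stage writes its artifact under the output directory, and a run with the
same configuration and seed is byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .data import ExpressionDataset, GroundTruth
from .de_sets import exclusive_de_sets
from .clustering import cluster_de_profiles
from .enrichment import AnnotationMap, enrich, read_annotation_tsv, read_gmt
from .io import (
    read_expression,
    write_dataset,
    write_effect_table,
    write_ground_truth,
    write_json,
)
from .lmm import cellpop_f_test, extract_gene_cellpop_effects, fit_reml
from .mixture import (
    DECalls,
    DegenerateInputError,
    classify_and_fdr,
    fit_scale_mixture,
    overall_fdr,
)
from .simulate import GeneratorConfig, generate_dataset

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of (``expression_path`` + ``metadata_path``) or
    ``generator`` must be supplied.
    """

    out_dir: str | Path
    expression_path: str | Path | None = None
    metadata_path: str | Path | None = None
    generator: GeneratorConfig | None = None
    log_transform: str = "none"
    de_threshold: float = 0.8
    enrichment_cutoff: float = 0.05
    cluster_levels: int = 3
    annotation_path: str | Path | None = None
    annotation_format: str = "tsv"  # or "gmt"
    seed: int = 0

    def __post_init__(self) -> None:
        has_files = self.expression_path is not None and self.metadata_path is not None
        has_gen = self.generator is not None
        if has_files == has_gen:
            raise ValueError(
                "supply exactly one of (expression_path + metadata_path) or generator"
            )
        if not 0.0 < self.de_threshold < 1.0:
            raise ValueError("de_threshold must lie in (0, 1)")


def _load_annotations(config: RunConfig) -> AnnotationMap | None:
    if config.annotation_path is None:
        return None
    if config.annotation_format == "gmt":
        return read_gmt(config.annotation_path)
    return read_annotation_tsv(config.annotation_path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the run report.

    On failure, a report naming the failed stage is persisted next to any
    partial outputs and :class:`PipelineError` is raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "version": __version__, "stages": []}
    stage = "setup"
    try:
        stage = "input"
        truth: GroundTruth | None = None
        if config.generator is not None:
            dataset, truth = generate_dataset(config.generator)
            write_dataset(dataset, out)
            write_ground_truth(truth, out)
        else:
            dataset = read_expression(
                config.expression_path, config.metadata_path, config.log_transform
            )
        report["n_genes"] = dataset.n_genes
        report["n_arrays"] = dataset.n_arrays
        report["populations"] = dataset.populations
        report["stages"].append(stage)

        stage = "fit_reml"
        fit = fit_reml(dataset)
        ftest = cellpop_f_test(fit)
        report["variance_components"] = fit.variance_components.as_dict()
        report["reml"] = {
            "loglik": fit.reml_loglik,
            "n_iterations": fit.n_iterations,
            "converged": fit.converged,
        }
        report["cellpop_test"] = {
            "f_statistic": ftest.f_statistic,
            "numerator_df": ftest.numerator_df,
            "denominator_df": ftest.denominator_df,
            "p_value": ftest.p_value,
        }
        write_json({**report["variance_components"], **report["cellpop_test"]},
                   out / "lmm_report.json")
        report["stages"].append(stage)

        stage = "extract_effects"
        effects = extract_gene_cellpop_effects(fit)
        write_effect_table(effects, out / "effects.tsv")
        report["stages"].append(stage)

        stage = "fit_mixture"
        mixture_report: dict = {}
        calls: list[DECalls] = []
        rows = []
        for i, pop in enumerate(effects.columns):
            x = effects[pop].to_numpy()
            try:
                mfit = fit_scale_mixture(x, seed=config.seed * 1000 + i)
            except DegenerateInputError:
                mixture_report[pop] = None  # no spread: nothing is DE
                calls.append(
                    DECalls(population=pop, threshold=config.de_threshold,
                            de_genes={}, fdr=None, effect_cutoff=float("inf"))
                )
                continue
            c = classify_and_fdr(
                mfit, x, effects.index, population=pop, threshold=config.de_threshold
            )
            calls.append(c)
            mixture_report[pop] = {
                "pi1": mfit.params.pi1,
                "sigma0": mfit.params.sigma0,
                "sigma1": mfit.params.sigma1,
                "n_iterations": mfit.n_iterations,
                "n_de": c.n_de,
                "fdr": c.fdr,
                "effect_cutoff": c.effect_cutoff,
            }
            for g in effects.index:
                rows.append(
                    {
                        "gene_id": g,
                        "population": pop,
                        "effect": effects.at[g, pop],
                        "posterior": c.posteriors.get(g, 0.0),
                        "called": g in c.de_genes,
                        "sign": c.de_genes.get(g, 0),
                    }
                )
        pd.DataFrame(rows).to_csv(out / "de_calls.tsv", sep="\t", index=False)
        write_json(mixture_report, out / "mixture_fits.json")
        report["mixture"] = mixture_report
        report["n_de"] = {c.population: c.n_de for c in calls}
        try:
            report["overall_fdr"] = overall_fdr(calls)
        except ValueError:
            report["overall_fdr"] = None
        report["stages"].append(stage)

        stage = "exclusive_sets"
        sets = exclusive_de_sets(calls, effects)
        report["exclusive_sets"] = {
            p: {"up": len(s.up), "down": len(s.down)} for p, s in sets.items()
        }
        for p, s in sets.items():
            safe = p.replace("/", "_").replace(" ", "_")
            rows = [{"gene_id": g, "direction": "up"} for g in sorted(s.up)]
            rows += [{"gene_id": g, "direction": "down"} for g in sorted(s.down)]
            pd.DataFrame(rows, columns=["gene_id", "direction"]).to_csv(
                out / f"exclusive_{safe}.tsv", sep="\t", index=False
            )
        report["stages"].append(stage)

        stage = "cluster"
        de_union = sorted(set().union(*(set(c.de_genes) for c in calls)))
        k = 2**config.cluster_levels
        if len(de_union) >= k:
            assignment = cluster_de_profiles(
                effects.loc[de_union], n_levels=config.cluster_levels
            )
            assignment.labels.to_csv(out / "clusters.tsv", sep="\t", index_label="gene_id")
            assignment.standardized_profiles.loc[assignment.leaf_order].to_csv(
                out / "heatmap_matrix.tsv", sep="\t", index_label="gene_id"
            )
            report["cluster_sizes"] = {
                str(c): n for c, n in assignment.sizes().items()
            }
        else:
            log.info("skipping clustering: %d DE genes < %d clusters", len(de_union), k)
            report["cluster_sizes"] = None
        report["stages"].append(stage)

        stage = "enrichment"
        ann = _load_annotations(config)
        if ann is not None:
            universe = list(effects.index)
            summary = {}
            targets: dict[str, set[str]] = {}
            if report["cluster_sizes"]:
                for c in sorted(set(assignment.labels)):
                    targets[f"cluster_{c}"] = set(
                        assignment.labels.index[assignment.labels == c]
                    )
            for p, s in sets.items():
                safe = p.replace("/", "_").replace(" ", "_")
                if s.up:
                    targets[f"up_{safe}"] = s.up
                if s.down:
                    targets[f"down_{safe}"] = s.down
            for name, gs in targets.items():
                res = enrich(gs, universe, ann, fdr_cutoff=config.enrichment_cutoff)
                res.to_csv(out / f"enrichment_{name}.tsv", sep="\t", index=False)
                summary[name] = int(res["significant"].sum()) if not res.empty else 0
            report["enrichment_significant_terms"] = summary
        report["stages"].append(stage)

    except Exception as exc:  # persist a failure report naming the stage
        write_json({"failed_stage": stage, "error": str(exc)}, out / "failure.json")
        raise PipelineError(stage, exc) from exc

    write_json(report, out / "run_report.json")
    return report
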