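"""End-to-end orchestration: simulate -> preprocess -> DE -> null -> recovery -> enrichment.

A single :class:`PipelineConfig` (loadable from YAML/JSON) drives the run;
every output file carries a provenance comment (stage, seed, config hash)
and a machine-readable JSON run report aggregates the results of all
stages. Stages run in dependency order and a failed stage raises
:class:`PipelineError` naming the stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import arrays, counts, diffexpr, enrichment, io, recovery, simulate

logger = logging.getLogger("rpewound")
if not logger.handlers:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All thresholds and toggles of the analysis, in one place."""

    out_dir: str = "pipeline_out"
    seed: int = 17
    n_genes: int = 4000
    # stage toggles
    run_array: bool = True
    run_rnaseq: bool = True
    run_de: bool = True
    run_null: bool = True
    run_recovery: bool = True
    run_enrichment: bool = True
    # thresholds (the analysis defaults)
    min_each_fold: float = 1.5
    min_mean_fold: float = 2.0
    detection_multiplier: float = 2.0
    min_rpm: float = 1.0
    min_rpm_samples: int = 3
    recovery_thresholds: tuple[float, ...] = (0.25, 0.50)
    anova_alpha: float = 0.05
    screen_fold: float = 2.0
    recovery_scale: str = "log2"

    def __post_init__(self):
        for name in ("min_each_fold", "min_mean_fold", "detection_multiplier",
                     "min_rpm", "anova_alpha", "screen_fold"):
            if getattr(self, name) <= 0:
                raise PipelineError(f"{name} must be > 0")
        if self.run_recovery and not (self.run_de or self.run_rnaseq):
            raise PipelineError(
                "recovery needs a passage-dependent gene list: enable the DE "
                "stage (and the RNA-seq arm) or supply one")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if "recovery_thresholds" in data:
            data["recovery_thresholds"] = tuple(data["recovery_thresholds"])
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages on synthetic data and write a JSON run report.

    Returns the report dict; every result block also lands under
    ``config.out_dir`` as TSV/JSON with provenance headers.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = simulate.SimulationConfig(seed=config.seed, n_genes=config.n_genes)
    report: dict = {"seed": config.seed, "config_sha": config.config_hash(),
                    "stages": {}}

    def header(stage):
        return io.provenance_header(stage, seed=config.seed,
                                    config=asdict(config))

    stage = "simulate"
    try:
        logger.info("stage %s", stage)
        probe_raw, annot, array_sheet, truth = \
            simulate.simulate_array_experiment(sim_cfg)
        count_mat, rnaseq_sheet, _ = simulate.simulate_rnaseq_experiment(sim_cfg)
        io.write_matrix(probe_raw, out / "probes_raw.tsv", "probe_id", header(stage))
        io.write_table(annot, out / "probe_annotation.tsv", header(stage))
        io.write_table(array_sheet, out / "array_samples.tsv", header(stage))
        io.write_table(rnaseq_sheet, out / "rnaseq_samples.tsv", header(stage))
        io.write_matrix(count_mat, out / "counts.tsv", "gene", header(stage))
        io.write_table(truth, out / "truth.tsv", header(stage))
        sets = simulate.make_disease_gene_sets(truth, seed=config.seed)
        io.write_gmt({k: v["members"] for k, v in sets.items()},
                     out / "disease_sets.gmt",
                     {k: v["description"] for k, v in sets.items()})
        report["stages"][stage] = {
            "n_probes": len(probe_raw), "n_array_samples": len(array_sheet),
            "n_genes": len(count_mat), "n_rnaseq_samples": len(rnaseq_sheet)}
    except Exception as exc:
        raise PipelineError(f"stage {stage} failed: {exc}") from exc

    gene_expr = None
    if config.run_array:
        stage = "preprocess_array"
        try:
            logger.info("stage %s", stage)
            result = arrays.preprocess_array(
                probe_raw, annot,
                detection_multiplier=config.detection_multiplier)
            gene_expr = result["gene_matrix"]
            io.write_matrix(gene_expr, out / "gene_expression.tsv", "gene",
                            header(stage))
            report["stages"]["preprocess"] = {
                "n_probes_in": result["n_probes_in"],
                "n_probes_detected": result["n_probes_detected"],
                "n_genes": result["n_genes"]}
        except Exception as exc:
            raise PipelineError(f"stage {stage} failed: {exc}") from exc

    rpm = None
    if config.run_rnaseq:
        stage = "preprocess_rnaseq"
        try:
            logger.info("stage %s", stage)
            factors = counts.tmm_factors(count_mat)
            rpm_all = counts.cpm_normalize(count_mat, factors, floor=0.5)
            kept = counts.expression_filter(rpm_all, config.min_rpm,
                                            config.min_rpm_samples)
            rpm = rpm_all.loc[kept]
            io.write_matrix(rpm, out / "rpm.tsv", "gene", header(stage))
            io.write_table(factors.reset_index().rename(
                columns={"index": "sample_id"}), out / "tmm_factors.tsv",
                header(stage))
            report["stages"].setdefault("preprocess", {})["rnaseq"] = {
                "n_genes_in": len(count_mat), "n_genes_expressed": len(kept),
                "tmm_factors": {s: round(float(f), 6)
                                for s, f in factors.items()}}
        except Exception as exc:
            raise PipelineError(f"stage {stage} failed: {exc}") from exc

    de_table = None
    if config.run_de and gene_expr is not None:
        stage = "de_call"
        try:
            logger.info("stage %s", stage)
            de_table = diffexpr.de_call_table(
                gene_expr, array_sheet, min_each=config.min_each_fold,
                min_mean=config.min_mean_fold)
            io.write_matrix(de_table.to_frame(), out / "de_calls.tsv", "gene",
                            header(stage))
            per_day = {str(day): {"up": int((t["call"] == "up").sum()),
                                  "down": int((t["call"] == "down").sum())}
                       for day, t in de_table.per_time.items()}
            report["stages"]["de"] = {
                "per_day": per_day,
                "n_up": len(de_table.up_genes),
                "n_down": len(de_table.down_genes),
                "n_ambiguous": len(de_table.ambiguous_genes)}
        except Exception as exc:
            raise PipelineError(f"stage {stage} failed: {exc}") from exc

    if config.run_null and gene_expr is not None:
        stage = "null_estimate"
        try:
            logger.info("stage %s", stage)
            nulls = {}
            for passage in array_sheet["passage"].unique():
                for day in sorted(array_sheet["day"].unique()):
                    est = diffexpr.empirical_null_counts(
                        gene_expr, array_sheet,
                        {"passage": passage, "day": day},
                        min_each=config.min_each_fold,
                        min_mean=config.min_mean_fold)
                    nulls[f"{passage}_day{day}"] = est.to_dict()
            (out / "null_estimates.json").write_text(
                json.dumps(nulls, indent=2))
            report["stages"]["null"] = {
                k: v["count"] for k, v in nulls.items()}
        except Exception as exc:
            raise PipelineError(f"stage {stage} failed: {exc}") from exc

    rnaseq_de_up = rnaseq_de_down = None
    if config.run_recovery and rpm is not None:
        stage = "recovery"
        try:
            logger.info("stage %s", stage)
            untreated = rnaseq_sheet[rnaseq_sheet["treatment"] == "none"]
            rnaseq_de = diffexpr.de_call_table(
                rpm, untreated, ref="P0", alt=sim_cfg.treated_passage,
                min_each=config.min_each_fold, min_mean=config.min_mean_fold)
            rnaseq_de_up, rnaseq_de_down = rnaseq_de.up_genes, rnaseq_de.down_genes
            passage_dep = rnaseq_de_up.union(rnaseq_de_down)
            rep = recovery.recovery_from_matrix(
                rpm, rnaseq_sheet, passage_dep,
                reference={"passage": "P0"},
                baseline={"passage": sim_cfg.treated_passage,
                          "treatment": "none"},
                treated={"passage": sim_cfg.treated_passage,
                         "treatment": "A-83-01"},
                scale=config.recovery_scale,
                thresholds=config.recovery_thresholds)
            io.write_matrix(rep.per_gene, out / "recovery_per_gene.tsv",
                            "gene", header(stage))
            (out / "recovery_report.json").write_text(
                json.dumps(rep.to_dict(), indent=2))
            report["stages"]["recovery"] = {
                "n_passage_dependent": int(len(passage_dep)),
                **rep.to_dict()}
        except Exception as exc:
            raise PipelineError(f"stage {stage} failed: {exc}") from exc

    if config.run_enrichment and gene_expr is not None and de_table is not None:
        stage = "enrichment"
        try:
            logger.info("stage %s", stage)
            universe = gene_expr.index
            gmt = io.read_gmt(out / "disease_sets.gmt")
            disease = {name: enrichment.GeneSet(name, d["description"],
                                                tuple(d["members"]))
                       for name, d in gmt.items()}
            de_up = enrichment.GeneSet("DE_up", "up",
                                       tuple(de_table.up_genes))
            de_down = enrichment.GeneSet("DE_down", "down",
                                         tuple(de_table.down_genes))
            results = enrichment.enrich_directional(disease, de_up, de_down,
                                                    universe)
            (out / "enrichment.json").write_text(
                json.dumps([r.to_dict() for r in results], indent=2))
            report["stages"]["enrichment"] = [r.to_dict() for r in results]
        except Exception as exc:
            raise PipelineError(f"stage {stage} failed: {exc}") from exc

    (out / "run_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", out / "run_report.json")
    return report
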