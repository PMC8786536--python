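"""End-to-end orchestration: inputs -> EI/ES calls -> drivers -> clinical.

Stages run in the screening order of the analysis: preprocess the
expression and methylation matrices, call differential expression and
differential promoter methylation, intersect into EI/ES classes, keep
negatively correlated candidates, score each candidate's interaction
neighborhood for EI/ES enrichment, select drivers, and validate the
marker against the clinical endpoints. Every run writes a manifest
with a config hash, seed, package versions and per-stage row counts so
identical inputs reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, clinical, differential, io, network, preprocess

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    expression_path: str = ""
    methylation_path: str = ""
    samples_path: str | None = None
    probe_annotation_path: str = ""
    gene_models_path: str = ""
    edges_path: str = ""
    clinical_path: str | None = None
    outdir: str = "results"

    expression_units: str = "tpm"          # "fpkm" triggers the TPM transform
    upstream_bp: int = 800
    downstream_bp: int = 200
    stranded: bool = True
    max_missing_fraction: float = 0.0
    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    meth_p_threshold: float = 0.05
    rho_threshold: float = 0.0
    driver_fdr: float = 0.05
    driver_proportion: float = 0.10
    adjust_method: str = "fdr_bh"           # or "bonferroni"
    chi2_corrections: dict = field(default_factory=dict)
    survival_cut: str = "ihc"
    cox_select_p: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for v in (self.fdr_threshold, self.meth_p_threshold, self.driver_fdr,
                  self.driver_proportion):
            if not 0 < v < 1:
                raise ValueError("thresholds must lie in (0, 1)")
        if self.expression_units not in {"tpm", "fpkm"}:
            raise ValueError("expression_units must be 'tpm' or 'fpkm'")

    def hash(self) -> str:
        fields = dataclasses.asdict(self)
        fields.pop("outdir")  # the analysis is the same wherever it is written
        payload = json.dumps(fields, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    differential: pd.DataFrame
    ei_genes: list[str]
    es_genes: list[str]
    enrichment: pd.DataFrame
    drivers: list[str]
    association: pd.DataFrame | None
    logrank: clinical.LogrankResult | None
    cox: list[clinical.CoxResult] | None
    manifest: dict


_CLINICAL_FEATURES = [
    "age_gt55", "male", "hbv", "alt_gt35", "ast_gt31",
    "tb_gt12", "alb_gt40", "tnm_late", "tumor_gt5cm",
]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    def stage(name):
        logger.info("pipeline stage: %s", name)

    # -- preprocess --------------------------------------------------------
    stage("preprocess")
    expr = io.read_matrix(config.expression_path, config.samples_path)
    if config.expression_units == "fpkm":
        expr = preprocess.fpkm_to_tpm(expr)
    beta = io.read_matrix(config.methylation_path, config.samples_path)
    annotations = io.read_probe_annotation(config.probe_annotation_path)
    genes = io.read_gene_models(config.gene_models_path)
    beta = preprocess.filter_probes(beta, annotations, config.max_missing_fraction)
    mapping = preprocess.map_probes_to_promoters(
        annotations, genes, config.upstream_bp, config.downstream_bp, config.stranded
    )
    meth = preprocess.aggregate_promoter_methylation(beta, mapping)
    counts["genes_expression"] = len(expr.features)
    counts["probes_retained"] = len(beta.features)
    counts["genes_with_promoter_meth"] = len(meth.features)

    # -- differential calls and EI/ES classification -----------------------
    stage("differential")
    de = differential.call_differential_expression(
        expr, config.lfc_threshold, config.fdr_threshold,
        fdr_method=config.adjust_method,
    )
    dm = differential.call_differential_methylation(meth, config.meth_p_threshold)
    calls = differential.classify_ei_es(de, dm)
    kept = differential.correlation_filter(
        calls, expr, meth, config.rho_threshold
    )
    table = differential.differential_table(de, dm, calls)
    ei = sorted(g for g, c in kept.items() if c.epigenetic_class == differential.EI)
    es = sorted(g for g, c in kept.items() if c.epigenetic_class == differential.ES)
    counts["expression_up"] = sum(r.direction == "up" for r in de.values())
    counts["expression_down"] = sum(r.direction == "down" for r in de.values())
    counts["methylation_up"] = sum(r.direction == "up" for r in dm.values())
    counts["methylation_down"] = sum(r.direction == "down" for r in dm.values())
    counts["ei_candidates"] = sum(
        c.epigenetic_class == differential.EI for c in calls.values()
    )
    counts["es_candidates"] = sum(
        c.epigenetic_class == differential.ES for c in calls.values()
    )
    counts["ei_after_correlation"] = len(ei)
    counts["es_after_correlation"] = len(es)

    # -- network enrichment and driver selection ---------------------------
    stage("network")
    net = network.load_network(config.edges_path)
    background = set(ei) | set(es)
    sub, sub_summary = network.induced_subnetwork(net, background)
    results = network.neighborhood_enrichment(
        net, background, adjust=config.adjust_method
    )
    criteria = network.DriverCriteria(config.driver_fdr, config.driver_proportion)
    drivers = [r.gene_id for r in network.select_drivers(results, criteria)]
    enr_table = network.enrichment_table(results, criteria)
    counts["network_nodes"] = net.number_of_nodes()
    counts["subnetwork_nodes"] = sub_summary["n_nodes"]
    counts["drivers_selected"] = len(drivers)

    # -- clinical validation ----------------------------------------------
    assoc = logrank = cox_results = None
    if config.clinical_path:
        stage("clinical")
        clin = io.read_clinical(config.clinical_path)
        clin["marker_level"] = clinical.dichotomize(
            clin["staining_score"], rule=config.survival_cut
        )
        features = [f for f in _CLINICAL_FEATURES if f in clin.columns]
        assoc = clinical.association_table(
            clin, "marker_level", features, config.chi2_corrections
        )
        logrank = clinical.logrank_test(clin["time"], clin["event"], clin["marker_level"])
        cox_df = clin.assign(marker_high=(clin["marker_level"] == "high").astype(int))
        cox_results = clinical.cox_fit(
            cox_df,
            ["marker_high"] + features,
            model="multivariate",
            select_p=config.cox_select_p,
        )
        counts["patients"] = len(clin)

    # -- outputs and manifest ----------------------------------------------
    table.to_csv(outdir / "differential.tsv", sep="\t", float_format="%.6g")
    enr_table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
    pd.Series(ei, name="gene").to_csv(outdir / "ei_genes.tsv", sep="\t", index=False)
    pd.Series(es, name="gene").to_csv(outdir / "es_genes.tsv", sep="\t", index=False)
    pd.Series(drivers, name="gene").to_csv(outdir / "drivers.tsv", sep="\t", index=False)
    if assoc is not None:
        assoc.to_csv(outdir / "association.tsv", sep="\t", index=False, float_format="%.6g")
    if cox_results is not None:
        pd.DataFrame([dataclasses.asdict(r) for r in cox_results]).to_csv(
            outdir / "cox.tsv", sep="\t", index=False, float_format="%.6g"
        )
    manifest = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
        "counts": counts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(
        table, ei, es, enr_table, drivers, assoc, logrank, cox_results, manifest
    )
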