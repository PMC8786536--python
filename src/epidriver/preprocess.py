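"""Raw-input preprocessing: FPKM->TPM, probe filtering, promoter mapping.

Gene-level promoter methylation is the unweighted mean beta of the CpG
probes falling in a window around the transcription start site (TSS),
by default 800 bp upstream to 200 bp downstream. Coordinates are
1-based inclusive throughout, matching 450K manifest conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import OmicsMatrix

logger = logging.getLogger(__name__)

DEFAULT_UPSTREAM = 800
DEFAULT_DOWNSTREAM = 200


@dataclass(frozen=True)
class GeneModel:
    """A gene anchored by its TSS, used to place the promoter window."""

    gene_id: str
    chromosome: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise ValueError(f"{self.gene_id}: tss must be >= 1")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass(frozen=True)
class ProbeAnnotation:
    """Genomic location of a CpG probe (1-based)."""

    probe_id: str
    chromosome: str
    position: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.probe_id}: position must be >= 1")


@dataclass(frozen=True)
class PromoterWindow:
    gene_id: str
    chromosome: str
    start: int
    end: int

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


def fpkm_to_tpm(expr: OmicsMatrix) -> OmicsMatrix:
    """Rescale each sample column so it sums to one million.

    TPM_ij = FPKM_ij / sum_i FPKM_ij * 1e6. Idempotent up to floating
    point error.
    """
    expr.validate_expression()
    sums = expr.values.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"sample column(s) sum to zero: {list(zero.index)}")
    out = expr.values.div(sums, axis=1) * 1e6
    return OmicsMatrix(out, expr.groups, expr.pairs)


def filter_probes(
    beta: OmicsMatrix,
    annotations: dict[str, ProbeAnnotation],
    max_missing_fraction: float = 0.0,
) -> OmicsMatrix:
    """Drop unannotated probes and probes with too many missing betas.

    With the default ``max_missing_fraction=0`` any probe with a single
    missing value is removed. Remaining values must be finite betas.
    """
    annotated = beta.values.index.isin(annotations)
    n_unannotated = int((~annotated).sum())
    kept = beta.values.loc[annotated]
    missing_frac = kept.isna().mean(axis=1)
    complete = missing_frac <= max_missing_fraction
    n_missing = int((~complete).sum())
    out = kept.loc[complete]
    if n_unannotated or n_missing:
        logger.info(
            "filter_probes: removed %d unannotated and %d high-missingness probes",
            n_unannotated,
            n_missing,
        )
    if out.empty:
        logger.warning("filter_probes: no probes remain after filtering")
    result = OmicsMatrix(out, beta.groups, beta.pairs)
    result.validate_beta()
    return result


def promoter_window(
    gene: GeneModel,
    upstream_bp: int = DEFAULT_UPSTREAM,
    downstream_bp: int = DEFAULT_DOWNSTREAM,
    stranded: bool = True,
) -> PromoterWindow:
    """Window around the TSS, mirrored on the minus strand when stranded.

    Plus strand (or unstranded): [tss - upstream, tss + downstream].
    Minus strand, stranded: [tss - downstream, tss + upstream].
    Start is clamped at 1 near the chromosome edge.
    """
    if upstream_bp < 0 or downstream_bp < 0:
        raise ValueError("window extents must be non-negative")
    if stranded and gene.strand == "-":
        start, end = gene.tss - downstream_bp, gene.tss + upstream_bp
    else:
        start, end = gene.tss - upstream_bp, gene.tss + downstream_bp
    if start < 1:
        logger.info("promoter_window: clamping %s window start to 1", gene.gene_id)
        start = 1
    return PromoterWindow(gene.gene_id, gene.chromosome, start, end)


def map_probes_to_promoters(
    annotations: dict[str, ProbeAnnotation],
    genes: list[GeneModel],
    upstream_bp: int = DEFAULT_UPSTREAM,
    downstream_bp: int = DEFAULT_DOWNSTREAM,
    stranded: bool = True,
) -> dict[str, list[str]]:
    """Assign each probe to every gene whose promoter window contains it.

    A probe inside two overlapping promoters contributes to both genes.
    Returns gene_id -> sorted probe ids; genes with no probe map to [].
    """
    by_chrom: dict[str, list[ProbeAnnotation]] = {}
    for ann in annotations.values():
        by_chrom.setdefault(ann.chromosome, []).append(ann)
    for anns in by_chrom.values():
        anns.sort(key=lambda a: (a.position, a.probe_id))

    mapping: dict[str, list[str]] = {}
    positions = {c: np.array([a.position for a in anns]) for c, anns in by_chrom.items()}
    for gene in sorted(genes, key=lambda g: g.gene_id):
        win = promoter_window(gene, upstream_bp, downstream_bp, stranded)
        anns = by_chrom.get(gene.chromosome, [])
        if not anns:
            mapping[gene.gene_id] = []
            continue
        pos = positions[gene.chromosome]
        lo = int(np.searchsorted(pos, win.start, side="left"))
        hi = int(np.searchsorted(pos, win.end, side="right"))
        mapping[gene.gene_id] = sorted(a.probe_id for a in anns[lo:hi])
    n_unmapped = sum(1 for v in mapping.values() if not v)
    if n_unmapped:
        logger.info("map_probes_to_promoters: %d genes with zero probes", n_unmapped)
    return mapping


def aggregate_promoter_methylation(
    beta: OmicsMatrix, mapping: dict[str, list[str]]
) -> OmicsMatrix:
    """Average mapped probe betas per gene and sample.

    Genes with no mapped probe are absent from the output. Rows are
    sorted by gene id for deterministic output.
    """
    rows = {}
    for gene_id in sorted(mapping):
        probes = mapping[gene_id]
        if not probes:
            continue
        missing = [p for p in probes if p not in beta.values.index]
        if missing:
            raise KeyError(f"{gene_id}: mapped probes absent from matrix: {missing[:5]}")
        rows[gene_id] = beta.values.loc[probes].mean(axis=0)
    values = pd.DataFrame(rows).T if rows else pd.DataFrame(columns=beta.values.columns)
    values.columns = beta.values.columns
    return OmicsMatrix(values, beta.groups, beta.pairs)
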