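"""End-to-end analysis: classify -> select -> map -> target set -> enrichment.

This is the library layer the command-line interface wraps; tests and the
acceptance script call it directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .enrichment import run_permutation_test
from .mapping import GeneIndex, map_snps
from .model import (
    AssociationTable,
    EnrichmentResult,
    GeneRecord,
    GenomeLayout,
    MirnaInteraction,
    OrthologPair,
    SelectionMask,
    SnpArray,
    TargetSet,
    TierConfig,
)
from .screen import EvidenceSummary, select_top_fraction, summarize
from .target_db import build_target_set, map_orthologs

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    summary: EvidenceSummary
    mask: SelectionMask
    targets: TargetSet
    mapped_genes: set[str]
    per_snp_genes: dict[str, set[str]]
    enrichment: EnrichmentResult


def run_pipeline(
    layout: GenomeLayout,
    genes: list[GeneRecord],
    array: SnpArray,
    association: AssociationTable,
    interactions: list[MirnaInteraction],
    orthologs: list[OrthologPair],
    source_mirnas: list[str] | None = None,
    *,
    fraction: float = 0.005,
    tiers: TierConfig = TierConfig(),
    min_support: int = 2,
    min_mirnas: int = 2,
    n_sims: int = 10_000,
    seed: int | None = None,
    rank_by: str = "posterior",
) -> PipelineResult:
    """Run the whole enrichment analysis on one set of tables.

    When *source_mirnas* is None, every source miRNA appearing in the
    ortholog table is taken as a miRNA of interest.
    """
    summary = summarize(association)
    log.info(
        "evidence: %d SNPs, %d uninformative, %d for, %d against",
        summary.n_total, summary.n_uninformative, summary.n_for, summary.n_against,
    )
    mask = select_top_fraction(association, array, fraction, rank_by=rank_by)
    log.info("selected %d of %d evidence-for SNPs (fraction %g)", mask.popcount, summary.n_for, fraction)

    if source_mirnas is None:
        source_mirnas = sorted({p.source_mirna for p in orthologs})
    mapped_mirnas, unmapped = map_orthologs(source_mirnas, orthologs)
    if unmapped:
        log.info("%d of %d source miRNAs had no ortholog", len(unmapped), len(source_mirnas))
    targets = build_target_set(interactions, mapped_mirnas, min_support, min_mirnas)
    log.info("target set: %d genes (support>=%d, miRNAs>=%d)", len(targets), min_support, min_mirnas)

    index = GeneIndex(genes, layout)
    selected = [array.record(int(i)) for i in mask.indices()]
    mapped_genes, per_snp = map_snps(selected, index, tiers)
    log.info("selected SNPs map to %d genes", len(mapped_genes))

    enrichment = run_permutation_test(array, mask, index, tiers, targets, n_sims=n_sims, seed=seed)
    log.info(
        "observed fraction %.4f (%d/%d genes); null mean %.4f; p = %.4g",
        enrichment.observed_fraction, enrichment.observed_hit_count,
        enrichment.observed_gene_count, enrichment.null_fraction_mean, enrichment.p_value,
    )
    return PipelineResult(summary, mask, targets, mapped_genes, per_snp, enrichment)
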