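"""Density-adaptive tiered SNP-to-gene assignment.

Each SNP is searched against gene intervals with an expanding ladder of
windows (default 25 kb, 250 kb, 500 kb, 1 Mb half-widths). The search
stops at the first tier that captures at least one gene and returns every
gene within that tier, so gene-poor regions are searched further out while
gene-dense regions contribute only nearby candidates.

Distance is measured from the SNP point to the nearest edge of the gene
body (0 inside the gene), boundary inclusive: a gene exactly 25,000 bp
away is captured by the 25 kb tier. Searches never cross chromosome
boundaries.

``map_snp_bruteforce`` is a deliberately naive twin used as the oracle in
equivalence tests; it exists solely to guard the indexed implementation.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .model import GeneRecord, GenomeLayout, SnpRecord, TierConfig


def interval_distance(pos: int, start: int, end: int) -> int:
    """Distance from point *pos* to interval [start, end); 0 if inside."""
    if start <= pos < end:
        return 0
    if pos < start:
        return start - pos
    return pos - (end - 1)


class GeneIndex:
    """Per-chromosome interval index over a gene annotation."""

    def __init__(self, genes: Iterable[GeneRecord], layout: GenomeLayout):
        self.layout = layout
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self.genes = list(genes)
        for g in self.genes:
            if g.chrom not in layout:
                raise KeyError(f"gene {g.gene_id!r}: chromosome {g.chrom!r} not in layout")
            self._trees[g.chrom].addi(g.start, g.end, g.gene_id)

    def within(self, chrom: str, pos: int, half_width: int) -> set[str]:
        """Gene ids at interval distance <= half_width from (chrom, pos)."""
        if chrom not in self.layout:
            raise KeyError(f"chromosome {chrom!r} not in layout")
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        # distance(pos, [s, e)) <= w  <=>  [s, e) overlaps [pos - w, pos + w + 1)
        return {iv.data for iv in tree.overlap(pos - half_width, pos + half_width + 1)}


def map_snp(snp: SnpRecord, index: GeneIndex, tiers: TierConfig = TierConfig()) -> set[str]:
    """All genes at the smallest tier that captures any; empty if none do."""
    for w in tiers.half_widths:
        hit = index.within(snp.chrom, snp.pos, w)
        if hit:
            return hit
    return set()


def map_snp_detailed(
    snp: SnpRecord, index: GeneIndex, tiers: TierConfig = TierConfig()
) -> list[tuple[str, int, int]]:
    """Like :func:`map_snp` but returns (gene_id, tier_bp, distance_bp) rows."""
    by_id = {g.gene_id: g for g in index.genes}
    for w in tiers.half_widths:
        hit = index.within(snp.chrom, snp.pos, w)
        if hit:
            return sorted(
                (gid, w, interval_distance(snp.pos, by_id[gid].start, by_id[gid].end))
                for gid in hit
            )
    return []


def map_snps(
    snps: Iterable[SnpRecord], index: GeneIndex, tiers: TierConfig = TierConfig()
) -> tuple[set[str], dict[str, set[str]]]:
    """Map many SNPs; returns the deduplicated union and the per-SNP sets."""
    per_snp: dict[str, set[str]] = {}
    union: set[str] = set()
    for snp in snps:
        genes = map_snp(snp, index, tiers)
        per_snp[snp.snp_id] = genes
        union |= genes
    return union, per_snp


def map_snp_bruteforce(
    snp: SnpRecord,
    genes: Sequence[GeneRecord],
    layout: GenomeLayout,
    tiers: TierConfig = TierConfig(),
) -> set[str]:
    """Exhaustive-scan twin of :func:`map_snp` (test oracle)."""
    if snp.chrom not in layout:
        raise KeyError(f"chromosome {snp.chrom!r} not in layout")
    for w in tiers.half_widths:
        hit = {
            g.gene_id
            for g in genes
            if g.chrom == snp.chrom and interval_distance(snp.pos, g.start, g.end) <= w
        }
        if hit:
            return hit
    return set()
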