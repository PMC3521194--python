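"""miRNA-of-interest construction and target gene set assembly.

The miRNAs of interest start as a list in a source species (here, miRNAs
downregulated in a mouse model) and are carried to the study species
through an ortholog table. Genes then qualify as targets when enough of
those miRNAs interact with them with enough experimental (CLIP-seq)
support.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from typing import Iterable

from .model import MirnaInteraction, OrthologPair, TargetSet


def map_orthologs(
    source_mirnas: Iterable[str], pairs: Iterable[OrthologPair]
) -> tuple[set[str], set[str]]:
    """Map source-species miRNAs to study-species orthologs.

    Mapping is many-to-many: every target of any listed source enters the
    mapped set. Returns ``(mapped, unmapped)`` so callers can report
    ortholog coverage; missing mappings are not an error.
    """
    sources = set(source_mirnas)
    by_source: dict[str, set[str]] = defaultdict(set)
    for p in pairs:
        by_source[p.source_mirna].add(p.target_mirna)
    mapped: set[str] = set()
    unmapped: set[str] = set()
    for s in sources:
        if by_source.get(s):
            mapped |= by_source[s]
        else:
            unmapped.add(s)
    return mapped, unmapped


def _qualifying_mirna_counts(
    interactions: Iterable[MirnaInteraction], mirnas: set[str], min_support: int
) -> Counter:
    """Per gene, the number of distinct miRNAs of interest whose
    interaction has support >= min_support."""
    per_gene: dict[str, set[str]] = defaultdict(set)
    for it in interactions:
        if it.mirna_id in mirnas and it.support >= min_support:
            per_gene[it.gene_id].add(it.mirna_id)
    return Counter({g: len(ms) for g, ms in per_gene.items()})


def build_target_set(
    interactions: Iterable[MirnaInteraction],
    mirnas: Iterable[str],
    min_support: int = 2,
    min_mirnas: int = 2,
) -> TargetSet:
    """Genes targeted, with support >= *min_support* per interaction, by at
    least *min_mirnas* distinct miRNAs of interest.

    Both thresholds default to 2: interactions are required to be seen in
    two or more CLIP-seq experiments, and a gene must be a target of two
    or more of the miRNAs of interest.
    """
    if min_support < 1 or min_mirnas < 1:
        raise ValueError("min_support and min_mirnas must be >= 1")
    mirna_set = set(mirnas)
    if not mirna_set:
        raise ValueError("empty miRNA set: target query is meaningless")
    counts = _qualifying_mirna_counts(interactions, mirna_set, min_support)
    genes = frozenset(g for g, k in counts.items() if k >= min_mirnas)
    return TargetSet(genes, min_support, min_mirnas, frozenset(mirna_set))


def interaction_count_histogram(
    interactions: Iterable[MirnaInteraction],
    mirnas: Iterable[str],
    min_support: int = 2,
) -> dict[int, int]:
    """Histogram k -> number of genes interacting with exactly k distinct
    miRNAs of interest (support-filtered). Genes with no qualifying
    interaction do not appear; the counts sum to the number of genes with
    at least one."""
    mirna_set = set(mirnas)
    if not mirna_set:
        raise ValueError("empty miRNA set: histogram is meaningless")
    counts = _qualifying_mirna_counts(interactions, mirna_set, min_support)
    hist: Counter = Counter(counts.values())
    return dict(sorted(hist.items()))
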