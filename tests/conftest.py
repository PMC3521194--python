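import pytest

from mirshift.model import GeneRecord, GenomeLayout, MirnaInteraction


@pytest.fixture
def layout() -> GenomeLayout:
    return GenomeLayout((("chr1", 5_000_000), ("chr2", 3_000_000)))


@pytest.fixture
def small_genes(layout) -> list[GeneRecord]:
    return [
        GeneRecord("GENE_A", "chr1", 100_000, 110_000, "+"),
        GeneRecord("GENE_B", "chr1", 600_000, 610_000, "-"),
        GeneRecord("GENE_C", "chr2", 50_000, 60_000, "+"),
    ]


# Printed per-gene distinct-miRNA counts of the reference CLIP-seq
# catalogue: (k or k-range, number of genes). The 6-10 and >10 ranges are
# realised by a fixed deterministic within-range split.
REFERENCE_HISTOGRAM_ROWS = [
    (1, 1047),
    (2, 689),
    (3, 395),
    (4, 235),
    (5, 169),
    ("6-10", 281),
    (">10", 44),
]


def reference_interactions() -> tuple[list[MirnaInteraction], list[str]]:
    """A synthetic interaction table realising the printed per-gene
    distinct-miRNA count distribution exactly (support fixed at 2)."""
    per_k: dict[int, int] = {}
    for k, n in REFERENCE_HISTOGRAM_ROWS:
        if k == "6-10":
            for i, kk in enumerate(range(6, 11)):
                per_k[kk] = n // 5 + (1 if i < n % 5 else 0)
        elif k == ">10":
            # spread over 11..34 (the printed maximum), cycling
            for j in range(n):
                kk = 11 + j % 24
                per_k[kk] = per_k.get(kk, 0) + 1
        else:
            per_k[k] = n
    mirnas = [f"hsa-ref-miR-{i + 1}" for i in range(40)]
    interactions = []
    gene_no = 0
    for k in sorted(per_k):
        for _ in range(per_k[k]):
            gid = f"RG{gene_no:04d}"
            gene_no += 1
            for j in range(k):
                interactions.append(MirnaInteraction(mirnas[j], gid, 2))
    return interactions, mirnas
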