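"""Domain types shared by the whole pipeline.

Coordinate convention: all coordinates are 0-based, half-open (BED style).
Gene intervals are ``[start, end)``; SNPs are 0-based point coordinates.
Chromosome order is whatever order the genome layout lists them in — it is
never inferred by sorting names — and that order defines the genome-wide
concatenation used by the circular-shift null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "GenomeLayout",
    "GeneRecord",
    "SnpRecord",
    "SnpArray",
    "AssociationTable",
    "MirnaInteraction",
    "OrthologPair",
    "SelectionMask",
    "TierConfig",
    "TargetSet",
    "EnrichmentResult",
]


class ValidationError(ValueError):
    """Raised when a table violates a model invariant."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths; the substrate of genome order.

    The listed order is authoritative: it defines how chromosomes are laid
    end-to-end to form the single SNP array the permutation test rotates.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names in layout")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "_index", {n: i for i, (n, _) in enumerate(self.chromosomes)})
        object.__setattr__(self, "_length", {n: l for n, l in self.chromosomes})

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._index  # type: ignore[attr-defined]

    def rank(self, chrom: str) -> int:
        """Position of *chrom* in the genome concatenation order."""
        return self._index[chrom]  # type: ignore[attr-defined]

    def length(self, chrom: str) -> int:
        return self._length[chrom]  # type: ignore[attr-defined]

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive
    strand: str = "unknown"  # stored but ignored by all computations

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"gene {self.gene_id!r}: require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "unknown"):
            raise ValidationError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class SnpRecord:
    snp_id: str
    chrom: str
    pos: int  # 0-based point coordinate

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValidationError(f"SNP {self.snp_id!r}: negative position {self.pos}")


class SnpArray:
    """The genome-ordered SNP vector.

    Backed by flat numpy arrays for speed at array sizes of ~2x10^5; the
    integer index of a SNP in this order is its genome-wide rank, the
    quantity the circular shift rotates.
    """

    def __init__(self, records: Sequence[SnpRecord], layout: GenomeLayout):
        ids = [r.snp_id for r in records]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate snp_id in SNP array")
        for r in records:
            if r.chrom not in layout:
                raise ValidationError(f"SNP {r.snp_id!r}: chromosome {r.chrom!r} not in layout")
            if r.pos >= layout.length(r.chrom):
                raise ValidationError(
                    f"SNP {r.snp_id!r}: position {r.pos} beyond {r.chrom} length {layout.length(r.chrom)}"
                )
        order = sorted(range(len(records)), key=lambda i: (layout.rank(records[i].chrom), records[i].pos))
        key_pairs = [(records[i].chrom, records[i].pos) for i in order]
        if len(set(key_pairs)) != len(key_pairs):
            dup = [k for k in key_pairs if key_pairs.count(k) > 1][0]
            raise ValidationError(f"duplicate SNP position {dup}")
        self.layout = layout
        self.snp_ids = np.array([records[i].snp_id for i in order], dtype=object)
        self.chroms = np.array([records[i].chrom for i in order], dtype=object)
        self.positions = np.array([records[i].pos for i in order], dtype=np.int64)
        self._id_index = {s: i for i, s in enumerate(self.snp_ids)}

    @classmethod
    def from_arrays(
        cls, snp_ids: Sequence[str], chroms: Sequence[str], positions: Sequence[int], layout: GenomeLayout
    ) -> "SnpArray":
        """Vectorised constructor; same invariants as the record path."""
        obj = cls.__new__(cls)
        ids = np.asarray(snp_ids, dtype=object)
        ch = np.asarray(chroms, dtype=object)
        pos = np.asarray(positions, dtype=np.int64)
        if len(np.unique(ids)) != len(ids):
            raise ValidationError("duplicate snp_id in SNP array")
        ranks = np.array([layout.rank(c) if c in layout else -1 for c in ch])
        if (ranks < 0).any():
            bad = ch[ranks < 0][0]
            raise ValidationError(f"chromosome {bad!r} not in layout")
        lengths = np.array([layout.length(c) for c in ch])
        if (pos < 0).any() or (pos >= lengths).any():
            raise ValidationError("SNP position outside chromosome bounds")
        order = np.lexsort((pos, ranks))
        ranks, pos, ids, ch = ranks[order], pos[order], ids[order], ch[order]
        same = (ranks[1:] == ranks[:-1]) & (pos[1:] == pos[:-1])
        if same.any():
            i = int(np.flatnonzero(same)[0])
            raise ValidationError(f"duplicate SNP position ({ch[i]}, {pos[i]})")
        obj.layout = layout
        obj.snp_ids = ids
        obj.chroms = ch
        obj.positions = pos
        obj._id_index = {s: i for i, s in enumerate(ids)}
        return obj

    def __len__(self) -> int:
        return len(self.snp_ids)

    def __iter__(self) -> Iterator[SnpRecord]:
        for s, c, p in zip(self.snp_ids, self.chroms, self.positions):
            yield SnpRecord(str(s), str(c), int(p))

    def record(self, index: int) -> SnpRecord:
        return SnpRecord(str(self.snp_ids[index]), str(self.chroms[index]), int(self.positions[index]))

    def index_of(self, snp_id: str) -> int:
        return self._id_index[snp_id]


class AssociationTable:
    """Per-SNP prior and posterior probabilities of association.

    The prior is typically shared by every SNP (the study's prior on any
    one SNP being associated); per-SNP priors are permitted and the
    selection step then offers a posterior/prior ranking.
    """

    def __init__(self, snp_ids: Sequence[str], priors: Sequence[float], posteriors: Sequence[float]):
        self.snp_ids = np.asarray(snp_ids, dtype=object)
        self.priors = np.asarray(priors, dtype=np.float64)
        self.posteriors = np.asarray(posteriors, dtype=np.float64)
        if not (len(self.snp_ids) == len(self.priors) == len(self.posteriors)):
            raise ValidationError("association table columns have unequal lengths")
        if len(np.unique(self.snp_ids)) != len(self.snp_ids):
            raise ValidationError("duplicate snp_id in association table")
        if ((self.priors <= 0) | (self.priors >= 1)).any():
            raise ValidationError("priors must lie strictly inside (0, 1)")
        if ((self.posteriors < 0) | (self.posteriors > 1)).any():
            raise ValidationError("posteriors must lie in [0, 1]")
        self._id_index = {s: i for i, s in enumerate(self.snp_ids)}

    def __len__(self) -> int:
        return len(self.snp_ids)

    def aligned_to(self, array: SnpArray) -> tuple[np.ndarray, np.ndarray]:
        """(priors, posteriors) reordered to the genome order of *array*.

        Every SNP of the array must be present in the table.
        """
        try:
            idx = np.array([self._id_index[s] for s in array.snp_ids])
        except KeyError as exc:
            raise ValidationError(f"SNP {exc.args[0]!r} missing from association table") from exc
        return self.priors[idx], self.posteriors[idx]


@dataclass(frozen=True)
class MirnaInteraction:
    """One miRNA–gene interaction with its CLIP-seq experiment count."""

    mirna_id: str
    gene_id: str
    support: int

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValidationError(
                f"interaction ({self.mirna_id}, {self.gene_id}): support {self.support} < 1"
            )


@dataclass(frozen=True)
class OrthologPair:
    source_mirna: str
    target_mirna: str


@dataclass
class SelectionMask:
    """Boolean pattern of selected SNPs over a companion SnpArray."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 1:
            raise ValidationError("selection mask must be one-dimensional")

    def __len__(self) -> int:
        return len(self.bits)

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())

    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.bits)


@dataclass(frozen=True)
class TierConfig:
    """Expanding half-widths of the density-adaptive search windows.

    The default ladder 25 kb -> 250 kb -> 500 kb -> 1 Mb stops at the first
    non-empty tier, so gene-poor regions are searched further out while
    gene-dense regions contribute only nearby genes.
    """

    half_widths: tuple[int, ...] = (25_000, 250_000, 500_000, 1_000_000)

    def __post_init__(self) -> None:
        if not self.half_widths:
            raise ValidationError("tier list must be non-empty")
        if any(w <= 0 for w in self.half_widths):
            raise ValidationError("tier half-widths must be positive")
        if any(b <= a for a, b in zip(self.half_widths, self.half_widths[1:])):
            raise ValidationError("tier half-widths must be strictly increasing")


@dataclass(frozen=True)
class TargetSet:
    """Genes supported as targets of enough of the miRNAs of interest."""

    gene_ids: frozenset[str]
    min_support: int
    min_mirnas: int
    mirnas_used: frozenset[str]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class EnrichmentResult:
    """Observed statistic, circular-shift null, and empirical p-value."""

    observed_fraction: float
    observed_gene_count: int
    observed_hit_count: int
    null_fractions: np.ndarray
    null_gene_counts: np.ndarray
    null_hit_counts: np.ndarray
    null_fraction_mean: float
    null_gene_count_mean: float
    null_gene_count_sd: float
    p_value: float
    n_sims: int
    seed: int | None
    offsets_used: np.ndarray
    offset_range: tuple[int, int] = (1, 0)  # inclusive range offsets were drawn from
    empty_observed: bool = False
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        """JSON-serialisable summary (full null vectors included)."""
        return {
            "observed_fraction": self.observed_fraction,
            "observed_gene_count": self.observed_gene_count,
            "observed_hit_count": self.observed_hit_count,
            "null_fraction_mean": self.null_fraction_mean,
            "null_gene_count_mean": self.null_gene_count_mean,
            "null_gene_count_sd": self.null_gene_count_sd,
            "p_value": self.p_value,
            "n_sims": self.n_sims,
            "seed": self.seed,
            "offset_range": list(self.offset_range),
            "empty_observed": self.empty_observed,
            "offsets_used": [int(o) for o in self.offsets_used],
            "null_fractions": [float(f) for f in self.null_fractions],
            "null_gene_counts": [int(g) for g in self.null_gene_counts],
            "null_hit_counts": [int(h) for h in self.null_hit_counts],
            "metadata": self.metadata,
        }
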