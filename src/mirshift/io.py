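"""Readers and writers for every table the pipeline touches.

All files are UTF-8, tab-separated, with ``#`` comment lines ignored.
Internal coordinates are 0-based half-open; 1-based inputs can be declared
with ``one_based=True``, which shifts starts/positions down by one on read
(end coordinates of 1-based inclusive intervals are already the half-open
end and are left alone).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

from .model import (
    AssociationTable,
    GeneRecord,
    GenomeLayout,
    MirnaInteraction,
    OrthologPair,
    SnpArray,
    ValidationError,
)

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """A malformed row; message names the file and 1-based line number."""


def _rows(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def _int(value: str, path, lineno: int, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: {what} {value!r} is not an integer") from None


def _float(value: str, path, lineno: int, what: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: {what} {value!r} is not a number") from None


def read_layout(path: str | Path) -> GenomeLayout:
    """TSV(chrom, length); row order fixes the genome concatenation order."""
    chroms: list[tuple[str, int]] = []
    for lineno, fields in _rows(path):
        if fields[0] == "chrom":  # optional header
            continue
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns (chrom, length)")
        chroms.append((fields[0], _int(fields[1], path, lineno, "length")))
    return GenomeLayout(tuple(chroms))


_GENE_HEADER = ("gene_id", "chrom", "start", "end", "strand")


def read_genes(path: str | Path, layout: GenomeLayout, one_based: bool = False) -> list[GeneRecord]:
    """Read a gene annotation as BED6 or a headered TSV.

    A first row starting with ``gene_id`` selects the TSV dialect
    (gene_id, chrom, start, end, strand); anything else is treated as BED,
    honouring the first six columns (chrom, start, end, name, score,
    strand). Rows on chromosomes absent from *layout* are dropped and the
    count logged.
    """
    genes: list[GeneRecord] = []
    dropped = 0
    seen: set[str] = set()
    tsv: bool | None = None
    for lineno, fields in _rows(path):
        if tsv is None:
            tsv = fields[0] == _GENE_HEADER[0]
            if tsv:
                if tuple(fields[:5]) != _GENE_HEADER:
                    raise ParseError(f"{path}:{lineno}: bad header, expected {list(_GENE_HEADER)}")
                continue
        if tsv:
            if len(fields) < 5:
                raise ParseError(f"{path}:{lineno}: expected 5 columns")
            gene_id, chrom, strand = fields[0], fields[1], fields[4]
            start = _int(fields[2], path, lineno, "start")
            end = _int(fields[3], path, lineno, "end")
        else:
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: BED gene rows need at least 4 columns")
            chrom, gene_id = fields[0], fields[3]
            start = _int(fields[1], path, lineno, "start")
            end = _int(fields[2], path, lineno, "end")
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "unknown"
        if one_based:
            start -= 1
        if strand not in ("+", "-"):
            strand = "unknown"
        if chrom not in layout:
            dropped += 1
            continue
        if start >= end:
            raise ValidationError(f"{path}:{lineno}: gene {gene_id!r} has start >= end")
        if end > layout.length(chrom):
            raise ValidationError(
                f"{path}:{lineno}: gene {gene_id!r} extends past {chrom} length {layout.length(chrom)}"
            )
        if gene_id in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        genes.append(GeneRecord(gene_id, chrom, start, end, strand))
    if dropped:
        log.info("read_genes(%s): dropped %d rows on chromosomes absent from layout", path, dropped)
    return genes


def write_genes(path: str | Path, genes: Iterable[GeneRecord]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tchrom\tstart\tend\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\n")


def read_snp_array(path: str | Path, layout: GenomeLayout, one_based: bool = False) -> SnpArray:
    """TSV(snp_id, chrom, pos) -> SnpArray sorted into genome order."""
    ids: list[str] = []
    chroms: list[str] = []
    positions: list[int] = []
    for lineno, fields in _rows(path):
        if fields[0] == "snp_id":
            continue
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected 3 columns (snp_id, chrom, pos)")
        ids.append(fields[0])
        chroms.append(fields[1])
        pos = _int(fields[2], path, lineno, "pos")
        positions.append(pos - 1 if one_based else pos)
    return SnpArray.from_arrays(ids, chroms, positions, layout)


def write_snp_array(path: str | Path, array: SnpArray) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("snp_id\tchrom\tpos\n")
        for s, c, p in zip(array.snp_ids, array.chroms, array.positions):
            fh.write(f"{s}\t{c}\t{p}\n")


def read_association(path: str | Path) -> AssociationTable:
    """TSV(snp_id, prior, posterior) -> AssociationTable."""
    ids: list[str] = []
    priors: list[float] = []
    posteriors: list[float] = []
    for lineno, fields in _rows(path):
        if fields[0] == "snp_id":
            continue
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected 3 columns (snp_id, prior, posterior)")
        ids.append(fields[0])
        priors.append(_float(fields[1], path, lineno, "prior"))
        posteriors.append(_float(fields[2], path, lineno, "posterior"))
    return AssociationTable(ids, priors, posteriors)


def write_association(path: str | Path, table: AssociationTable) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("snp_id\tprior\tposterior\n")
        for s, pr, po in zip(table.snp_ids, table.priors, table.posteriors):
            fh.write(f"{s}\t{float(pr)!r}\t{float(po)!r}\n")


def read_interactions(path: str | Path) -> list[MirnaInteraction]:
    """TSV(mirna_id, gene_id, support); duplicate pairs keep max support.

    Support counts the number of CLIP-seq experiments backing the
    interaction, so the maximum over duplicate rows is the conservative,
    idempotent aggregate.
    """
    best: dict[tuple[str, str], int] = {}
    order: list[tuple[str, str]] = []
    n_dup = 0
    for lineno, fields in _rows(path):
        if fields[0] == "mirna_id":
            continue
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected 3 columns (mirna_id, gene_id, support)")
        support = _int(fields[2], path, lineno, "support")
        if support < 1:
            raise ValidationError(f"{path}:{lineno}: support {support} < 1")
        key = (fields[0], fields[1])
        if key in best:
            n_dup += 1
            best[key] = max(best[key], support)
        else:
            best[key] = support
            order.append(key)
    if n_dup:
        log.info("read_interactions(%s): aggregated %d duplicate pairs by max support", path, n_dup)
    return [MirnaInteraction(m, g, best[(m, g)]) for m, g in order]


def write_interactions(path: str | Path, interactions: Iterable[MirnaInteraction]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mirna_id\tgene_id\tsupport\n")
        for it in interactions:
            fh.write(f"{it.mirna_id}\t{it.gene_id}\t{it.support}\n")


def read_orthologs(path: str | Path) -> list[OrthologPair]:
    """TSV(source_mirna, target_mirna); duplicate pairs collapsed."""
    pairs: list[OrthologPair] = []
    seen: set[tuple[str, str]] = set()
    for lineno, fields in _rows(path):
        if fields[0] == "source_mirna":
            continue
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns (source_mirna, target_mirna)")
        key = (fields[0], fields[1])
        if key in seen:
            continue
        seen.add(key)
        pairs.append(OrthologPair(*key))
    return pairs


def write_orthologs(path: str | Path, pairs: Iterable[OrthologPair]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source_mirna\ttarget_mirna\n")
        for p in pairs:
            fh.write(f"{p.source_mirna}\t{p.target_mirna}\n")


def write_layout(path: str | Path, layout: GenomeLayout) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("chrom\tlength\n")
        for name, length in layout.chromosomes:
            fh.write(f"{name}\t{length}\n")
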