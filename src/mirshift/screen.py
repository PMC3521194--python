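"""Evidence-direction classification and top-fraction SNP selection.

The association evidence for each SNP is a posterior probability that
moved up or down from a prior: a posterior above the prior is evidence
for association, below is evidence against, and a posterior equal to the
prior (within tolerance) means the data were uninformative for that SNP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import AssociationTable, SelectionMask, SnpArray

#: classification labels
FOR, AGAINST, UNINFORMATIVE = "for", "against", "uninformative"


def classify(prior: float, posterior: float, tol: float = 1e-12) -> str:
    """Direction of evidence for one SNP."""
    if not (0 <= prior <= 1 and 0 <= posterior <= 1):
        raise ValueError("prior and posterior must lie in [0, 1]")
    if abs(posterior - prior) <= tol:
        return UNINFORMATIVE
    return FOR if posterior > prior + tol else AGAINST


def classify_table(assoc: AssociationTable, tol: float = 1e-12) -> np.ndarray:
    """Vectorised :func:`classify` over a whole table; returns a label array."""
    diff = assoc.posteriors - assoc.priors
    labels = np.full(len(assoc), AGAINST, dtype=object)
    labels[np.abs(diff) <= tol] = UNINFORMATIVE
    labels[diff > tol] = FOR
    return labels


@dataclass(frozen=True)
class EvidenceSummary:
    n_total: int
    n_uninformative: int
    n_for: int
    n_against: int
    pct_for: int | None      # rounded over informative SNPs; None if none
    pct_against: int | None
    frac_for: float | None   # full precision
    frac_against: float | None


def summarize(assoc: AssociationTable, tol: float = 1e-12) -> EvidenceSummary:
    """Counts and informative-SNP percentages of evidence direction.

    Percentages are over informative SNPs only (total minus
    uninformative), reported rounded to the nearest integer alongside the
    full-precision fractions; with no informative SNPs they are None.
    """
    labels = classify_table(assoc, tol)
    n_total = len(labels)
    n_un = int(np.sum(labels == UNINFORMATIVE))
    n_for = int(np.sum(labels == FOR))
    n_against = n_total - n_un - n_for
    informative = n_total - n_un
    if informative == 0:
        return EvidenceSummary(n_total, n_un, n_for, n_against, None, None, None, None)
    frac_for = n_for / informative
    frac_against = n_against / informative
    return EvidenceSummary(
        n_total, n_un, n_for, n_against,
        round(100 * frac_for), round(100 * frac_against),
        frac_for, frac_against,
    )


def selection_count(n_for: int, fraction: float) -> int:
    """Number of SNPs selected from *n_for* positives: floor(fraction * n_for)."""
    return math.floor(fraction * n_for)


def select_top_fraction(
    assoc: AssociationTable,
    array: SnpArray,
    fraction: float = 0.005,
    rank_by: str = "posterior",
    tol: float = 1e-12,
) -> SelectionMask:
    """Mark the top *fraction* of evidence-for SNPs in a genome-order mask.

    SNPs classified "for" are ranked by posterior descending (or by the
    posterior/prior ratio with ``rank_by="ratio"``, the natural key when
    priors differ per SNP); ties are broken by genome order, earlier index
    first. The selection count is floor(fraction * n_for).
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    if rank_by not in ("posterior", "ratio"):
        raise ValueError(f"unknown rank_by {rank_by!r}")
    priors, posteriors = assoc.aligned_to(array)
    is_for = posteriors > priors + tol
    n_for = int(is_for.sum())
    if n_for == 0:
        raise ValueError("no SNPs with evidence for association; nothing to select")
    k = selection_count(n_for, fraction)
    if k == 0:
        raise ValueError(
            f"floor({fraction} * {n_for}) = 0 selected SNPs; raise the selection fraction"
        )
    key = posteriors if rank_by == "posterior" else posteriors / priors
    for_idx = np.flatnonzero(is_for)
    # stable sort on descending key => ties keep ascending genome order
    order = np.argsort(-key[for_idx], kind="stable")
    chosen = for_idx[order[:k]]
    bits = np.zeros(len(array), dtype=bool)
    bits[chosen] = True
    return SelectionMask(bits)
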