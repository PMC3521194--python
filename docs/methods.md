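# Methods

## Statistical model

Let the genotyping array define a single sequence of N SNPs, ordered by
laying the chromosomes end-to-end in the order the genome layout file
lists them and sorting by position within each chromosome. Association
evidence per SNP is a pair (prior π, posterior P) of probabilities of
association: P > π is evidence for, P < π evidence against, P = π (within
tolerance 1e−12) uninformative. Percent summaries are computed over
informative SNPs only.

The observed selection is the top `k = ⌊f · n_for⌋` evidence-for SNPs
(default f = 0.005) ranked by posterior descending; with a shared prior,
posterior order is evidence order. When priors differ per SNP a
posterior/prior ratio ranking is available (`rank_by="ratio"`). Ties are
broken by genome order, earlier index first, purely for determinism.

Each selected SNP maps to genes through the tier ladder
w ∈ {25 kb, 250 kb, 500 kb, 1 Mb}: the mapped set is all genes at
interval distance ≤ w for the smallest w capturing at least one gene;
an empty set if even 1 Mb captures none. Distance is from the SNP point
to the nearest edge of the gene body — 0 inside the gene, otherwise
`min(|pos − start|, |pos − (end−1)|)` — boundary inclusive, never
crossing a chromosome boundary. Whole-gene spans (not TSSs) are the
reference because the annotation consumed is gene-span shaped; the
inclusive boundary is an explicit dialect choice, not an inferred one.
Strand is stored but ignored: the mapping is a strand-agnostic physical
distance.

The test statistic is the target fraction: of the union of genes mapped
by the selected SNPs, the share belonging to the miRNA target set (genes
with ≥ `min_mirnas` = 2 distinct miRNAs of interest, each interaction
supported by ≥ `min_support` = 2 CLIP-seq experiments). The two
thresholds are deliberately separate parameters: requiring experimental
replication per interaction and requiring multiple miRNAs per gene are
different filters, even though informal descriptions sometimes conflate
them.

### Circular-shift null

Each of `n_sims` (default 10,000) replicates draws an offset uniformly
from {1, …, N−1}, rotates the boolean selection pattern by it (bit i →
bit (i+offset) mod N), and re-runs the full tiered mapping on the rotated
selection. Offsets 0 and N are identity rotations and are excluded so the
null never contains the observed configuration by construction; offsets
are sampled with replacement (independent replicates). Rotation preserves
the run structure of the selection (clustering of top signals in LD) and
confronts every replicate with the true gene-density landscape, which is
the point of the scheme — a hypergeometric or gene-label permutation null
would erase exactly the artefacts this design keeps.

The p-value is the add-one estimator `p = (1 + #{null ≥ obs})/(n_sims+1)`
with ties counted as extreme; it can never report 0. Fraction comparisons
are performed on exact rationals (cross-multiplication of hit/gene
counts) so that, e.g., 2/12 and 1/6 tie exactly regardless of floating
point. An empty mapped set has fraction 0 and is flagged rather than
fatal, since rotated selections can legitimately map nowhere.

Determinism: given a seed, `offsets_used` fully determines the null, and
results are bit-identical across runs. Per-SNP gene sets are memoised
across replicates — the mapping of an array index is a fixed property of
the annotation, so this is a pure optimisation with no statistical
effect.

## Synthetic studies

`mirshift.simulate` generates complete studies as pure functions of
(config, seed); per-generator streams are `default_rng([seed, k])` with a
fixed component index k, so each table can be regenerated independently.

What the generator emulates, and the defaults:

| parameter | default | rationale |
|---|---|---|
| `n_chrom × chrom_length` | 22 × 130 Mb | genome of ~2.9 Gb in numbered chromosomes |
| `n_genes` | 20,000 | RefSeq-scale gene count |
| `gene_length_law` | log-normal(10.0, 1.1) on bp | median ~22 kb gene span |
| `density_blocks` | (4×, 25%), (1×, 50%), (0.25×, 25%) | gene-rich and gene-poor regions so every tier of the ladder is exercised |
| `n_snps` | 221,996 | the array size after QC in the study emulated |
| `n_mirnas` | 65 | the source-species miRNA list size |
| `target_gene_frac` | 0.143 | 2,860 catalogue genes over 20,000 |
| `mirna_count_law` | 0.37 | zero-truncated geometric: P(K=1) ≈ 1047/2860, matching the catalogue's decay |
| `support_law` | 0.7 | P(interaction support ≥ 2); support is 1 + Geometric(1/2) when high |
| `prior` | 0.0004 | the emulated study's prior |
| `frac_uninformative` | 9191/221996 | its uninformative share |
| `frac_positive` | 0.07 | its 7% evidence-for share among informative SNPs |
| `max_posterior` | 0.017 | its maximum posterior |
| `boost`, `boost_window`, `n_risk_genes` | 1, 25 kb, 20 | planted-signal controls |

Positive-SNP posteriors are drawn log-uniform on (prior, max_posterior].
Magnitudes are arbitrary ranks — only order matters to selection — but a
bounded law makes the planted odds boost (×`boost` on posterior odds of
SNPs within `boost_window` of a risk gene) dominate the ranking, so the
planted signal must survive the actual tiered mapping end-to-end rather
than being injected by relabeling genes. With `risk_gene_source="any"`
the boost is target-blind and with `boost=1` it is skipped entirely,
giving a null study identical across regimes.

Not emulated: LD between SNPs (positions are uniform; a `clustered` SNP
layout exists as a crude spacing stand-in), pedigree structure, the
evidence measure's actual sampling distribution, and sequence content of
any kind. Passing tests therefore demonstrate the correctness and
calibration of the *pipeline* under its stated assumptions, not the
biological conclusions of any real dataset.

## Scaled study conditions used in tests

The statistical suites run on a 4 × 25 Mb genome with 1,300 genes and
20,000 SNPs (all shape fractions at their defaults), 500 permutation
replicates per study. At this size the 0.5% selection keeps ~6 SNPs and a
study completes in well under a second, so 200 null studies (type-I
calibration against the exact binomial 95% interval around 0.05) and a
20-seed × {1, 10, 50} boost grid (power monotonicity) are practical; the
gene density (1 per ~77 kb) keeps the mapped-gene unions large enough
that the discrete target-fraction statistic has usable resolution.

## Numerical and degenerate-input choices

- `⌊f · n_for⌋` for the selection count (floor, not round), the only
  rounding consistent with a 0.5% selection of 14,705 positives being 73.
- Zero selected SNPs (`n_for = 0`, or k = 0) is an error naming the
  remedy; an empty miRNA-of-interest set is an error (meaningless query).
- Duplicate interaction rows aggregate by max support: support counts
  experiments, so max is conservative and idempotent.
- Ortholog mapping is many-to-many; unmapped sources are reported, not
  fatal.
- Annotations must be pre-collapsed to one row per gene identifier;
  transcript-isoform collapsing is upstream of this package.
- Coordinates are 0-based half-open internally; 1-based inputs are
  declared at the boundary (`one_based`), never guessed.
- Interval lookups use an interval tree; a brute-force twin
  (`map_snp_bruteforce`) exists solely as the oracle in equivalence
  tests and is never used by the pipeline.

## Known limitations

- No LD-aware window expansion, eQTL integration, or regulatory-element
  annotation; mapping is purely positional.
- The circular shift assumes the SNP array order is fixed and exchange-
  able under rotation; arrays with gross chromosome-scale artefacts would
  weaken that exchangeability.
- With few selected SNPs the target-fraction statistic is coarse and the
  add-one, ties-as-extreme p-value is conservative at small `n_sims`.

## Worked-example snippet

The README's printed block comes from:

```python
e = res.enrichment
print(f"selected SNPs        : {res.mask.popcount}")
print(f"mapped genes         : {e.observed_gene_count}")
print(f"target-set hits      : {e.observed_hit_count} ({100*e.observed_fraction:.1f}%)")
print(f"null fraction mean   : {100*e.null_fraction_mean:.1f}%")
print(f"null gene count      : {e.null_gene_count_mean:.1f} (s.d. {e.null_gene_count_sd:.1f})")
print(f"empirical p-value    : {e.p_value:.4f}")
```
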