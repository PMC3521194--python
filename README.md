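# mirshift

Circular-shift enrichment testing of miRNA-target genes near the top
signals of a GWAS, with density-adaptive SNP-to-gene mapping and a
synthetic study generator.

## The problem

In 22q11.2 deletion syndrome, haploinsufficiency of *DGCR8* globally
dampens miRNA processing, and one hypothesis for the syndrome's high
schizophrenia risk is that the damaged miRNA buffer unmasks regulatory
variants near genes those miRNAs normally control. Under that hypothesis,
the strongest association signals in a genotyping-array GWAS of deletion
carriers should sit unusually close to genes that are experimental
(CLIP-seq) targets of the miRNAs depleted by *DGCR8* haploinsufficiency.

`mirshift` implements that test as a reusable pipeline:

1. **Evidence screen** — each SNP carries a prior and posterior
   probability of association (a PPL-style evidence measure); SNPs with
   posterior > prior are "evidence for", and the top fraction *f*
   (default 0.5%, count `⌊f · n_for⌋`) of them, ranked by posterior, are
   selected.
2. **Density-adaptive mapping** — each selected SNP is mapped to all
   genes within an expanding window ladder (25 kb → 250 kb → 500 kb →
   1 Mb half-widths), stopping at the first non-empty tier, so gene-poor
   regions are searched further out while gene-dense regions contribute
   only nearby candidates.
3. **Target set** — source-species miRNAs of interest are carried through
   an ortholog table; a gene is a target when ≥ 2 of those miRNAs
   interact with it, each interaction supported by ≥ 2 CLIP-seq
   experiments (both thresholds configurable).
4. **Circular-shift null** — the test statistic is the fraction of mapped
   genes in the target set. The null rotates the boolean selection
   pattern along the genome-ordered SNP array (all chromosomes laid
   end-to-end; offsets uniform on {1, …, N−1}, wrapping at the end) and
   re-runs the full tiered mapping per replicate. Rotation preserves both
   the clustering of the selected SNPs (LD) and the gene-density
   landscape, which a label permutation would destroy. The empirical
   p-value uses the add-one estimator
   `p = (1 + #{null ≥ observed}) / (n_sims + 1)`, ties counted as extreme.

Because the real inputs (array genotypes, PPL outputs, the CLIP-seq
catalogue) are not redistributable, the package ships a generator of
complete synthetic studies — genome, annotation, SNP array, interaction
and ortholog tables, association scores — with planted enrichment
optional, so every stage runs and is testable with no external download.

## Worked example

A scaled synthetic study (4 × 25 Mb genome, 1,300 genes, 20,000 SNPs)
with enrichment planted near miRNA-target genes (posterior odds of SNPs
within 25 kb of 20 target genes multiplied by 50):

```python
from mirshift import run_pipeline
from mirshift.simulate import SimConfig, generate_study_data

cfg = SimConfig(seed=7, n_chrom=4, chrom_length=25_000_000, n_genes=1_300,
                n_snps=20_000, boost=50.0, risk_gene_source="target")
study = generate_study_data(cfg)
res = run_pipeline(study.layout, study.genes, study.array, study.association,
                   study.interactions, study.orthologs, study.source_mirnas,
                   n_sims=2_000, seed=11)
```

prints (via the snippet in `docs/methods.md`):

```
selected SNPs        : 8
mapped genes         : 24
target-set hits      : 8 (33.3%)
null fraction mean   : 6.4%
null gene count      : 16.4 (s.d. 7.1)
empirical p-value    : 0.0025
```

33% of the genes near the top SNPs are miRNA targets versus 6.4% for a
randomly rotated selection — the planted signal is recovered at
p ≈ 0.0025. With `boost=1.0, risk_gene_source="any"` (a null study) the
observed fraction is typical of the rotated ones and p is uniform.

The same analysis is available from the shell:

```sh
mirshift run-all --config config.yaml --seed 7 --out results/
```

writing `result.json` (statistic, null vectors, p-value, provenance),
`selection.tsv` and `replicates.tsv`. `mirshift simulate|map|summarize`
expose the individual stages; all tables are plain TSV.

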