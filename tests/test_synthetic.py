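import json

import numpy as np
import pytest

from mirshift.screen import classify_table, select_top_fraction
from mirshift.simulate import (
    SimConfig,
    config_from_manifest,
    generate_association,
    generate_genome,
    generate_interactions,
    generate_snp_array,
    generate_study,
    generate_study_data,
)
from mirshift.target_db import build_target_set, interaction_count_histogram, map_orthologs

SMALL = dict(n_chrom=2, chrom_length=5_000_000, n_genes=200, n_snps=2_000)


def small_cfg(**kw):
    return SimConfig(**{**SMALL, **kw})


class TestGenerateGenome:
    def test_same_seed_identical_annotation(self):
        cfg = small_cfg(seed=5)
        l1, g1 = generate_genome(cfg)
        l2, g2 = generate_genome(cfg)
        assert l1 == l2 and g1 == g2

    def test_no_genes(self):
        layout, genes = generate_genome(small_cfg(n_genes=0))
        assert genes == [] and len(layout.names) == 2

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            generate_genome(SimConfig(n_chrom=1, chrom_length=1_000, n_genes=100,
                                      gene_length_law=(8.0, 1.0), n_snps=10))

    def test_density_blocks_concentrate_genes(self):
        """Blocks (10x, 20%) vs (0.5x, 80%): expected share in the first
        fifth is 2/2.4 ~ 83%; assert >= 60% pooled over 20 seeds."""
        blocks = ((10.0, 0.2), (0.5, 0.8))
        in_first = total = 0
        for seed in range(20):
            cfg = small_cfg(seed=seed, density_blocks=blocks, n_genes=150)
            layout, genes = generate_genome(cfg)
            cut = 0.2 * layout.total_length
            offsets = {name: sum(layout.length(n) for n in layout.names[:i])
                       for i, name in enumerate(layout.names)}
            in_first += sum(offsets[g.chrom] + g.start < cut for g in genes)
            total += len(genes)
        assert in_first / total >= 0.60

    def test_genes_respect_chromosome_bounds(self):
        layout, genes = generate_genome(small_cfg(seed=3))
        for g in genes:
            assert 0 <= g.start < g.end <= layout.length(g.chrom)


class TestGenerateSnpArray:
    def test_positions_unique_and_genome_ordered(self):
        cfg = small_cfg(seed=2)
        layout, _ = generate_genome(cfg)
        arr = generate_snp_array(cfg, layout)
        assert len(arr) == cfg.n_snps
        keys = [(layout.rank(c), p) for c, p in zip(arr.chroms, arr.positions)]
        assert keys == sorted(keys) and len(set(keys)) == len(keys)

    def test_clustered_layout_also_valid(self):
        cfg = small_cfg(seed=2, snp_layout="clustered")
        layout, _ = generate_genome(cfg)
        arr = generate_snp_array(cfg, layout)
        assert len(arr) == cfg.n_snps


class TestGenerateInteractions:
    def test_degenerate_count_law_gives_single_mirna_targets(self):
        cfg = small_cfg(seed=1, mirna_count_law=1.0)
        _, genes = generate_genome(cfg)
        interactions, pairs, sources = generate_interactions(cfg, genes)
        per_gene = {}
        for it in interactions:
            per_gene.setdefault(it.gene_id, set()).add(it.mirna_id)
        assert all(len(ms) == 1 for ms in per_gene.values())
        mapped, _ = map_orthologs(sources, pairs)
        assert len(build_target_set(interactions, mapped, min_support=1, min_mirnas=2)) == 0

    def test_mirna_count_histogram_decays(self):
        """With geometric parameter >= 0.5 the pooled distinct-miRNA
        histogram is non-increasing in k."""
        pooled = {}
        for seed in range(20):
            cfg = small_cfg(seed=seed, mirna_count_law=0.5)
            _, genes = generate_genome(cfg)
            interactions, pairs, sources = generate_interactions(cfg, genes)
            mapped, _ = map_orthologs(sources, pairs)
            for k, n in interaction_count_histogram(interactions, mapped, min_support=1).items():
                pooled[k] = pooled.get(k, 0) + n
        ks = sorted(pooled)
        assert all(pooled[a] >= pooled[b] for a, b in zip(ks, ks[1:]))

    def test_ortholog_table_is_one_to_one(self):
        cfg = small_cfg()
        _, genes = generate_genome(cfg)
        _, pairs, sources = generate_interactions(cfg, genes)
        assert len(pairs) == cfg.n_mirnas == len(sources)
        assert len({p.source_mirna for p in pairs}) == len({p.target_mirna for p in pairs})

    def test_same_seed_identical_tables(self):
        cfg = small_cfg(seed=9)
        _, genes = generate_genome(cfg)
        assert generate_interactions(cfg, genes) == generate_interactions(cfg, genes)


class TestGenerateAssociation:
    def test_positive_fraction_converges(self):
        cfg = SimConfig(seed=4, n_chrom=2, chrom_length=20_000_000, n_genes=400, n_snps=10_000)
        study = generate_study_data(cfg)
        labels = classify_table(study.association)
        informative = labels != "uninformative"
        frac = np.mean(labels[informative] == "for")
        # binomial 4-sigma band around frac_positive at ~9,600 informative SNPs
        se = np.sqrt(cfg.frac_positive * (1 - cfg.frac_positive) / informative.sum())
        assert abs(frac - cfg.frac_positive) < 4 * se

    def test_boost_one_makes_regimes_identical(self):
        a = generate_study_data(small_cfg(seed=6, boost=1.0, risk_gene_source="any"))
        b = generate_study_data(small_cfg(seed=6, boost=1.0, risk_gene_source="target"))
        assert np.array_equal(a.association.posteriors, b.association.posteriors)

    def test_no_positives_breaks_selection_downstream(self):
        study = generate_study_data(small_cfg(seed=7, frac_positive=0.0, boost=1.0))
        with pytest.raises(ValueError):
            select_top_fraction(study.association, study.array, 0.005)

    def test_posteriors_bounded_by_ceiling_without_boost(self):
        study = generate_study_data(small_cfg(seed=8, boost=1.0))
        assert study.association.posteriors.max() <= study.cfg.max_posterior + 1e-15

    def test_target_source_with_empty_target_set_rejected(self):
        cfg = small_cfg(seed=1, mirna_count_law=1.0, boost=10.0, risk_gene_source="target")
        with pytest.raises(ValueError, match="target set is empty"):
            generate_study_data(cfg)

    def test_planted_boost_raises_posteriors_near_risk_genes(self):
        null = generate_study_data(small_cfg(seed=11, boost=1.0))
        planted = generate_study_data(
            small_cfg(seed=11, boost=50.0, risk_gene_source="target", n_risk_genes=10)
        )
        # the boost only moves posteriors upward, and moves at least some
        changed = planted.association.posteriors != null.association.posteriors
        assert changed.any()
        assert np.all(
            planted.association.posteriors[changed] > null.association.posteriors[changed]
        )


class TestGenerateStudy:
    def test_manifest_regeneration_is_bit_identical(self, tmp_path):
        cfg = small_cfg(seed=13)
        sums1 = generate_study(cfg, tmp_path / "a")
        cfg2 = config_from_manifest(tmp_path / "a" / "manifest.json")
        sums2 = generate_study(cfg2, tmp_path / "b")
        assert sums1 == sums2
        assert sorted(sums1) == sorted(
            ["layout.tsv", "genes.tsv", "snps.tsv", "association.tsv",
             "interactions.tsv", "orthologs.tsv"]
        )
        manifest = json.loads((tmp_path / "a" / "manifest.json").read_text())
        assert manifest["config"]["seed"] == 13

    def test_written_tables_pass_model_validation_on_reread(self, tmp_path):
        from mirshift import io as mio

        generate_study(small_cfg(seed=14), tmp_path)
        layout = mio.read_layout(tmp_path / "layout.tsv")
        genes = mio.read_genes(tmp_path / "genes.tsv", layout)
        arr = mio.read_snp_array(tmp_path / "snps.tsv", layout)
        assoc = mio.read_association(tmp_path / "association.tsv")
        mio.read_interactions(tmp_path / "interactions.tsv")
        mio.read_orthologs(tmp_path / "orthologs.tsv")
        assert len(genes) == 200 and len(arr) == 2_000 and len(assoc) == 2_000
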