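import numpy as np
import pytest
from scipy import stats

from trnacodon.codon_model import SENSE_CODONS, codon_families, count_codons, rscu
from trnacodon.synthetic_data import (
    SimConfig,
    default_anticodon_set,
    simulate_genes,
    simulate_reads,
    simulate_trna_pool,
)


class TestConfig:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(beta=-1.0)
        with pytest.raises(ValueError):
            SimConfig(gc_bias=1.5)
        with pytest.raises(ValueError):
            SimConfig(copy_link=2.0)
        with pytest.raises(ValueError):
            SimConfig(read_length=100)


class TestPool:
    def test_determinism(self):
        cfg = SimConfig(seed=42)
        t1, p1 = simulate_trna_pool(cfg)
        t2, p2 = simulate_trna_pool(cfg)
        assert [(a.id, a.sequence, a.copy_number, a.methylation_sites) for a in t1] == [
            (a.id, a.sequence, a.copy_number, a.methylation_sites) for a in t2
        ]
        assert p1.values == p2.values

    def test_copy_link_one_preserves_ranks(self):
        cfg = SimConfig(seed=3, copy_link=1.0)
        trnas, pool = simulate_trna_pool(cfg)
        abund = np.array([pool.values[t.anticodon] for t in trnas])
        copies = np.array([t.copy_number for t in trnas])
        order = np.argsort(abund)
        assert (np.diff(copies[order]) >= 0).all()  # rank-preserving discretization

    def test_copy_link_zero_decorrelates(self):
        rhos = []
        for seed in range(40):
            cfg = SimConfig(seed=seed, copy_link=0.0)
            trnas, pool = simulate_trna_pool(cfg)
            abund = [pool.values[t.anticodon] for t in trnas]
            copies = [t.copy_number for t in trnas]
            rhos.append(stats.spearmanr(abund, copies).statistic)
        assert abs(np.mean(rhos)) < 0.15

    def test_every_sense_codon_readable(self):
        assert len(default_anticodon_set()) >= 21
        trnas, pool = simulate_trna_pool(SimConfig(seed=0))
        from trnacodon.trna_quant import codon_availability

        avail, _ = codon_availability(pool, trnas)
        assert all(avail[c] > 0 for c in SENSE_CODONS)


class TestGenes:
    def test_determinism(self):
        cfg = SimConfig(seed=9, n_genes=50)
        trnas, pool = simulate_trna_pool(cfg)
        g1 = simulate_genes(cfg, trnas, pool)
        g2 = simulate_genes(cfg, trnas, pool)
        assert g1.cds == g2.cds
        assert g1.protein.equals(g2.protein)

    def test_cds_are_valid_orfs(self):
        cfg = SimConfig(seed=9, n_genes=20)
        trnas, pool = simulate_trna_pool(cfg)
        genes = simulate_genes(cfg, trnas, pool)
        for _gid, seq in genes.cds:
            assert len(seq) % 3 == 0
            assert seq.startswith("AUG") and seq.endswith("UAA")
            count_codons(seq)  # no internal stops

    def test_beta_zero_heg_leg_indistinguishable(self):
        """With no selection and symmetric mutation the HEG and LEG RSCU
        distributions should be statistically indistinguishable."""
        p_values = []
        for seed in range(20):
            cfg = SimConfig(seed=seed, beta=0.0, gc_bias=0.5, n_genes=120,
                            min_gene_codons=80, max_gene_codons=160)
            trnas, pool = simulate_trna_pool(cfg)
            genes = simulate_genes(cfg, trnas, pool)
            heg_ids = set(genes.gene_truth.loc[genes.gene_truth.is_heg, "gene_id"])
            heg = rscu(count_codons([s for g, s in genes.cds if g in heg_ids]))
            leg = rscu(count_codons([s for g, s in genes.cds if g not in heg_ids]))
            codons = [c for f in codon_families() for c in f.codons]
            p_values.append(stats.ks_2samp([heg[c] for c in codons],
                                           [leg[c] for c in codons]).pvalue)
        assert np.median(p_values) > 0.01

    def test_beta_three_heg_argmax_matches_planted_truth(self):
        cfg = SimConfig(seed=2, beta=3.0, n_genes=400)
        trnas, pool = simulate_trna_pool(cfg)
        genes = simulate_genes(cfg, trnas, pool)
        heg_ids = set(genes.gene_truth.loc[genes.gene_truth.is_heg, "gene_id"])
        counts = count_codons([s for g, s in genes.cds if g in heg_ids])
        truth = dict(zip(genes.family_truth.family, genes.family_truth.planted_codon))
        hits = 0
        for fam in codon_families():
            argmax = max(fam.codons, key=lambda c: counts[c])
            hits += argmax == truth[fam.label]
        assert hits >= 0.95 * len(codon_families())

    def test_gamma_zero_decouples_expression_from_selection(self):
        from trnacodon.expression import protein_per_transcript, select_heg_leg

        overlaps = []
        for seed in range(8):
            cfg = SimConfig(seed=seed, beta=2.0, gamma=0.0, n_genes=300)
            trnas, pool = simulate_trna_pool(cfg)
            genes = simulate_genes(cfg, trnas, pool)
            sets = select_heg_leg([protein_per_transcript(genes.protein, genes.mrna)])
            planted = set(genes.gene_truth.loc[genes.gene_truth.is_heg, "gene_id"])
            overlaps.append(len(sets.heg & planted) / len(sets.heg))
        # ~30% of genes are planted HEGs; with gamma=0 the ppt ranking is blind to them
        assert 0.15 < np.mean(overlaps) < 0.45

    def test_gamma_positive_elevates_planted_heg_ppt(self):
        cfg = SimConfig(seed=1, beta=2.0, gamma=2.0, n_genes=300)
        trnas, pool = simulate_trna_pool(cfg)
        genes = simulate_genes(cfg, trnas, pool)
        ppt = genes.protein / genes.mrna.tpm
        planted = genes.gene_truth.set_index("gene_id").is_heg
        assert ppt[planted].median() > ppt[~planted].median()


class TestReads:
    def test_zero_reads(self):
        cfg = SimConfig(seed=0, n_reads=0)
        trnas, pool = simulate_trna_pool(cfg)
        assert simulate_reads(pool, trnas, cfg) == []

    def test_determinism_and_length_floor(self):
        cfg = SimConfig(seed=6, n_reads=500, p_stop=0.5)
        trnas, pool = simulate_trna_pool(cfg)
        r1 = simulate_reads(pool, trnas, cfg)
        r2 = simulate_reads(pool, trnas, cfg)
        assert r1 == r2
        assert all(len(r) >= 25 for r in r1)

    def test_reads_are_substrings_without_truncation(self):
        cfg = SimConfig(seed=6, n_reads=300, p_stop=0.0)
        trnas, pool = simulate_trna_pool(cfg)
        reads = simulate_reads(pool, trnas, cfg)
        assert len(reads) == 300
        seqs = [t.sequence for t in trnas]
        assert all(any(r in s for s in seqs) for r in reads)
        assert all(len(r) == cfg.read_length for r in reads)
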