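import math

import numpy as np
import pytest

from trnacodon.codon_model import SENSE_CODONS, count_codons, gc3s, nc, reverse_complement
from trnacodon.pairing import COGNATE, PairingRule, PairingRules, default_rules
from trnacodon.synthetic_data import SimConfig, simulate_genes, simulate_trna_pool
from trnacodon.tai import gene_tai, s_statistic, tai_weights
from trnacodon.trna_quant import TrnaAbundance

from conftest import make_trna


class TestWeights:
    def test_thr_toy_hand_computed(self, thr_trnas):
        rules = default_rules(include_modified=False)
        model = tai_weights({"GGU": 2.0, "UGU": 1.0}, thr_trnas, rules)
        assert model.W["ACC"] == pytest.approx(2.0)
        assert model.W["ACU"] == pytest.approx(1.18)
        assert model.W["ACA"] == pytest.approx(1.0)
        assert model.W["ACG"] == pytest.approx(0.32)
        got = {c: round(model.w[c], 4) for c in ("ACC", "ACU", "ACA", "ACG")}
        assert got == {"ACC": 1.0, "ACU": 0.59, "ACA": 0.5, "ACG": 0.16}

    def test_scale_invariance(self, thr_trnas):
        m1 = tai_weights({"GGU": 2.0, "UGU": 1.0}, thr_trnas)
        m2 = tai_weights({"GGU": 20.0, "UGU": 10.0}, thr_trnas)
        for c in SENSE_CODONS:
            assert math.isclose(m1.w[c], m2.w[c], rel_tol=1e-12)

    def test_single_trna_degenerate_fill(self):
        trna = make_trna("CAU")  # reads AUG only
        model = tai_weights({"CAU": 5.0}, [trna])
        assert model.w["AUG"] == 1.0
        assert model.w_fill == 1.0  # geometric mean of the single nonzero weight
        assert all(v == 1.0 for v in model.w.values())

    def test_all_cognate_equal_abundance_gives_unit_weights(self):
        # cognate-only rules, one tRNA per codon, equal abundance
        rules = PairingRules(
            (
                PairingRule("A", "U", COGNATE, 0.0),
                PairingRule("C", "G", COGNATE, 0.0),
                PairingRule("G", "C", COGNATE, 0.0),
                PairingRule("U", "A", COGNATE, 0.0),
            )
        )
        trnas = [make_trna(reverse_complement(c)) for c in SENSE_CODONS]
        abundance = {t.anticodon: 3.0 for t in trnas}
        model = tai_weights(abundance, trnas, rules)
        assert all(v == 1.0 for v in model.w.values())
        counts = count_codons("AUGGCUAAAUAA")
        assert gene_tai(model, counts) == 1.0

    def test_monotone_in_sole_cognate_abundance(self, thr_trnas):
        rules = default_rules(include_modified=False)
        lo = tai_weights({"GGU": 2.0, "UGU": 1.0}, thr_trnas, rules)
        hi = tai_weights({"GGU": 2.0, "UGU": 2.5}, thr_trnas, rules)
        assert hi.w["ACA"] >= lo.w["ACA"]
        gene = {"ACA": 3, "ACC": 1}
        assert gene_tai(hi, gene) >= gene_tai(lo, gene)

    def test_zero_pool_raises(self, thr_trnas):
        with pytest.raises(ValueError, match="zero"):
            tai_weights({"GGU": 0.0, "UGU": 0.0}, thr_trnas)


class TestGeneTai:
    def test_two_codon_hand_value(self, thr_trnas):
        rules = default_rules(include_modified=False)
        model = tai_weights({"GGU": 2.0, "UGU": 1.0}, thr_trnas, rules)
        assert gene_tai(model, {"ACC": 1, "ACU": 1}) == pytest.approx(math.sqrt(0.59))

    def test_codon_order_invariance(self, thr_trnas):
        model = tai_weights({"GGU": 2.0, "UGU": 1.0}, thr_trnas)
        a = gene_tai(model, {"ACC": 2, "ACA": 1})
        b = gene_tai(model, {"ACA": 1, "ACC": 2})
        assert a == b

    def test_empty_gene_raises(self, thr_trnas):
        model = tai_weights({"GGU": 1.0, "UGU": 1.0}, thr_trnas)
        with pytest.raises(ValueError, match="no sense codons"):
            gene_tai(model, {})


class TestSStatistic:
    def test_perfect_correlation(self):
        # genes whose tai equals their deviation exactly
        tai_v = {"a": 0.1, "b": 0.5, "c": 0.9}
        nc_v = {"a": 60.4, "b": 60.0, "c": 59.6}
        gc_v = {"a": 0.5, "b": 0.5, "c": 0.5}  # f = 60.5 -> deviation 0.1/0.5/0.9
        result = s_statistic(tai_v, nc_v, gc_v)
        assert result.S == pytest.approx(1.0)

    def test_null_permutation_small_s(self, study_run):
        genes = study_run["genes"]
        model = tai_weights(study_run["pool"], study_run["trnas"])
        sub = genes.cds[:500]
        tai_v, nc_v, gc_v = {}, {}, {}
        for g, s in sub:
            counts = count_codons(s)
            tai_v[g] = gene_tai(model, counts)
            nc_v[g] = nc(counts)
            gc_v[g] = gc3s(s)
        rng = np.random.default_rng(123)
        ids = list(tai_v)
        vals = [tai_v[g] for g in ids]
        rng.shuffle(vals)
        result = s_statistic(dict(zip(ids, vals)), nc_v, gc_v)
        assert abs(result.S) < 0.1

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            s_statistic({"a": 1.0, "b": 1.0, "c": 1.0}, {"a": 50.0, "b": 51.0, "c": 52.0},
                        {"a": 0.4, "b": 0.5, "c": 0.6})

    def test_too_few_genes_raises(self):
        with pytest.raises(ValueError, match=">= 3"):
            s_statistic({"a": 0.1, "b": 0.2}, {"a": 50.0, "b": 51.0}, {"a": 0.4, "b": 0.5})

    def test_spearman_method_available(self):
        tai_v = {"a": 0.1, "b": 0.5, "c": 0.9, "d": 0.2}
        nc_v = {"a": 60.0, "b": 55.0, "c": 50.0, "d": 59.0}
        gc_v = {"a": 0.5, "b": 0.5, "c": 0.5, "d": 0.5}
        result = s_statistic(tai_v, nc_v, gc_v, method="spearman")
        assert result.method == "spearman" and result.S == pytest.approx(1.0)


class TestPlantedCoupling:
    def test_s_positive_each_replicate_and_tpm_beats_decoupled_copies(self):
        """Under planted tRNA-driven selection S is strongly positive in
        every replicate; with copy numbers decoupled from the planted
        abundances the tpm-based S' exceeds the copy-based S on average
        (the direction, as in real species, is not universal per
        replicate)."""
        s_tpm, s_copy = [], []
        for seed in range(1, 21):
            cfg = SimConfig(seed=seed, beta=2.0, gamma=2.0, n_genes=150, copy_link=0.0,
                            min_gene_codons=100, max_gene_codons=200)
            trnas, pool = simulate_trna_pool(cfg)
            genes = simulate_genes(cfg, trnas, pool)
            m_t = tai_weights(pool, trnas)
            m_c = tai_weights(TrnaAbundance.from_copy_numbers(trnas), trnas)
            tt, tc, nv, gv = {}, {}, {}, {}
            for g, s in genes.cds:
                counts = count_codons(s)
                tt[g] = gene_tai(m_t, counts)
                tc[g] = gene_tai(m_c, counts)
                nv[g] = nc(counts)
                gv[g] = gc3s(s)
            rt = s_statistic(tt, nv, gv)
            rc = s_statistic(tc, nv, gv)
            assert rt.S > 0 and rt.p_value < 0.01
            s_tpm.append(rt.S)
            s_copy.append(rc.S)
        assert np.mean(s_tpm) > np.mean(s_copy)
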