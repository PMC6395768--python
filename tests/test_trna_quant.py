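import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from trnacodon.codon_model import codon_families
from trnacodon.synthetic_data import SimConfig, simulate_reads, simulate_trna_pool
from trnacodon.trna_quant import (
    TrnaAbundance,
    assign_reads,
    codon_availability,
    depth_from_reads,
    detect_hard_stops,
    methylation_classes,
    readable_codon_usage,
    rtu,
    tpm_from_counts,
)

from conftest import make_trna
from oracles import oracle_welch


class TestTpm:
    def test_single_transcript(self):
        assert tpm_from_counts({"a": 5}, {"a": 76}).tpm["a"] == pytest.approx(1e6)

    def test_hand_computed(self):
        table = tpm_from_counts({"a": 10, "b": 10}, {"a": 100, "b": 200})
        assert table.tpm["a"] == pytest.approx(666666.67, abs=0.01)
        assert table.tpm["b"] == pytest.approx(333333.33, abs=0.01)

    def test_scale_invariance(self):
        t1 = tpm_from_counts({"a": 3, "b": 9}, {"a": 70, "b": 90})
        t2 = tpm_from_counts({"a": 6, "b": 18}, {"a": 70, "b": 90})
        assert t1.tpm.tolist() == pytest.approx(t2.tpm.tolist())

    def test_all_zero_raises(self):
        with pytest.raises(ValueError, match="zero"):
            tpm_from_counts({"a": 0}, {"a": 76})


class TestAssignReads:
    def test_unique_and_shared_assignment(self):
        t1 = make_trna("GGU")
        t2 = make_trna("UGU")
        unique = t1.sequence[30:60]  # spans the anticodon, unique to t1
        counts, dropped = assign_reads([unique], [t1, t2])
        assert counts[t1.id] == 1.0 and dropped == 0
        # a read present in both sequences splits
        both = "G" * 30
        counts, _ = assign_reads([both], [t1, t2])
        assert counts[t1.id] == counts[t2.id] == 0.5

    def test_short_and_unmatched_dropped(self):
        t1 = make_trna("GGU")
        counts, dropped = assign_reads(["ACGU" * 5, "U" * 30], [t1])
        assert dropped == 2 and counts[t1.id] == 0.0

    def test_rank_recovery_from_simulated_reads(self):
        cfg = SimConfig(seed=5, n_reads=10_000)
        trnas, pool = simulate_trna_pool(cfg)
        reads = simulate_reads(pool, trnas, cfg)
        counts, _ = assign_reads(reads, trnas)
        table = tpm_from_counts(counts, {t.id: len(t.sequence) for t in trnas})
        est = TrnaAbundance.from_tpm(table, trnas)
        antis = sorted(pool.values)
        rho = stats.spearmanr(
            [pool.values[a] for a in antis], [est.values[a] for a in antis]
        ).statistic
        assert rho >= 0.95


class TestAvailability:
    def test_thr_example_with_cognate_split(self, thr_trnas):
        avail, cog = codon_availability({"GGU": 300.0, "UGU": 100.0}, thr_trnas)
        assert avail["ACC"] == avail["ACU"] == 400.0
        assert cog["ACC"] == 300.0 and cog["ACU"] == 0.0
        assert avail["ACA"] == 100.0 and cog["ACA"] == 100.0

    def test_zero_pool_gives_zeros(self, thr_trnas):
        avail, _ = codon_availability({"GGU": 0.0, "UGU": 0.0}, thr_trnas)
        assert not any(avail.values())

    def test_additive_over_disjoint_subsets(self, thr_trnas):
        full, _ = codon_availability({"GGU": 10.0, "UGU": 5.0}, thr_trnas)
        a, _ = codon_availability({"GGU": 10.0}, thr_trnas[:1])
        b, _ = codon_availability({"UGU": 5.0}, thr_trnas[1:])
        assert all(math.isclose(full[c], a[c] + b[c]) for c in full)

    def test_unknown_anticodon_rejected(self, thr_trnas):
        with pytest.raises(ValueError, match="absent"):
            codon_availability({"AAA": 1.0}, thr_trnas)


class TestRtu:
    def test_hand_computed(self):
        fam = [f for f in codon_families() if f.label == "Thr-4fold"][0]
        table = rtu(dict(zip(fam.codons, [300.0, 100.0, 300.0, 100.0])), [fam])
        assert [round(table[c], 6) for c in fam.codons] == [1.5, 0.5, 1.5, 0.5]

    def test_equal_availability_flagged(self):
        fam = [f for f in codon_families() if f.label == "Lys-2fold"][0]
        table = rtu({c: 7.0 for c in fam.codons}, [fam])
        assert table.flagged_families == ("Lys-2fold",)

    def test_zero_family_is_nan(self):
        fam = [f for f in codon_families() if f.label == "Lys-2fold"][0]
        table = rtu({c: 0.0 for c in fam.codons}, [fam])
        assert all(math.isnan(table[c]) for c in fam.codons)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 1e4))
    def test_family_mean_one_and_scale_invariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        avail = {c: float(rng.uniform(0.1, 100)) for f in codon_families() for c in f.codons}
        t1 = rtu(avail)
        t2 = rtu({c: scale * v for c, v in avail.items()})
        for fam in codon_families():
            mean = sum(t1[c] for c in fam.codons) / fam.fold
            assert math.isclose(mean, 1.0, abs_tol=1e-9)
            for c in fam.codons:
                assert math.isclose(t1[c], t2[c], rel_tol=1e-9)


class TestReadableCodonUsage:
    def test_ala_example(self):
        trna = make_trna("GGC")  # Ala: cognate GCC, wobble GCU
        counts = {"GCC": 11, "GCU": 5, "GCA": 100}
        assert readable_codon_usage([trna], None, counts) == {"GGC": 16.0}

    def test_zero_counts(self):
        assert readable_codon_usage([make_trna("GGC")], None, {}) == {"GGC": 0.0}


class TestMethylation:
    def test_threshold_rule(self):
        trnas = [
            make_trna("GGU", sites=(1, 2, 3, 4, 5)),
            make_trna("UGU", sites=(1, 2, 3, 4, 5, 6)),
            make_trna("GGC", sites=(1,)),
            make_trna("UGC", sites=(1, 2)),
        ]
        report = methylation_classes(trnas, {t.id: 10.0 for t in trnas})
        classes = dict(zip(report.per_trna.trna_id, report.per_trna.methyl_class))
        assert classes == {
            "trna-GGU": "heavy", "trna-UGU": "heavy", "trna-GGC": "light", "trna-UGC": "light",
        }

    def test_identical_distributions_give_p_near_one(self):
        trnas = [make_trna(a, sites=(1, 2, 3, 4, 5) if i < 3 else ())
                 for i, a in enumerate(["GGU", "UGU", "GGC", "UGC", "GAU", "UAU"])]
        tpm = {t.id: 5.0 + (i % 3) for i, t in enumerate(trnas)}
        report = methylation_classes(trnas, tpm)
        assert report.p_value > 0.9

    def test_welch_statistic_matches_textbook_formula(self):
        heavy = [12.0, 15.0, 11.0, 18.0, 14.0]
        light = [8.0, 9.0, 7.5, 10.0, 8.5]
        trnas = []
        tpm = {}
        for i, v in enumerate(heavy + light):
            t = make_trna(["GGU", "UGU", "GGC", "UGC", "GAU", "UAU", "CAU", "GAA", "UUU", "CUU"][i],
                          sites=(1, 2, 3, 4, 5) if i < 5 else ())
            trnas.append(t)
            tpm[t.id] = v
        report = methylation_classes(trnas, tpm)
        t_ref, _df = oracle_welch(heavy, light)
        assert report.t_statistic == pytest.approx(t_ref, rel=1e-12)

    def test_small_class_gives_nan_p(self):
        trnas = [make_trna("GGU", sites=(1, 2, 3, 4, 5)), make_trna("UGU")]
        report = methylation_classes(trnas, {t.id: 1.0 for t in trnas})
        assert math.isnan(report.p_value)


class TestHardStops:
    def test_flat_profile_has_no_stops(self):
        assert detect_hard_stops({"t": np.full(76, 50.0)}) == []

    def test_cliff_reported_at_boundary_site(self):
        profile = np.array([100.0] * 20 + [2.0] * 20)
        stops = detect_hard_stops({"t": profile})
        assert [(h.trna_id, h.site) for h in stops] == [("t", 20)]
        assert stops[0].upstream_mean == pytest.approx(100.0)
        assert stops[0].downstream_mean == pytest.approx(2.0)

    def test_monotone_in_ratio(self):
        profile = np.array([100.0] * 20 + [50.0] * 20)
        assert detect_hard_stops({"t": profile}, ratio=0.2) == []
        lax = detect_hard_stops({"t": profile}, ratio=1.0)
        assert lax  # any decline reported once the threshold is permissive

    def test_low_coverage_ignored(self):
        profile = np.array([5.0] * 20 + [0.5] * 20)
        assert detect_hard_stops({"t": profile}, min_depth=10) == []

    def test_planted_truncation_recovered(self):
        from dataclasses import replace

        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            cfg = SimConfig(seed=seed, n_reads=3000, p_stop=0.9, read_length=40)
            trnas, _pool = simulate_trna_pool(cfg)
            planted = replace(trnas[0], methylation_sites=(50,))
            sub_pool = TrnaAbundance({planted.anticodon: 1.0})
            reads = simulate_reads(sub_pool, [planted], cfg)
            stops = detect_hard_stops(depth_from_reads(reads, [planted]))
            if stops and all(abs(h.site - 50) <= 1 for h in stops):
                hits += 1
        assert hits >= 0.95 * n_rep
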