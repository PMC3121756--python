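"""Generator correctness: estimator closure, truth-ledger consistency, sampling."""

import numpy as np
import pytest
from scipy.stats import binom

from zeinhap.divergence_dating import k2p, pairwise_site_counts
from zeinhap.genomic_model import FeatureKind, GenomicSequence
from zeinhap.synthetic_data import (
    ConfigError,
    REInsertion,
    SimulationConfig,
    evolve_sequence,
    random_sequence,
    simulate_bisulfite_reads,
    simulate_clone_library,
    simulate_locus_pair,
)


class TestEvolveSequence:
    def test_zero_divergence_identity(self):
        assert evolve_sequence("ACGTACGT", 0.0, 2.0, 1) == "ACGTACGT"

    def test_determinism(self):
        seq = random_sequence(500, np.random.default_rng(3))
        assert evolve_sequence(seq, 0.1, 2.0, 42) == evolve_sequence(seq, 0.1, 2.0, 42)

    def test_negative_divergence_rejected(self):
        with pytest.raises(ConfigError):
            evolve_sequence("ACGT", -0.1, 2.0, 1)

    def test_estimator_generator_closure(self):
        """K2P estimate between input and 100-kb output within 0.01 of target."""
        anc = random_sequence(100_000, np.random.default_rng(1))
        out = evolve_sequence(anc, 0.1702, 2.0, 42)
        est = k2p(pairwise_site_counts(anc, out, prealigned=True))
        assert est.K == pytest.approx(0.1702, abs=0.01)

    def test_kappa_controls_ts_tv_ratio(self):
        anc = random_sequence(100_000, np.random.default_rng(2))
        out = evolve_sequence(anc, 0.05, 8.0, 7)
        c = pairwise_site_counts(anc, out, prealigned=True)
        assert c.P / c.Q > 2.5  # strongly transition-biased at kappa=8


class TestSimulateLocusPair:
    def test_age_zero_gives_identical_ltrs(self):
        cfg = SimulationConfig(
            seed=5, re_insertions=[REInsertion(age=0.0, ltr_len=300, body_len=500)]
        )
        hap_a, _, _ = simulate_locus_pair(cfg)
        ltrs = [f for f in hap_a.features if f.kind == FeatureKind.ltr]
        assert len(ltrs) == 2
        seqs = [hap_a.contig.seq[f.start:f.end] for f in ltrs]
        assert seqs[0] == seqs[1]

    def test_copy_counts(self, default_pair):
        cfg, hap_a, hap_b, _ = default_pair
        for hap in (hap_a, hap_b):
            genes = hap.features_of_kind(FeatureKind.zein_gene)
            assert len(genes) == cfg.n_zein_copies

    def test_absent_copy_in_b(self):
        cfg = SimulationConfig(seed=5, absent_in_b=(4,))
        hap_a, hap_b, _ = simulate_locus_pair(cfg)
        assert len(hap_a.features_of_kind(FeatureKind.zein_gene)) == 5
        assert len(hap_b.features_of_kind(FeatureKind.zein_gene)) == 4

    def test_determinism(self):
        cfg = SimulationConfig(seed=17)
        a1, b1, t1 = simulate_locus_pair(cfg)
        a2, b2, t2 = simulate_locus_pair(SimulationConfig(seed=17))
        assert a1.contig.seq == a2.contig.seq
        assert b1.contig.seq == b2.contig.seq
        assert t1.true_ages == t2.true_ages

    def test_truth_ledger_consistency(self, default_pair):
        """Every generated gene/RE feature appears in the truth and vice versa."""
        cfg, hap_a, hap_b, truth = default_pair
        seen = set()
        for hap in (hap_a, hap_b):
            for f in hap.features:
                if f.kind in (FeatureKind.zein_gene, FeatureKind.retroelement):
                    seen.add(f.feature_id)
        assert seen == set(truth.true_ages)

    def test_nesting_age_invariant(self, default_pair):
        _, _, _, truth = default_pair
        for nested, host in truth.nesting.items():
            assert truth.true_ages[nested] <= truth.true_ages[host]

    def test_insertion_order_matches_ages(self, default_pair):
        _, _, _, truth = default_pair
        ages = [truth.true_ages[e] for e in truth.insertion_order]
        assert ages == sorted(ages, reverse=True)

    def test_tsd_flanks_identical(self, default_pair):
        cfg, hap_a, _, _ = default_pair
        for re_feat in hap_a.features_of_kind(FeatureKind.retroelement):
            tsds = [
                f for f in hap_a.children_of(re_feat.feature_id)
                if f.kind == FeatureKind.tsd
            ]
            assert len(tsds) == 2
            s1, s2 = (hap_a.contig.seq[f.start:f.end] for f in tsds)
            assert s1 == s2 and len(s1) == cfg.tsd_len

    def test_haplotype_specific_presence(self, default_pair):
        _, hap_a, hap_b, truth = default_pair
        ids_a = {f.feature_id for f in hap_a.features_of_kind(FeatureKind.retroelement)}
        ids_b = {f.feature_id for f in hap_b.features_of_kind(FeatureKind.retroelement)}
        for eid, carriers in truth.carriers.items():
            if not eid.startswith("re"):
                continue
            assert (eid in ids_a) == ("A" in carriers)
            assert (eid in ids_b) == ("B" in carriers)

    def test_nested_inside_host_span(self, default_pair):
        _, hap_a, _, truth = default_pair
        feats = {f.feature_id: f for f in hap_a.features}
        for nested, host in truth.nesting.items():
            if nested in feats and host in feats:
                assert feats[host].start <= feats[nested].start
                assert feats[nested].end <= feats[host].end

    def test_ltr_divergence_matches_age(self):
        """Dating the generator's own elements recovers the configured age."""
        from zeinhap.divergence_dating import date_ltr_pair
        from zeinhap.genomic_model import extract_feature_sequence

        cfg = SimulationConfig(
            seed=23,
            re_insertions=[REInsertion(age=6.2, ltr_len=5000, body_len=500)],
        )
        hap_a, _, _ = simulate_locus_pair(cfg)
        ltrs = sorted(
            (f for f in hap_a.features if f.kind == FeatureKind.ltr),
            key=lambda f: f.start,
        )
        ev = date_ltr_pair(
            extract_feature_sequence(hap_a, ltrs[0].feature_id).seq,
            extract_feature_sequence(hap_a, ltrs[1].feature_id).seq,
            cfg.clock,
            prealigned=True,
        )
        assert ev.age == pytest.approx(6.2, rel=0.15)

    def test_nested_in_younger_host_rejected(self):
        cfg = SimulationConfig(
            seed=1,
            re_insertions=[
                REInsertion(age=1.0),
                REInsertion(age=3.0, nested_in=0),
            ],
        )
        with pytest.raises(ConfigError, match="younger host"):
            simulate_locus_pair(cfg)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ConfigError, match="sum"):
            SimulationConfig(seed=1, expression_fractions=(0.5, 0.2, 0.1, 0.1, 0.05)).validate()


class TestCloneLibrary:
    @pytest.fixture
    def refdb(self):
        rng = np.random.default_rng(9)
        return [GenomicSequence(f"c{i}", random_sequence(300, rng)) for i in range(2)]

    def test_pure_library(self, refdb):
        lib = simulate_clone_library(refdb, (1.0, 0.0), 10, 0.0, 3)
        assert len(lib.clones) == 10
        assert all(c.seq == refdb[0].seq for c in lib.clones)
        assert set(lib.sources.values()) == {"c0"}

    def test_count_contract(self, refdb):
        lib = simulate_clone_library(refdb, (0.5, 0.5), 288, 0.005, 4)
        assert len(lib.clones) == 288

    def test_multinomial_within_3_sigma(self, refdb):
        """Empirical counts match the binomial oracle at n=10,000."""
        n, p = 10_000, 0.9
        lib = simulate_clone_library(refdb, (p, 1 - p), n, 0.0, 5)
        k = sum(1 for v in lib.sources.values() if v == "c0")
        sigma = (n * p * (1 - p)) ** 0.5
        assert abs(k - n * p) <= 3 * sigma

    def test_fraction_sum_enforced(self, refdb):
        with pytest.raises(ConfigError):
            simulate_clone_library(refdb, (0.6, 0.6), 10, 0.0, 1)

    def test_error_rate_applied(self, refdb):
        lib = simulate_clone_library(refdb, (1.0, 0.0), 50, 0.02, 6)
        diffs = sum(
            sum(a != b for a, b in zip(c.seq, refdb[0].seq)) for c in lib.clones
        )
        total = 50 * 300
        sigma = (total * 0.02 * 0.98) ** 0.5
        assert abs(diffs - total * 0.02) <= 4 * sigma


class TestBisulfiteReads:
    PROM = "ACGTCCATGCAATCGGCTAC"  # 6 top-strand Cs... counted in test

    def test_full_conversion(self):
        n_c = self.PROM.count("C")
        reads = simulate_bisulfite_reads(self.PROM, [0.0] * n_c, 0.0, 5, 1)
        for r in reads:
            assert "C" not in r.seq
            assert len(r.seq) == len(self.PROM)

    def test_full_methylation(self):
        n_c = self.PROM.count("C")
        reads = simulate_bisulfite_reads(self.PROM, [1.0] * n_c, 0.0, 5, 1)
        for r in reads:
            assert r.seq == self.PROM

    def test_non_c_bases_unchanged(self):
        n_c = self.PROM.count("C")
        reads = simulate_bisulfite_reads(self.PROM, [0.0] * n_c, 0.0, 1, 1)
        for orig, got in zip(self.PROM, reads[0].seq):
            if orig != "C":
                assert got == orig

    def test_per_site_within_binomial_ci(self):
        """Retained-C fraction at each site inside the exact 95% CI for p=0.3."""
        prom = random_sequence(200, np.random.default_rng(12))
        n_c = prom.count("C")
        n_reads = 96
        reads = simulate_bisulfite_reads(prom, [0.3] * n_c, 0.0, n_reads, 77)
        positions = [i for i, b in enumerate(prom) if b == "C"]
        lo, hi = binom.ppf(0.025, n_reads, 0.3), binom.ppf(0.975, n_reads, 0.3)
        inside = 0
        for pos in positions:
            k = sum(1 for r in reads if r.seq[pos] == "C")
            inside += lo <= k <= hi
        # by CI construction ~95% of sites qualify; require >= 90% for this seed
        assert inside / len(positions) >= 0.90

    def test_probability_length_mismatch(self):
        with pytest.raises(ConfigError, match="cytosines"):
            simulate_bisulfite_reads("ACGC", [0.5], 0.0, 1, 1)
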