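"""Promoters, enhancers, PEI calling, RPS, covariation, PP contacts."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from archcomp import (
    FeatureTrack,
    GenomicInterval,
    SimParams,
    build_binning,
    simulate_architecture,
    simulate_contact_map,
    simulate_expression,
    simulate_peaks,
)
from archcomp.genome_model import GeneAnnotation
from archcomp.contacts import OEMatrix
from archcomp.pipeline import balance_and_oe
from archcomp.regulatory import (
    PeiSet,
    Pei,
    call_pei,
    define_enhancers,
    define_promoters,
    pei_overlap,
    promoter_promoter_analysis,
    regulatory_potential,
    rps_expression_covariation,
    stitch_super,
    strict_expression_filter,
)


def genes_fixture():
    return [
        GeneAnnotation("plus", GenomicInterval("chr1", 10_000, 20_000, "+"), 10_000),
        GeneAnnotation("minus", GenomicInterval("chr1", 5_000, 10_000, "-"), 5_000),
        GeneAnnotation("edge", GenomicInterval("chr1", 500, 4_000, "+"), 3_500),
    ]


@pytest.fixture(scope="module")
def pei_setup():
    """Default-architecture map with called PEIs and planted truth."""
    truth = simulate_architecture(SimParams(seed=1))
    m = simulate_contact_map(truth, 1, seed=51)
    oe, _ = balance_and_oe(m)
    k27, _ = simulate_peaks(truth, 1, seed=61)
    promoters = define_promoters(truth.genes, truth.binning)
    enhancers = define_enhancers(k27, promoters, truth.binning)
    pei = call_pei(oe, m, promoters, enhancers)
    return truth, m, oe, promoters, enhancers, pei


class TestPromoters:
    def test_plus_strand_flank(self):
        b = build_binning({"chr1": 1_000_000}, 100_000)
        ps = define_promoters(genes_fixture(), b, flank=2_000)
        iv = ps.promoters["plus"]
        assert (iv.start, iv.end) == (8_000, 12_000)

    def test_minus_strand_tss_at_end(self):
        b = build_binning({"chr1": 1_000_000}, 100_000)
        ps = define_promoters(genes_fixture(), b, flank=2_000)
        iv = ps.promoters["minus"]
        assert (iv.start, iv.end) == (7_999, 11_999)

    def test_clipped_at_chromosome_start(self):
        b = build_binning({"chr1": 1_000_000}, 100_000)
        ps = define_promoters(genes_fixture(), b, flank=2_000)
        iv = ps.promoters["edge"]
        assert (iv.start, iv.end) == (0, 2_500)

    def test_positive_flank_required(self):
        b = build_binning({"chr1": 1_000_000}, 100_000)
        with pytest.raises(ValueError):
            define_promoters(genes_fixture(), b, flank=0)


class TestEnhancers:
    def test_peak_inside_promoter_excluded(self):
        b = build_binning({"chr1": 1_000_000}, 100_000)
        ps = define_promoters(genes_fixture(), b, flank=2_000)
        peaks = FeatureTrack([
            (GenomicInterval("chr1", 9_000, 9_500), 5.0),     # inside promoter
            (GenomicInterval("chr1", 500_000, 501_000), 3.0),  # distal
        ])
        enh = define_enhancers(peaks, ps, b)
        assert len(enh.enhancers) == 1
        assert enh.enhancers[0].interval.start == 500_000

    def test_empty_peaks_rejected(self):
        b = build_binning({"chr1": 1_000_000}, 100_000)
        ps = define_promoters(genes_fixture(), b, flank=2_000)
        with pytest.raises(ValueError):
            define_enhancers(FeatureTrack([]), ps, b)

    def test_elbow_isolates_outlier_super(self):
        b = build_binning({"chr1": 10_000_000}, 100_000)
        ps = define_promoters(genes_fixture(), b, flank=1_000)
        feats = [(GenomicInterval("chr1", 1_000_000 * (i + 1),
                                  1_000_000 * (i + 1) + 1_000), v)
                 for i, v in enumerate([1.0, 1.0, 1.0, 1.0, 100.0])]
        enh = stitch_super(define_enhancers(FeatureTrack(feats), ps, b))
        klass = {e.signal: e.klass for e in enh.enhancers}
        assert klass[100.0] == "super"
        assert all(k == "regular" for s, k in klass.items() if s != 100.0)

    def test_stitching_merges_nearby_peaks(self):
        b = build_binning({"chr1": 10_000_000}, 100_000)
        ps = define_promoters(genes_fixture(), b, flank=1_000)
        feats = [
            (GenomicInterval("chr1", 1_000_000, 1_002_000), 2.0),
            (GenomicInterval("chr1", 1_012_000, 1_014_000), 3.0),  # 10 kb gap
            (GenomicInterval("chr1", 2_000_000, 2_002_000), 1.0),
        ]
        enh = stitch_super(define_enhancers(FeatureTrack(feats), ps, b),
                           stitch_dist=12_500)
        assert len(enh.enhancers) == 2
        merged = [e for e in enh.enhancers if e.interval.start == 1_000_000][0]
        assert merged.interval.end == 1_014_000
        assert merged.signal == 5.0


class TestCallPei:
    def test_infinite_threshold_empty(self, pei_setup):
        truth, m, oe, promoters, enhancers, _ = pei_setup
        empty = call_pei(oe, m, promoters, enhancers, oe_threshold=np.inf)
        assert len(empty) == 0

    def test_same_bin_distance_zero_excluded(self, pei_setup):
        _, _, _, _, _, pei = pei_setup
        assert all(p.distance_bins > 0 for p in pei.peis)

    def test_distance_cap_respected(self, pei_setup):
        truth, m, oe, promoters, enhancers, pei = pei_setup
        max_bins = 1_000_000 // truth.binning.bin_size
        assert all(p.distance_bins <= max_bins for p in pei.peis)

    def test_planted_loops_recovered(self, pei_setup):
        truth, m, oe, promoters, enhancers, pei = pei_setup
        planted = {(pb, eb) for pb, eb, _ in truth.planted_peis[1]}
        called = {(promoters.tss_bin[p.gene_id], p.enhancer_bin)
                  for p in pei.peis}
        recall = len(planted & called) / len(planted)
        tp = sum(1 for p in pei.peis
                 if (promoters.tss_bin[p.gene_id], p.enhancer_bin) in planted)
        precision = tp / len(pei)
        assert recall >= 0.9
        assert precision >= 0.8


class TestPeiOverlap:
    def _sets(self, n1, n2, shared):
        common = [("g", "chr1", i, i + 1) for i in range(shared)]
        k1 = common + [("a", "chr1", 10_000 + i, 10_001 + i)
                       for i in range(n1 - shared)]
        k2 = common + [("b", "chr1", 90_000 + i, 90_001 + i)
                       for i in range(n2 - shared)]
        return k1, k2

    def test_published_counts_reproduce_percentages(self):
        k1, k2 = self._sets(20_389, 30_852, 5_547)
        shared, pct1, pct2 = pei_overlap(k1, k2)
        assert (shared, pct1, pct2) == (5_547, 27.21, 17.98)

    def test_identical_sets(self):
        k1, _ = self._sets(100, 100, 100)
        assert pei_overlap(k1, list(k1)) == (100, 100.0, 100.0)

    def test_disjoint_sets(self):
        k1 = [("a", "chr1", i, i + 1) for i in range(10)]
        k2 = [("b", "chr2", i, i + 1) for i in range(10)]
        assert pei_overlap(k1, k2) == (0, 0.0, 0.0)

    def test_percentages_symmetric_under_swap(self):
        k1, k2 = self._sets(300, 150, 77)
        s12 = pei_overlap(k1, k2)
        s21 = pei_overlap(k2, k1)
        assert s12[0] == s21[0]
        assert (s12[1], s12[2]) == (s21[2], s21[1])

    def test_rounding_is_half_up(self):
        # 1/800 = 0.125% -> 0.13 under half-up (banker's would give 0.12)
        k1 = [("g", "c", i, i + 1) for i in range(800)]
        k2 = [("g", "c", 0, 1)] + [("x", "c", i, i + 1) for i in range(1, 200)]
        _, pct1, _ = pei_overlap(k1, k2)
        assert pct1 == 0.13

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            pei_overlap([], [("a", "c", 0, 1)])


class TestRps:
    def test_gene_without_pei_scores_zero(self, pei_setup):
        truth, _, _, _, enhancers, pei = pei_setup
        rps = regulatory_potential(pei, enhancers,
                                   [g.gene_id for g in truth.genes])
        with_pei = pei.genes()
        zero = rps[~rps.index.isin(with_pei)]
        assert (zero == 0).all()
        assert (rps[rps.index.isin(with_pei)] > 0).all()

    def test_linearity_in_enhancer_signal(self, pei_setup):
        truth, _, _, _, enhancers, pei = pei_setup
        genes = [g.gene_id for g in truth.genes]
        rps1 = regulatory_potential(pei, enhancers, genes)
        import copy

        doubled = copy.deepcopy(enhancers)
        for e in doubled.enhancers:
            e.signal *= 2
        rps2 = regulatory_potential(pei, doubled, genes)
        assert np.allclose(rps2, 2 * rps1)

    def test_additivity_over_single_peis(self, pei_setup):
        truth, _, _, _, enhancers, pei = pei_setup
        genes = [g.gene_id for g in truth.genes]
        total = regulatory_potential(pei, enhancers, genes)
        acc = pd.Series(0.0, index=genes)
        for p in pei.peis:
            single = PeiSet("", [p])
            acc += regulatory_potential(single, enhancers, genes)
        assert np.allclose(total, acc)

    def test_planted_multiloop_genes_rank_high(self):
        truth = simulate_architecture(SimParams(seed=16, n_loops=60))
        m = simulate_contact_map(truth, 1, seed=131)
        oe, _ = balance_and_oe(m)
        k27, _ = simulate_peaks(truth, 1, seed=132)
        promoters = define_promoters(truth.genes, truth.binning)
        enhancers = define_enhancers(k27, promoters, truth.binning)
        pei = call_pei(oe, m, promoters, enhancers)
        rps = regulatory_potential(pei, enhancers,
                                   [g.gene_id for g in truth.genes])
        from collections import Counter

        loop_counts = Counter(truth.loop_gene[1])
        multi = [g for g, k in loop_counts.items() if k >= 2]
        if not multi:
            pytest.skip("architecture drew no multi-loop gene")
        cutoff = rps.quantile(0.9)
        assert np.mean([rps[g] >= cutoff for g in multi]) >= 0.5


class TestCovariation:
    def _expr(self, truth, seeds):
        c1 = simulate_expression(truth, 1, seed=seeds[0])
        c2 = simulate_expression(truth, 2, seed=seeds[1])
        lens = pd.Series({g.gene_id: g.length for g in truth.genes})
        return c1, c2, lens

    def test_equal_rps_selects_nothing(self, pei_setup):
        truth, _, _, _, enhancers, pei = pei_setup
        genes = [g.gene_id for g in truth.genes]
        rps = regulatory_potential(pei, enhancers, genes)
        c1, c2, lens = self._expr(truth, (71, 72))
        sel, table = rps_expression_covariation(rps, rps, c1, c2, lens)
        assert sel == []

    def test_threshold_monotonicity(self, pei_setup):
        truth, _, _, _, enhancers, pei = pei_setup
        genes = [g.gene_id for g in truth.genes]
        rps1 = regulatory_potential(pei, enhancers, genes)
        rng = np.random.default_rng(0)
        rps2 = pd.Series(rng.permutation(rps1.to_numpy()), index=genes)
        c1, c2, lens = self._expr(truth, (73, 74))
        sizes = [len(rps_expression_covariation(rps1, rps2, c1, c2, lens,
                                                fc_threshold=fc)[0])
                 for fc in (0.5, 1.0, 2.0)]
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_planted_covariation_recall(self):
        """100 planted genes with 4x RPS gain and 4x expression gain."""
        rng = np.random.default_rng(21)
        genes = [f"g{i}" for i in range(2000)]
        base_rps = pd.Series(rng.lognormal(1, 1, 2000), index=genes)
        rps1 = base_rps.copy()
        planted = genes[:100]
        rps1[planted] *= 4
        mu = rng.lognormal(np.log(200), 1, 2000)
        mu1 = mu.copy()
        mu1[:100] *= 4
        sigma = 0.3  # replicate noise on the log2 scale

        def draws(mean, seed):
            r = np.random.default_rng(seed)
            return pd.DataFrame(
                {f"r{k}": mean * 2 ** r.normal(0, sigma, 2000)
                 for k in range(4)}, index=genes)

        c1, c2 = draws(mu1, 1), draws(mu, 2)
        lens = pd.Series(1000.0, index=genes)
        sel, table = rps_expression_covariation(base_rps * 0 + rps1, base_rps,
                                                c1, c2, lens)
        recall = len(set(sel) & set(planted)) / 100
        assert recall >= 0.8

    def test_null_simulation_fdr_control(self):
        """No planted effects: selection stays within 2% of genes."""
        fracs = []
        for s in range(1, 6):
            p = SimParams(seed=s, flip_fraction=0.0, loop_expression_boost=1.0,
                          loop_shared_fraction=1.0)
            truth = simulate_architecture(p)
            genes = [g.gene_id for g in truth.genes]
            rng = np.random.default_rng(100 + s)
            rps = pd.Series(rng.lognormal(1, 1, len(genes)), index=genes)
            noisy = rps * rng.lognormal(0, 0.2, len(genes))
            c1 = simulate_expression(truth, 1, seed=200 + s)
            c2 = simulate_expression(truth, 2, seed=300 + s)
            lens = pd.Series({g.gene_id: g.length for g in truth.genes})
            sel, _ = rps_expression_covariation(rps, noisy, c1, c2, lens)
            fracs.append(len(sel) / len(genes))
        assert max(fracs) <= 0.02


class TestStrictFilter:
    def test_threshold_inclusion_and_exclusion(self):
        t1 = pd.DataFrame({"r1": [6.0, 6.0], "r2": [6.0, 6.0]},
                          index=["inc", "exc"])
        t2 = pd.DataFrame({"r1": [0.2, 0.6], "r2": [0.2, 0.6]},
                          index=["inc", "exc"])
        assert strict_expression_filter(t1, t2, hi=5, lo=0.5) == ["inc"]

    def test_matches_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(500)]
        t1 = pd.DataFrame(rng.lognormal(0.5, 2, (500, 3)), index=genes)
        t2 = pd.DataFrame(rng.lognormal(0.5, 2, (500, 3)), index=genes)
        got = set(strict_expression_filter(t1, t2, hi=5, lo=0.5))
        oracle = {g for g in genes
                  if t1.loc[g].mean() > 5 and t2.loc[g].mean() < 0.5}
        assert got == oracle

    def test_invalid_thresholds(self):
        t = pd.DataFrame({"r": [1.0]}, index=["g"])
        with pytest.raises(ValueError):
            strict_expression_filter(t, t, hi=0.5, lo=5)


class TestPromoterPromoter:
    def test_infinite_threshold_all_degrees_zero(self, pei_setup):
        truth, _, oe, promoters, _, _ = pei_setup
        tpm = pd.Series(np.linspace(1, 100, len(truth.genes)),
                        index=[g.gene_id for g in truth.genes])
        with pytest.warns(UserWarning, match="zero"):
            res = promoter_promoter_analysis(oe, promoters, tpm,
                                             oe_threshold=np.inf)
        assert (res["degree"] == 0).all()
        assert res["test_top_vs_bottom"] is None

    def test_no_self_edges_for_shared_bins(self):
        b = build_binning({"chr1": 1_000_000}, 100_000)
        genes = [GeneAnnotation("a", GenomicInterval("chr1", 10_000, 20_000, "+"), 10_000),
                 GeneAnnotation("b", GenomicInterval("chr1", 30_000, 40_000, "+"), 10_000)]
        genes += [GeneAnnotation(f"f{i}", GenomicInterval(
            "chr1", 100_000 * (i % 9) + 50_000, 100_000 * (i % 9) + 60_000, "+"),
            10_000) for i in range(20)]
        promoters = define_promoters(genes, b)
        n = b.n_bins
        oe = OEMatrix(b, sp.csr_matrix(np.ones((n, n)) * 5), np.zeros(n, bool))
        tpm = pd.Series(np.arange(len(genes), dtype=float) + 1,
                        index=[g.gene_id for g in genes])
        res = promoter_promoter_analysis(oe, promoters, tpm, min_dist=100_000)
        # genes a and b share bin 0: pairs within one bin are skipped, so the
        # degree of 'a' counts exactly the genes promoted from other bins
        ia = res["gene_ids"].index("a")
        expected = sum(1 for g in res["gene_ids"] if promoters.tss_bin[g] != 0)
        assert res["degree"][ia] == expected

    def test_planted_cluster_elevates_top_quartile(self):
        rng = np.random.default_rng(7)
        b = build_binning({"chr1": 20_000_000}, 100_000)
        genes = []
        for i in range(100):
            s = 200_000 * i + 10_000
            genes.append(GeneAnnotation(
                f"g{i}", GenomicInterval("chr1", s, s + 5_000, "+"), 5_000))
        promoters = define_promoters(genes, b)
        tpm = pd.Series(np.r_[np.full(75, 1.0), np.full(25, 100.0)],
                        index=[g.gene_id for g in genes])
        n = b.n_bins
        mat = np.zeros((n, n))
        hot = [promoters.tss_bin[f"g{i}"] for i in range(75, 100)]
        for x in hot:
            for y in hot:
                if x != y:
                    mat[x, y] = 5.0
        oe = OEMatrix(b, sp.csr_matrix(mat), np.zeros(n, bool))
        res = promoter_promoter_analysis(oe, promoters, tpm)
        med = res["median_degree_by_quartile"]
        assert med[3] > med[0]
        assert res["test_top_vs_bottom"].p < 0.05
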