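"""Compartment calling, saddle strength, switch regions, enrichment tests."""

import numpy as np
import pytest
import scipy.sparse as sp

from archcomp import (
    FeatureTrack,
    GenomicInterval,
    SimParams,
    build_binning,
    simulate_architecture,
    simulate_contact_map,
)
from archcomp.compartments import (
    CompartmentTrack,
    compartment_eigenvector,
    compartment_strength,
    gene_density_track,
    peak_region_enrichment,
    region_expression_shift,
    switch_regions,
)
from archcomp.contacts import OEMatrix
from archcomp.genome_model import GeneAnnotation
from archcomp.pipeline import balance_and_oe
from conftest import bins_covered


def make_oe(binning, dense):
    return OEMatrix(binning, sp.csr_matrix(dense),
                    np.zeros(binning.n_bins, dtype=bool))


def two_block_oe(n=40, within=2.0, cross=0.5):
    half = n // 2
    arr = np.full((n, n), cross)
    arr[:half, :half] = within
    arr[half:, half:] = within
    np.fill_diagonal(arr, 0.0)
    b = build_binning({"chr1": n * 100_000}, 100_000)
    return b, make_oe(b, arr)


class TestEigenvector:
    def test_planted_checkerboard_accuracy(self, default_truth, track_default):
        fin = np.isfinite(track_default.e1)
        acc = np.mean(track_default.label[fin]
                      == default_truth.comp_label[1][fin])
        assert acc >= 0.95

    def test_negated_anchor_flips_all_labels(self, default_truth, oe_default):
        density = gene_density_track(default_truth.genes, default_truth.binning)
        t1 = compartment_eigenvector(oe_default, density)
        t2 = compartment_eigenvector(oe_default, -density)
        fin = np.isfinite(t1.e1)
        assert (t1.label[fin] != t2.label[fin]).all()
        assert np.allclose(t1.e1[fin], -t2.e1[fin])

    def test_structureless_map_low_confidence(self):
        p = SimParams(seed=6, comp_factor=1.0, tad_boost=1.0, n_loops=0,
                      n_loops2=0, trans_level=0.0)
        truth = simulate_architecture(p)
        m = simulate_contact_map(truth, 1, seed=8)
        oe, _ = balance_and_oe(m)
        density = gene_density_track(truth.genes, truth.binning)
        t_null = compartment_eigenvector(oe, density)
        assert sum(t_null.low_confidence.values()) >= 2
        # the structured default map must carry more leading-eigenvalue weight
        p2 = SimParams(seed=6)
        truth2 = simulate_architecture(p2)
        m2 = simulate_contact_map(truth2, 1, seed=8)
        oe2, _ = balance_and_oe(m2)
        t_struct = compartment_eigenvector(
            oe2, gene_density_track(truth2.genes, truth2.binning))
        assert (np.mean(list(t_struct.eigenvalue_fraction.values()))
                > np.mean(list(t_null.eigenvalue_fraction.values())))

    def test_label_accuracy_monotone_in_comp_factor(self):
        gammas = (1.1, 1.25, 1.4)
        mean_acc = []
        for g in gammas:
            accs = []
            for s in range(1, 6):
                truth = simulate_architecture(SimParams(seed=s, comp_factor=g))
                m = simulate_contact_map(truth, 1, seed=40 + s)
                oe, _ = balance_and_oe(m)
                t = compartment_eigenvector(
                    oe, gene_density_track(truth.genes, truth.binning))
                fin = np.isfinite(t.e1)
                accs.append(np.mean(t.label[fin]
                                    == truth.comp_label[1][fin]))
            mean_acc.append(np.mean(accs))
        assert mean_acc[0] <= mean_acc[1] + 1e-9
        assert mean_acc[1] <= mean_acc[2] + 1e-9


class TestSaddleStrength:
    def test_uniform_oe_strength_one(self):
        n = 40
        b = build_binning({"chr1": n * 100_000}, 100_000)
        arr = np.ones((n, n))
        np.fill_diagonal(arr, 0.0)
        oe = make_oe(b, arr)
        e1 = np.linspace(-1, 1, n)
        track = CompartmentTrack(b, e1, {"chr1": 0.5}, "vector", {"chr1": False})
        res = compartment_strength(oe, track)
        assert res.aa == res.bb == res.ab == 1.0
        assert res.strength == 1.0

    def test_two_block_strength_sixteen(self):
        b, oe = two_block_oe()
        e1 = np.r_[np.ones(20), -np.ones(20)] * np.linspace(1.5, 0.5, 40)
        track = CompartmentTrack(b, e1, {"chr1": 0.5}, "vector", {"chr1": False})
        res = compartment_strength(oe, track)
        assert res.strength == pytest.approx(16.0, rel=1e-12)

    def test_strength_scale_invariant(self):
        b, oe = two_block_oe()
        e1 = np.r_[np.ones(20), -np.ones(20)] * np.linspace(1.5, 0.5, 40)
        track = CompartmentTrack(b, e1, {"chr1": 0.5}, "vector", {"chr1": False})
        s1 = compartment_strength(oe, track).strength
        oe2 = OEMatrix(b, oe.matrix * 13.0, oe.mask)
        s2 = compartment_strength(oe2, track).strength
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_invalid_quantile(self, oe_default, track_default):
        for q in (0.0, 0.5, 0.9):
            with pytest.raises(ValueError):
                compartment_strength(oe_default, track_default, q=q)

    def test_preset_strength_ordering(self):
        """Weak-compartment maps score below strong-compartment maps."""
        from archcomp.synthetic import (differentiated_like_params,
                                        stem_like_params)

        wins = 0
        for s in range(1, 11):
            vals = []
            for maker in (stem_like_params, differentiated_like_params):
                truth = simulate_architecture(maker(seed=s, depth=2e6))
                m = simulate_contact_map(truth, 1, seed=70 + s)
                oe, _ = balance_and_oe(m)
                t = compartment_eigenvector(
                    oe, gene_density_track(truth.genes, truth.binning))
                vals.append(compartment_strength(oe, t).strength)
            wins += vals[0] < vals[1]
        assert wins == 10


class TestSwitchRegions:
    def _track(self, binning, labels):
        e1 = np.where(np.asarray(labels) == "A", 1.0, -1.0)
        return CompartmentTrack(binning, e1, {}, "vector", {})

    def test_identical_tracks_empty(self, track_default):
        res = switch_regions(track_default, track_default)
        assert res.restricted_a == [] and res.restricted_b == []
        assert res.restricted_a_mb == 0.0

    def test_full_genome_switch(self):
        b = build_binning({"chr1": 90_000_000}, 100_000)
        t1 = self._track(b, ["A"] * b.n_bins)
        t2 = self._track(b, ["B"] * b.n_bins)
        res = switch_regions(t1, t2)
        assert res.restricted_a_mb == pytest.approx(90.0)
        assert res.restricted_b == []

    def test_symmetry_under_argument_swap(self, default_truth):
        b = default_truth.binning
        rng = np.random.default_rng(5)
        l1 = np.where(rng.random(b.n_bins) < 0.5, "A", "B")
        l2 = np.where(rng.random(b.n_bins) < 0.5, "A", "B")
        r12 = switch_regions(self._track(b, l1), self._track(b, l2))
        r21 = switch_regions(self._track(b, l2), self._track(b, l1))
        assert r12.restricted_a == r21.restricted_b
        assert r12.restricted_b == r21.restricted_a

    def test_masked_bins_break_runs(self):
        b = build_binning({"chr1": 500_000}, 100_000)
        e1 = np.array([1.0, 1.0, np.nan, 1.0, 1.0])
        t1 = CompartmentTrack(b, e1, {}, "vector", {})
        t2 = CompartmentTrack(b, -e1, {}, "vector", {})
        res = switch_regions(t1, t2)
        assert len(res.restricted_a) == 2

    def test_planted_flip_recovery_jaccard(self, default_truth, track_default):
        m2 = simulate_contact_map(default_truth, 2, seed=12)
        oe2, _ = balance_and_oe(m2)
        t2 = compartment_eigenvector(
            oe2, gene_density_track(default_truth.genes, default_truth.binning))
        res = switch_regions(track_default, t2)
        called = bins_covered(default_truth.binning,
                              res.restricted_a + res.restricted_b)
        truth_flips = default_truth.flipped_bins()
        jac = (called & truth_flips).sum() / (called | truth_flips).sum()
        assert jac >= 0.9


class TestRegionExpressionShift:
    def _genes(self, n=20):
        return [GeneAnnotation(f"g{i}", GenomicInterval("chr1", 1000 + 10_000 * i,
                                                        2000 + 10_000 * i, "+"), 1000)
                for i in range(n)]

    def test_identical_tables_unit_fc(self):
        genes = self._genes()
        regions = [GenomicInterval("chr1", 0, 300_000)]
        tpm = np.linspace(1, 20, len(genes))
        n, med, test = region_expression_shift(regions, genes, tpm, tpm)
        assert med == pytest.approx(1.0)
        assert n == len(genes)

    def test_no_genes_in_regions_rejected(self):
        genes = self._genes()
        with pytest.raises(ValueError):
            region_expression_shift([GenomicInterval("chr1", 900_000, 950_000)],
                                    genes, np.ones(20), np.ones(20))

    def test_shift_detected(self):
        rng = np.random.default_rng(2)
        genes = self._genes(200)
        regions = [GenomicInterval("chr1", 0, 2_000_000)]
        tpm2 = rng.lognormal(2, 1, 200)
        tpm1 = tpm2 * 1.5 * rng.lognormal(0, 0.05, 200)
        n, med, test = region_expression_shift(regions, genes, tpm1, tpm2)
        assert med == pytest.approx(1.5, rel=0.1)
        assert test.p < 1e-10


class TestPeakRegionEnrichment:
    def _binning(self):
        return build_binning({"chr1": 50_000_000, "chr2": 50_000_000}, 100_000)

    def test_uniform_peaks_null(self):
        b = self._binning()
        rng = np.random.default_rng(0)
        feats = []
        for chrom in b.chrom_names:
            for s in rng.integers(0, 49_998_000, size=200):
                feats.append((GenomicInterval(chrom, int(s), int(s) + 2000), 1.0))
        regions = [GenomicInterval("chr1", 0, 5_000_000),
                   GenomicInterval("chr2", 20_000_000, 25_000_000)]
        fold, p = peak_region_enrichment(FeatureTrack(feats), regions, b,
                                         n_perm=200, seed=1)
        assert fold == pytest.approx(1.0, abs=0.35)
        assert p > 0.05

    def test_all_peaks_inside_ten_percent_regions(self):
        b = self._binning()
        regions = [GenomicInterval("chr1", 0, 10_000_000)]  # 10% of 100 Mb
        feats = [(GenomicInterval("chr1", int(s), int(s) + 1000), 1.0)
                 for s in np.linspace(0, 9_990_000, 50)]
        fold, p = peak_region_enrichment(FeatureTrack(feats), regions, b,
                                         n_perm=200, seed=1)
        assert fold == pytest.approx(10.0, rel=1e-9)

    def test_planted_threefold_enrichment(self):
        b = self._binning()
        rng = np.random.default_rng(3)
        regions = [GenomicInterval("chr1", 0, 10_000_000),
                   GenomicInterval("chr2", 0, 10_000_000)]  # 20% of genome
        # fold 3 over 20% of the genome: probability inside = 3 * 0.2
        feats = []
        for _ in range(400):
            chrom = "chr1" if rng.random() < 0.5 else "chr2"
            if rng.random() < 0.6:
                s = int(rng.integers(0, 9_998_000))
            else:
                s = int(rng.integers(10_000_000, 49_998_000))
            feats.append((GenomicInterval(chrom, s, s + 2000), 1.0))
        fold, p = peak_region_enrichment(FeatureTrack(feats), regions, b,
                                         n_perm=1000, seed=4)
        assert 2.5 <= fold <= 3.5
        assert p <= 0.01

    def test_zero_peaks_rejected(self):
        b = self._binning()
        with pytest.raises(ValueError):
            peak_region_enrichment(FeatureTrack([]),
                                   [GenomicInterval("chr1", 0, 1_000_000)],
                                   b, n_perm=100, seed=0)
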