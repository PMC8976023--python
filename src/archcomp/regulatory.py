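"""Promoter/enhancer definition, promoter-enhancer interaction (PEI) calling,
regulatory potential scores, covariation with expression, and the
promoter-promoter contact graph.

A promoter is the TSS +/- flank; enhancers are signal peaks (H3K27ac) not
overlapping any promoter, optionally stitched and split into regular vs
super enhancers at the rank-curve elbow (ROSE-style). A PEI links a gene to
an enhancer on the same chromosome within ``max_dist`` when the O/E contact
between their bins clears a threshold with minimal raw-count support. The
regulatory potential score of a gene sums enhancer signal weighted by O/E
contact over its PEIs.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .genome_model import (
    FeatureTrack,
    GeneAnnotation,
    GenomeBinning,
    GenomicInterval,
    interval_to_bins,
)
from .contacts import ContactMatrix, OEMatrix
from .stats_report import TestResult, bh_fdr, de_lite, wilcoxon_rank_sum

__all__ = [
    "PromoterSet",
    "EnhancerSet",
    "Pei",
    "PeiSet",
    "define_promoters",
    "define_enhancers",
    "stitch_super",
    "call_pei",
    "pei_overlap",
    "regulatory_potential",
    "rps_expression_covariation",
    "strict_expression_filter",
    "promoter_promoter_analysis",
]


@dataclass
class PromoterSet:
    """One promoter interval (TSS +/- flank) and bin ids per gene."""

    binning: GenomeBinning
    promoters: dict[str, GenomicInterval]  # gene_id -> interval
    bins: dict[str, list[int]]
    tss_bin: dict[str, int]


@dataclass
class Enhancer:
    enhancer_id: str
    interval: GenomicInterval
    signal: float
    klass: str = "regular"  # or "super"


@dataclass
class EnhancerSet:
    binning: GenomeBinning
    enhancers: list[Enhancer]

    def bins_of(self, enh: Enhancer) -> list[int]:
        return interval_to_bins(self.binning, enh.interval)


@dataclass(frozen=True)
class Pei:
    gene_id: str
    enhancer_id: str
    enhancer_interval: GenomicInterval
    enhancer_bin: int
    distance_bins: int
    contact_oe: float
    raw_count: float
    enhancer_class: str = "regular"

    @property
    def key(self) -> tuple[str, str, int, int]:
        """Cross-condition identity: gene plus enhancer locus."""
        iv = self.enhancer_interval
        return (self.gene_id, iv.chrom, iv.start, iv.end)


@dataclass
class PeiSet:
    condition: str
    peis: list[Pei]

    def __len__(self) -> int:
        return len(self.peis)

    def keys(self) -> set:
        return {p.key for p in self.peis}

    def genes(self) -> set[str]:
        return {p.gene_id for p in self.peis}


def define_promoters(
    genes: list[GeneAnnotation], binning: GenomeBinning, flank: int = 2_000,
) -> PromoterSet:
    """Promoter = [TSS - flank, TSS + flank), clipped to the chromosome."""
    if flank <= 0:
        raise ValueError("flank must be > 0")
    promoters: dict[str, GenomicInterval] = {}
    bins: dict[str, list[int]] = {}
    tss_bin: dict[str, int] = {}
    for g in genes:
        chrom = g.interval.chrom
        length = binning.chrom_lengths[chrom]
        start = max(0, g.tss - flank)
        end = min(length, g.tss + flank)
        iv = GenomicInterval(chrom, start, end, g.interval.strand)
        promoters[g.gene_id] = iv
        bins[g.gene_id] = interval_to_bins(binning, iv)
        tss_bin[g.gene_id] = binning.bin_id(chrom, g.tss)
    return PromoterSet(binning, promoters, bins, tss_bin)


def define_enhancers(
    h3k27ac: FeatureTrack, promoters: PromoterSet, binning: GenomeBinning,
) -> EnhancerSet:
    """H3K27ac peaks minus any peak overlapping a promoter."""
    if len(h3k27ac) == 0:
        raise ValueError("empty peak set")
    prom_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in promoters.promoters.values():
        prom_by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[Enhancer] = []
    for idx, (iv, v) in enumerate(h3k27ac):
        if any(iv.overlaps(p) for p in prom_by_chrom.get(iv.chrom, ())):
            continue
        out.append(Enhancer(f"enh_{idx:05d}", iv, float(v)))
    return EnhancerSet(binning, out)


def stitch_super(enh: EnhancerSet, stitch_dist: int = 12_500) -> EnhancerSet:
    """Merge enhancers within ``stitch_dist`` and call super-enhancers.

    Stitched signal is the sum of member signals. The regular/super split is
    the elbow of the ascending rank-signal curve: the point of maximum
    distance to the chord from the first to the last point; entries strictly
    above the elbow rank are super.
    """
    by_chrom: dict[str, list[Enhancer]] = {}
    for e in enh.enhancers:
        by_chrom.setdefault(e.interval.chrom, []).append(e)
    stitched: list[Enhancer] = []
    k = 0
    for chrom in sorted(by_chrom):
        items = sorted(by_chrom[chrom], key=lambda e: e.interval.start)
        cur_start, cur_end = items[0].interval.start, items[0].interval.end
        cur_signal = items[0].signal
        for e in items[1:]:
            if e.interval.start - cur_end <= stitch_dist:
                cur_end = max(cur_end, e.interval.end)
                cur_signal += e.signal
            else:
                stitched.append(Enhancer(f"stitched_{k:05d}",
                                         GenomicInterval(chrom, cur_start, cur_end),
                                         cur_signal))
                k += 1
                cur_start, cur_end = e.interval.start, e.interval.end
                cur_signal = e.signal
        stitched.append(Enhancer(f"stitched_{k:05d}",
                                 GenomicInterval(chrom, cur_start, cur_end),
                                 cur_signal))
        k += 1

    if len(stitched) >= 3:
        sig = np.sort(np.array([e.signal for e in stitched]))
        order = np.argsort([e.signal for e in stitched], kind="stable")
        x = np.linspace(0.0, 1.0, len(sig))
        y = (sig - sig[0]) / (sig[-1] - sig[0]) if sig[-1] > sig[0] else sig * 0
        # perpendicular distance to the chord y = x
        dist = (x - y) / np.sqrt(2.0)
        elbow = int(np.argmax(dist))
        super_ranks = set(order[elbow + 1 :].tolist()) if dist[elbow] > 0 else set()
        for rank_pos in super_ranks:
            stitched[rank_pos].klass = "super"
    return EnhancerSet(enh.binning, stitched)


def call_pei(
    oe: OEMatrix,
    raw: ContactMatrix,
    promoters: PromoterSet,
    enhancers: EnhancerSet,
    max_dist: int = 1_000_000,
    oe_threshold: float = 2.0,
    min_raw: float = 3.0,
    condition: str = "",
) -> PeiSet:
    """Assign enhancers to promoters through elevated spatial contact.

    A (gene, enhancer) pair is kept when they share a chromosome, their bin
    separation is in (0, max_dist], the O/E contact reaches ``oe_threshold``
    and the raw count support reaches ``min_raw``. One record per pair (the
    best-supported bin combination wins).
    """
    binning = oe.binning
    max_bins = max(1, max_dist // binning.bin_size)
    rawm = raw.symmetric().tocsr()
    records: dict[tuple[str, str], Pei] = {}
    for chrom in binning.chrom_names:
        lo, hi = binning.chrom_bin_range(chrom)
        genes_here = [(g, bs) for g, bs in promoters.bins.items()
                      if lo <= bs[0] < hi]
        enh_here = [e for e in enhancers.enhancers if e.interval.chrom == chrom]
        if not genes_here or not enh_here:
            continue
        oed = oe.dense_chrom(chrom)
        rawd = rawm[lo:hi, lo:hi].toarray()
        for gene_id, pbins in genes_here:
            for e in enh_here:
                ebins = enhancers.bins_of(e)
                best = None
                for pb in pbins:
                    for eb in ebins:
                        d = abs(pb - eb)
                        if d == 0 or d > max_bins:
                            continue
                        o = oed[pb - lo, eb - lo]
                        r = rawd[pb - lo, eb - lo]
                        if np.isfinite(o) and o >= oe_threshold and r >= min_raw:
                            if best is None or o > best.contact_oe:
                                best = Pei(gene_id, e.enhancer_id, e.interval,
                                           eb, d, float(o), float(r), e.klass)
                if best is not None:
                    records[(gene_id, e.enhancer_id)] = best
    return PeiSet(condition, list(records.values()))


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def pei_overlap(pei1, pei2) -> tuple[int, float, float]:
    """Shared PEIs and the percentage each set shares with the other.

    Accepts PeiSet objects or raw key collections. Returns (shared count,
    100*shared/|set1|, 100*shared/|set2|), percentages rounded half-up to
    two decimals.
    """
    k1 = pei1.keys() if isinstance(pei1, PeiSet) else set(pei1)
    k2 = pei2.keys() if isinstance(pei2, PeiSet) else set(pei2)
    if not k1 or not k2:
        raise ValueError("empty PEI set")
    shared = len(k1 & k2)
    return shared, _round2(100.0 * shared / len(k1)), _round2(100.0 * shared / len(k2))


def regulatory_potential(
    pei: PeiSet, enhancers: EnhancerSet, all_genes: list[str] | None = None,
) -> pd.Series:
    """RPS(g) = sum over the gene's PEIs of enhancer signal x contact O/E."""
    signal = {e.enhancer_id: e.signal for e in enhancers.enhancers}
    rps: dict[str, float] = {}
    for p in pei.peis:
        rps[p.gene_id] = rps.get(p.gene_id, 0.0) + signal[p.enhancer_id] * p.contact_oe
    index = all_genes if all_genes is not None else sorted(rps)
    return pd.Series([rps.get(g, 0.0) for g in index], index=index, name="rps")


def rps_expression_covariation(
    rps1: pd.Series,
    rps2: pd.Series,
    expr_counts1: pd.DataFrame,
    expr_counts2: pd.DataFrame,
    gene_lengths: pd.Series,
    fc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
    epsilon: float = 1.0,
) -> tuple[list[str], pd.DataFrame]:
    """Genes whose RPS gain and expression gain co-occur.

    Selected genes satisfy log2((RPS1+eps)/(RPS2+eps)) > fc_threshold and
    expression log2FC > fc_threshold at BH q < fdr_threshold from the
    moderated t-test on log2(TPM+1). Returns (gene list, per-gene table).
    """
    from .stats_report import tpm as tpm_fn

    if expr_counts1.shape[1] < 2 or expr_counts2.shape[1] < 2:
        raise ValueError("need >= 2 replicates per condition")
    genes = rps1.index
    tpm1 = tpm_fn(expr_counts1, gene_lengths)
    tpm2 = tpm_fn(expr_counts2, gene_lengths)
    de = de_lite(np.log2(tpm1 + 1).loc[genes], np.log2(tpm2 + 1).loc[genes])
    rps_fc = np.log2((rps1 + epsilon) / (rps2.reindex(genes) + epsilon))
    table = pd.DataFrame({
        "rps_log2fc": rps_fc,
        "expr_log2fc": de["log2fc"],
        "p": de["p"],
        "q": de["q"],
    })
    sel = table[(table["rps_log2fc"] > fc_threshold)
                & (table["expr_log2fc"] > fc_threshold)
                & (table["q"] < fdr_threshold)]
    return sel.index.tolist(), table


def strict_expression_filter(
    tpm1: pd.DataFrame, tpm2: pd.DataFrame, hi: float = 5.0, lo: float = 0.5,
) -> list[str]:
    """Genes with mean TPM above ``hi`` in condition 1 and below ``lo`` in 2."""
    if hi <= lo:
        raise ValueError("hi must exceed lo")
    common = tpm1.index.intersection(tpm2.index)
    m1 = tpm1.loc[common].mean(axis=1)
    m2 = tpm2.loc[common].mean(axis=1)
    return common[(m1 > hi) & (m2 < lo)].tolist()


def promoter_promoter_analysis(
    oe: OEMatrix,
    promoters: PromoterSet,
    expr_tpm: pd.Series,
    oe_threshold: float = 2.0,
    min_dist: int = 40_000,
) -> dict:
    """Intrachromosomal promoter-promoter contact graph, stratified by
    expression quartile.

    Edges connect promoter bins (one per gene, at the TSS) with contact
    O/E >= threshold at separations >= min_dist on the same chromosome;
    promoter pairs sharing a bin are not self-edges. Reports per-gene degree,
    median degree per expression quartile, and a rank-sum test of top vs
    bottom quartile degrees.
    """
    gene_ids = [g for g in promoters.tss_bin if g in expr_tpm.index]
    if len(gene_ids) < 20:
        raise ValueError("need >= 20 genes with expression")
    binning = promoters.binning
    min_bins = max(1, min_dist // binning.bin_size)
    bins = np.array([promoters.tss_bin[g] for g in gene_ids])
    chrom_idx = binning.chrom_of_bins()[bins]
    oem = oe.matrix
    degree = np.zeros(len(gene_ids), dtype=int)
    for a in range(len(gene_ids)):
        same = (chrom_idx == chrom_idx[a])
        cand = np.nonzero(same & (np.abs(bins - bins[a]) >= min_bins))[0]
        cand = cand[cand != a]
        if len(cand) == 0:
            continue
        row = oem.getrow(bins[a]).toarray().ravel()
        degree[a] = int(np.count_nonzero(row[bins[cand]] >= oe_threshold))

    expr = expr_tpm.loc[gene_ids].to_numpy(dtype=float)
    quart = pd.qcut(pd.Series(expr).rank(method="first"), 4, labels=False)
    med = {int(qq): float(np.median(degree[quart == qq])) for qq in range(4)}
    top = degree[quart == 3]
    bot = degree[quart == 0]
    if degree.sum() == 0:
        import warnings

        warnings.warn("all promoter-promoter degrees are zero", stacklevel=2)
        test = None
    else:
        test = wilcoxon_rank_sum(top, bot)
    return {
        "gene_ids": gene_ids,
        "degree": degree,
        "median_degree_by_quartile": med,
        "test_top_vs_bottom": test,
    }
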