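"""Two-condition synthetic Hi-C / expression / peak generator with ground truth.

The generator plants the architectural features the downstream statistics are
meant to detect: power-law distance decay, a checkerboard A/B compartment
pattern (alternating blocks with geometric run lengths), block-diagonal TADs,
promoter-enhancer loops, a flat interchromosomal background, Poisson-sampled
sequencing depth, and negative-binomial expression with compartment-linked
fold changes. Condition 2 differs from condition 1 by flipping a fraction of
compartment bins (as contiguous runs), scaling TAD strength, changing the
trans-contact level, and using its own planted loop set.

Expected cis contact for bins i < j on one chromosome:

    E[c_ij]  ∝  |i-j|^(-alpha) * gamma^[same compartment] * tau^[same TAD]
                * lam^[planted loop pair]

scaled so the cis total equals ``depth``; trans pairs share a flat
expectation sized so the trans fraction of all contacts is ``trans_level``.
Observed counts are Poisson draws around these expectations.

Two presets bracket the biology under study: ``stem_like`` (weak
compartments, weak TADs, low trans contact, fewer loops — a dispersed,
pluripotent-like nucleus) and ``differentiated_like`` (the converse).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genome_model import (
    FeatureTrack,
    GeneAnnotation,
    GenomeBinning,
    GenomicInterval,
    build_binning,
)
from .contacts import ContactMatrix

__all__ = [
    "SimParams",
    "ArchitectureTruth",
    "simulate_architecture",
    "simulate_contact_map",
    "simulate_expression",
    "simulate_peaks",
    "stem_like_params",
    "differentiated_like_params",
]


@dataclass(frozen=True)
class SimParams:
    """Simulator contract; all defaults give a desk-scale, minutes-fast run.

    The default genome is 3 chromosomes x 30 Mb at 100-kb bins (900 bins);
    TAD-focused analyses use a finer single-chromosome genome built with
    ``tad_genome=True`` (1 x 10 Mb at 20 kb, 500 bins).
    """

    decay_exponent: float = 1.0      # alpha, power-law P(s) ~ s^-alpha
    comp_factor: float = 1.4         # gamma >= 1, same-compartment multiplier
    tad_boost: float = 1.5           # tau >= 1, same-TAD multiplier
    loop_boost: float = 3.0          # lambda >= 1, planted-loop multiplier
    loop_expression_boost: float = 4.0  # expression gain of cond1-only loop genes
    depth: float = 5e6               # total expected cis reads
    trans_level: float = 0.1         # t in [0,1): trans fraction of contacts
    flip_fraction: float = 0.1       # compartment bins flipped in condition 2
    tad_boost2: float | None = None  # condition-2 tau (defaults to tad_boost)
    n_loops: int = 50                # planted PEIs in condition 1
    n_loops2: int | None = None      # condition-2 count (defaults to n_loops)
    loop_shared_fraction: float = 0.5  # loops of cond 2 kept from cond 1
    trans_level2: float | None = None
    fc_restricted_a: float = 1.48    # expression FC planted on A->B flip genes
    fc_restricted_b: float = 0.59    # expression FC planted on B->A flip genes
    expression_dispersion: float = 0.05  # NB dispersion (var = mu + disp*mu^2)
    base_expression_mean: float = 200.0
    n_genes: int = 2000
    n_replicates: int = 4
    peak_background_per_mb: float = 0.5
    comp_run_mean_bins: float = 10.0  # geometric mean run length of A/B blocks
    tad_mean_bins: float = 25.0
    n_chroms: int = 3
    chrom_length: int = 30_000_000
    bin_size: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.trans_level < 1):
            raise ValueError("trans_level must be in [0, 1)")
        if not (0 <= self.flip_fraction < 1):
            raise ValueError("flip_fraction must be in [0, 1)")
        for name in ("comp_factor", "tad_boost", "loop_boost"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.expression_dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be > 0")


def stem_like_params(**overrides) -> SimParams:
    """Dispersed, pluripotent-like preset: weak structure, few loops."""
    base = dict(comp_factor=1.2, tad_boost=1.5, trans_level=0.05, n_loops=40)
    base.update(overrides)
    return SimParams(**base)


def differentiated_like_params(**overrides) -> SimParams:
    """Compact, differentiated-like preset: strong structure, more loops."""
    base = dict(comp_factor=1.5, tad_boost=2.0, trans_level=0.25, n_loops=60)
    base.update(overrides)
    return SimParams(**base)


@dataclass
class ArchitectureTruth:
    """Planted ground truth shared by the four generators."""

    binning: GenomeBinning
    params: SimParams
    comp_label: dict[int, np.ndarray]          # condition -> per-bin 'A'/'B'
    tads: dict[int, list[GenomicInterval]]     # condition -> TAD intervals
    tad_id: dict[int, np.ndarray]              # condition -> per-bin TAD id, -1 outside
    tad_boost: dict[int, float]
    planted_peis: dict[int, list[tuple[int, int, float]]]  # (prom bin, enh bin, boost)
    genes: list[GeneAnnotation]
    gene_mean: dict[int, np.ndarray]           # condition -> per-gene NB mean
    trans_level: dict[int, float]
    loop_gene: dict[int, list[str]] = field(default_factory=dict)  # gene per loop

    @property
    def conditions(self) -> tuple[int, int]:
        return (1, 2)

    def flipped_bins(self) -> np.ndarray:
        return self.comp_label[1] != self.comp_label[2]

    def restricted_a_bins(self) -> np.ndarray:
        """Bins A in condition 1 but B in condition 2."""
        return (self.comp_label[1] == "A") & (self.comp_label[2] == "B")

    def restricted_b_bins(self) -> np.ndarray:
        return (self.comp_label[1] == "B") & (self.comp_label[2] == "A")


def _geometric_blocks(rng: np.random.Generator, n_bins: int, mean_run: float,
                      start_label: str) -> np.ndarray:
    """Alternating A/B blocks with geometric run lengths."""
    labels = np.empty(n_bins, dtype="<U1")
    pos = 0
    cur = start_label
    while pos < n_bins:
        run = rng.geometric(1.0 / mean_run)
        labels[pos : pos + run] = cur
        pos += run
        cur = "B" if cur == "A" else "A"
    return labels


def simulate_architecture(params: SimParams) -> ArchitectureTruth:
    """Draw the planted two-condition architecture for a desk-scale genome."""
    rng = np.random.default_rng(params.seed)
    sizes = {f"chr{i+1}": params.chrom_length for i in range(params.n_chroms)}
    binning = build_binning(sizes, params.bin_size)
    n = binning.n_bins

    # --- compartments: alternating geometric blocks per chromosome -------
    lab1 = np.empty(n, dtype="<U1")
    for chrom in binning.chrom_names:
        lo, hi = binning.chrom_bin_range(chrom)
        start = "A" if rng.random() < 0.5 else "B"
        lab1[lo:hi] = _geometric_blocks(rng, hi - lo, params.comp_run_mean_bins, start)

    # condition 2: flip contiguous runs totalling ~flip_fraction of bins
    lab2 = lab1.copy()
    target = int(round(params.flip_fraction * n))
    flipped = np.zeros(n, dtype=bool)
    n_flipped = 0
    attempts = 0
    while n_flipped < target and attempts < 10_000:
        attempts += 1
        chrom = binning.chrom_names[rng.integers(len(binning.chrom_names))]
        lo, hi = binning.chrom_bin_range(chrom)
        run = int(rng.geometric(1.0 / params.comp_run_mean_bins))
        run = min(run, target - n_flipped, hi - lo)
        if run <= 0:
            continue
        s = int(rng.integers(lo, hi - run + 1))
        seg = slice(s, s + run)
        if flipped[seg].any():
            continue
        flipped[seg] = True
        n_flipped += run
    lab2[flipped] = np.where(lab2[flipped] == "A", "B", "A")

    # --- TADs: same boundaries in both conditions, different strength ----
    tads: list[GenomicInterval] = []
    tad_id = np.full(n, -1, dtype=int)
    next_id = 0
    for chrom in binning.chrom_names:
        lo, hi = binning.chrom_bin_range(chrom)
        pos = lo
        floor = max(5, int(round(0.4 * params.tad_mean_bins)))
        while pos < hi:
            # shifted geometric: enforces a realistic minimum domain size so
            # domains remain resolvable at the insulation window scale
            size = floor + int(rng.geometric(1.0 / (params.tad_mean_bins - floor)))
            end = min(pos + size, hi)
            if hi - end < 5:  # absorb a too-short trailing domain
                end = hi
            iv_start = (pos - lo) * binning.bin_size
            iv_end = min((end - lo) * binning.bin_size,
                         binning.chrom_lengths[chrom])
            tads.append(GenomicInterval(chrom, iv_start, iv_end))
            tad_id[pos:end] = next_id
            next_id += 1
            pos = end
    tau2 = params.tad_boost2 if params.tad_boost2 is not None else params.tad_boost

    # --- genes: TSS placement enriched in compartment A -----------------
    # gene-dense bins define active chromatin, so the orientation anchor
    # (gene density) correlates with A in both conditions
    genes: list[GeneAnnotation] = []
    a_bins = np.nonzero(lab1 == "A")[0]
    b_bins = np.nonzero(lab1 == "B")[0]
    for g in range(params.n_genes):
        pool = a_bins if (rng.random() < 0.8 and len(a_bins)) else b_bins
        if len(pool) == 0:
            pool = np.arange(n)
        home = int(pool[rng.integers(len(pool))])
        iv = binning.bin_interval(home)
        length = int(rng.integers(2_000, 50_000))
        lo_pos = iv.start
        hi_pos = max(lo_pos + 1, min(iv.end, binning.chrom_lengths[iv.chrom] - length) )
        start = int(rng.integers(lo_pos, hi_pos))
        end = min(start + length, binning.chrom_lengths[iv.chrom])
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneAnnotation(
                gene_id=f"gene_{g:05d}",
                interval=GenomicInterval(iv.chrom, start, end, strand),
                length=length,
            )
        )

    # --- planted promoter-enhancer loops --------------------------------
    n2 = params.n_loops2 if params.n_loops2 is not None else params.n_loops
    max_off = max(2, 1_000_000 // params.bin_size)
    gene_bins = np.array([binning.bin_id(g.interval.chrom, g.tss) for g in genes])

    # enhancers are distal active-chromatin elements: planted enhancer bins
    # share the promoter's compartment (usually A)
    def draw_loops(k: int, exclude: set[tuple[int, int]]) -> tuple[
            list[tuple[int, int, float]], list[str]]:
        loops: list[tuple[int, int, float]] = []
        gene_ids: list[str] = []
        used = set(exclude)
        attempts = 0
        while len(loops) < k and attempts < 100_000:
            attempts += 1
            gi = int(rng.integers(len(genes)))
            pbin = int(gene_bins[gi])
            chrom = genes[gi].interval.chrom
            lo, hi = binning.chrom_bin_range(chrom)
            off = int(rng.integers(2, max_off + 1)) * (1 if rng.random() < 0.5 else -1)
            ebin = pbin + off
            if not (lo <= ebin < hi) or (pbin, ebin) in used:
                continue
            if lab1[ebin] != lab1[pbin]:
                continue
            used.add((pbin, ebin))
            loops.append((pbin, ebin, params.loop_boost))
            gene_ids.append(genes[gi].gene_id)
        return loops, gene_ids

    loops1, lgenes1 = draw_loops(params.n_loops, set())
    n_keep = int(round(params.loop_shared_fraction * min(params.n_loops, n2)))
    kept = loops1[:n_keep]
    kept_genes = lgenes1[:n_keep]
    extra, extra_genes = draw_loops(
        n2 - n_keep, {(p, e) for p, e, _ in loops1}
    )
    loops2 = kept + extra
    lgenes2 = kept_genes + extra_genes

    # --- expression means with compartment-linked fold changes ----------
    base = rng.lognormal(mean=np.log(params.base_expression_mean), sigma=1.0,
                         size=params.n_genes)
    mean2 = base.copy()
    mean1 = base.copy()
    restricted_a = (lab1 == "A") & (lab2 == "B")
    restricted_b = (lab1 == "B") & (lab2 == "A")
    in_ra = restricted_a[gene_bins]
    in_rb = restricted_b[gene_bins]
    mean1[in_ra] *= params.fc_restricted_a
    mean1[in_rb] *= params.fc_restricted_b

    # genes that gain a condition-1-specific enhancer loop also gain
    # expression: the covariation the RPS analysis is designed to detect
    only1 = set(lgenes1) - set(lgenes2)
    if params.loop_expression_boost != 1.0 and only1:
        gid_to_idx = {g.gene_id: k for k, g in enumerate(genes)}
        for gid in only1:
            mean1[gid_to_idx[gid]] *= params.loop_expression_boost

    t2 = params.trans_level2 if params.trans_level2 is not None else params.trans_level
    return ArchitectureTruth(
        binning=binning,
        params=params,
        comp_label={1: lab1, 2: lab2},
        tads={1: tads, 2: tads},
        tad_id={1: tad_id, 2: tad_id},
        tad_boost={1: params.tad_boost, 2: tau2},
        planted_peis={1: loops1, 2: loops2},
        genes=genes,
        gene_mean={1: mean1, 2: mean2},
        trans_level={1: params.trans_level, 2: t2},
        loop_gene={1: lgenes1, 2: lgenes2},
    )


def _cis_expectation(truth: ArchitectureTruth, condition: int,
                     chrom: str) -> np.ndarray:
    """Dense expected cis matrix (unscaled) for one chromosome."""
    p = truth.params
    binning = truth.binning
    lo, hi = binning.chrom_bin_range(chrom)
    nb = hi - lo
    d = np.abs(np.subtract.outer(np.arange(nb), np.arange(nb))).astype(float)
    with np.errstate(divide="ignore"):
        exp = d ** (-p.decay_exponent)
    np.fill_diagonal(exp, 0.0)  # self-ligation masked

    lab = truth.comp_label[condition][lo:hi]
    same_comp = lab[:, None] == lab[None, :]
    exp *= np.where(same_comp, p.comp_factor, 1.0)

    tid = truth.tad_id[condition][lo:hi]
    same_tad = (tid[:, None] == tid[None, :]) & (tid[:, None] >= 0)
    exp *= np.where(same_tad, truth.tad_boost[condition], 1.0)

    for pbin, ebin, boost in truth.planted_peis[condition]:
        if lo <= pbin < hi and lo <= ebin < hi:
            exp[pbin - lo, ebin - lo] *= boost
            exp[ebin - lo, pbin - lo] *= boost
    return exp


def simulate_contact_map(
    truth: ArchitectureTruth, condition: int, seed: int | None = None,
    name: str = "", depth: float | None = None,
) -> ContactMatrix:
    """Poisson-sample a symmetric genome-wide contact map for one condition.

    ``seed`` defaults to the architecture seed; pass distinct seeds to draw
    replicate maps from the same truth.
    """
    if condition not in (1, 2):
        raise ValueError(f"unknown condition {condition}")
    p = truth.params
    depth = p.depth if depth is None else depth
    if depth <= 0:
        raise ValueError("depth must be > 0")
    rng = np.random.default_rng(p.seed if seed is None else seed)
    binning = truth.binning
    n = binning.n_bins

    blocks: dict[str, np.ndarray] = {}
    cis_total = 0.0
    for chrom in binning.chrom_names:
        e = _cis_expectation(truth, condition, chrom)
        blocks[chrom] = e
        cis_total += np.triu(e, 1).sum()
    cis_scale = depth / cis_total

    rows, cols, data = [], [], []
    for chrom in binning.chrom_names:
        lo, hi = binning.chrom_bin_range(chrom)
        e = np.triu(blocks[chrom] * cis_scale, 1)
        counts = rng.poisson(e)
        i, j = np.nonzero(counts)
        rows.append(i + lo)
        cols.append(j + lo)
        data.append(counts[i, j])

    t = truth.trans_level[condition]
    if t > 0 and len(binning.chrom_names) > 1:
        # flat trans expectation sized so trans/(cis+trans) ~= t
        chrom_idx = binning.chrom_of_bins()
        n_trans_pairs = (n * n - sum(
            binning.n_bins_per_chrom[c] ** 2 for c in binning.chrom_names)) // 2
        trans_total = depth * t / (1 - t)
        per_pair = trans_total / n_trans_pairs
        # sample trans counts pairwise per chromosome pair (upper blocks)
        for a in range(len(binning.chrom_names)):
            for b in range(a + 1, len(binning.chrom_names)):
                la, ha = binning.chrom_bin_range(binning.chrom_names[a])
                lb, hb = binning.chrom_bin_range(binning.chrom_names[b])
                counts = rng.poisson(per_pair, size=(ha - la, hb - lb))
                i, j = np.nonzero(counts)
                rows.append(i + la)
                cols.append(j + lb)
                data.append(counts[i, j])

    rows = np.concatenate(rows) if rows else np.array([], dtype=int)
    cols = np.concatenate(cols) if cols else np.array([], dtype=int)
    data = np.concatenate(data) if data else np.array([], dtype=float)
    m = sp.coo_matrix((data.astype(float), (rows, cols)), shape=(n, n)).tocsr()
    return ContactMatrix(binning, m, name=name or f"cond{condition}",
                         condition=str(condition))


def simulate_expression(
    truth: ArchitectureTruth, condition: int, seed: int | None = None,
) -> pd.DataFrame:
    """Negative-binomial replicate counts (genes x replicates) for a condition.

    Var = mu + dispersion * mu^2; genes whose TSS lies in a condition-
    restricted compartment region carry the planted fold change.
    """
    p = truth.params
    if p.n_replicates < 2:
        raise ValueError("need n_replicates >= 2")
    rng = np.random.default_rng((p.seed if seed is None else seed))
    mu = truth.gene_mean[condition]
    disp = p.expression_dispersion
    # NB as Gamma-Poisson: shape r = 1/disp, scale mu*disp
    r = 1.0 / disp
    lam = rng.gamma(shape=r, scale=(mu * disp)[:, None],
                    size=(len(mu), p.n_replicates))
    counts = rng.poisson(lam)
    return pd.DataFrame(
        counts,
        index=[g.gene_id for g in truth.genes],
        columns=[f"cond{condition}_rep{k+1}" for k in range(p.n_replicates)],
    )


def simulate_peaks(
    truth: ArchitectureTruth, condition: int, seed: int | None = None,
) -> tuple[FeatureTrack, FeatureTrack]:
    """(H3K27ac, ATAC) peak tracks: one peak per planted enhancer bin plus
    uniform Poisson background at ``peak_background_per_mb``."""
    p = truth.params
    rng = np.random.default_rng((p.seed if seed is None else seed))
    binning = truth.binning
    peak_w = min(2_000, binning.bin_size // 2)

    # planted enhancer peaks must stay distal: avoid TSS neighborhoods so the
    # peak is not swallowed by a promoter during enhancer definition
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in truth.genes:
        tss_by_chrom.setdefault(g.interval.chrom, []).append(g.tss)
    tss_by_chrom = {c: np.sort(np.asarray(v)) for c, v in tss_by_chrom.items()}
    tss_margin = 2_500 + peak_w

    def peak_at(bin_id: int) -> GenomicInterval:
        iv = binning.bin_interval(bin_id)
        tss = tss_by_chrom.get(iv.chrom, np.array([]))
        candidates = [(iv.start + iv.end) // 2]
        if iv.end - iv.start > 3 * peak_w:
            candidates += list(rng.integers(iv.start + peak_w,
                                            iv.end - peak_w, size=20))
        for center in candidates:
            if len(tss) == 0 or np.min(np.abs(tss - center)) > tss_margin:
                break
        return GenomicInterval(iv.chrom, int(center) - peak_w // 2,
                               int(center) + peak_w // 2)

    k27: list[tuple[GenomicInterval, float]] = []
    for _, ebin, _ in truth.planted_peis[condition]:
        signal = float(rng.lognormal(mean=np.log(10.0), sigma=0.5))
        k27.append((peak_at(ebin), signal))

    for chrom in binning.chrom_names:
        length = binning.chrom_lengths[chrom]
        n_bg = rng.poisson(p.peak_background_per_mb * length / 1e6)
        for _ in range(n_bg):
            s = int(rng.integers(0, length - peak_w))
            signal = float(rng.lognormal(mean=np.log(3.0), sigma=0.5))
            k27.append((GenomicInterval(chrom, s, s + peak_w), signal))

    atac: list[tuple[GenomicInterval, float]] = []
    for iv, v in k27:  # accessibility mirrors active chromatin
        atac.append((iv, v * float(rng.lognormal(0.0, 0.25))))
    for g in truth.genes:  # promoters are accessible
        if rng.random() < 0.5:
            tss = g.tss
            lo = max(0, tss - peak_w // 2)
            atac.append((
                GenomicInterval(g.interval.chrom, lo, lo + peak_w),
                float(rng.lognormal(np.log(5.0), 0.5)),
            ))
    return FeatureTrack(k27), FeatureTrack(atac)
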