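"""A/B compartment calling and compartment-linked differential statistics.

The per-bin eigenvector E1 is the leading eigenvector of the Pearson
correlation matrix of the intra-chromosomal O/E map (masked bins removed),
computed per chromosome and concatenated; its sign is anchored so it
correlates positively with an activity track (gene density or ATAC signal).
Bins with E1 > 0 are compartment A. Compartmentalization strength is the
saddle statistic AA*BB/AB^2 over the extreme E1 quantiles. Regions that are
A in one condition but B in the other ("restricted" regions) are merged
runs of switching bins; gene expression shifts and peak enrichment inside
them are tested with a signed-rank test and a circular-shift permutation
test respectively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genome_model import FeatureTrack, GeneAnnotation, GenomeBinning, GenomicInterval, interval_to_bins
from .contacts import OEMatrix
from .stats_report import TestResult, signed_rank_one_sample

__all__ = [
    "CompartmentTrack",
    "SaddleResult",
    "SwitchRegions",
    "compartment_eigenvector",
    "compartment_strength",
    "switch_regions",
    "region_expression_shift",
    "peak_region_enrichment",
    "gene_density_track",
]

MIN_EIGVAL_GAP = 1e-9
LOW_CONFIDENCE_VARIANCE = 0.05  # leading-eigenvalue share of total variance


@dataclass
class CompartmentTrack:
    """Per-bin E1 with A/B labels; NaN E1 marks masked bins."""

    binning: GenomeBinning
    e1: np.ndarray
    eigenvalue_fraction: dict[str, float]  # per-chromosome variance explained
    orientation_reference: str
    low_confidence: dict[str, bool]

    @property
    def label(self) -> np.ndarray:
        """'A' where E1 > 0, 'B' where E1 <= 0, 'masked' where NaN."""
        out = np.where(self.e1 > 0, "A", "B").astype("<U6")
        out[~np.isfinite(self.e1)] = "masked"
        return out


@dataclass(frozen=True)
class SaddleResult:
    aa: float
    bb: float
    ab: float

    @property
    def strength(self) -> float:
        return self.aa * self.bb / self.ab**2


@dataclass
class SwitchRegions:
    """Regions switching compartment between two conditions.

    ``restricted_a``: A in condition 1 but B in condition 2; ``restricted_b``
    is the converse. Intervals are merged maximal runs of switching bins.
    """

    restricted_a: list[GenomicInterval]
    restricted_b: list[GenomicInterval]

    @staticmethod
    def _mb(ivs: list[GenomicInterval]) -> float:
        return sum(len(iv) for iv in ivs) / 1e6

    @property
    def restricted_a_mb(self) -> float:
        return self._mb(self.restricted_a)

    @property
    def restricted_b_mb(self) -> float:
        return self._mb(self.restricted_b)


def gene_density_track(genes: list[GeneAnnotation], binning: GenomeBinning) -> np.ndarray:
    """Genes-per-bin count vector, the default E1 orientation anchor."""
    dens = np.zeros(binning.n_bins)
    for g in genes:
        for b in interval_to_bins(binning, g.interval):
            dens[b] += 1.0
    return dens


def _bin_signal(track: FeatureTrack | np.ndarray, binning: GenomeBinning) -> np.ndarray:
    if isinstance(track, np.ndarray):
        if track.shape != (binning.n_bins,):
            raise ValueError("activity vector length does not match binning")
        return track.astype(float)
    sig = np.zeros(binning.n_bins)
    for iv, v in track:
        for b in interval_to_bins(binning, iv):
            sig[b] += max(v, 1.0)  # presence counts even for unscored peaks
    return sig


def compartment_eigenvector(
    oe: OEMatrix,
    active: FeatureTrack | np.ndarray,
    min_bins: int = 10,
) -> CompartmentTrack:
    """Leading eigenvector of the per-chromosome O/E correlation matrix.

    Sign per chromosome is chosen so that E1 correlates non-negatively with
    the binned activity signal; A is E1 > 0.
    """
    binning = oe.binning
    signal = _bin_signal(active, binning)
    e1 = np.full(binning.n_bins, np.nan)
    var_frac: dict[str, float] = {}
    low_conf: dict[str, bool] = {}
    for chrom in binning.chrom_names:
        lo, hi = binning.chrom_bin_range(chrom)
        dense = oe.dense_chrom(chrom)
        good = np.isfinite(dense).any(axis=1) & ~oe.mask[lo:hi]
        if good.sum() < min_bins:
            raise ValueError(f"{chrom}: fewer than {min_bins} unmasked bins")
        sub = dense[np.ix_(good, good)]
        sub = np.nan_to_num(sub, nan=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            corr = np.corrcoef(sub)
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 1.0)
        vals, vecs = np.linalg.eigh(corr)
        if vals[-1] - vals[-2] < MIN_EIGVAL_GAP:
            raise ValueError(f"{chrom}: ambiguous E1 (degenerate leading eigenvalues)")
        v = vecs[:, -1]
        frac = float(vals[-1] / np.sum(np.abs(vals)))
        sig = signal[lo:hi][good]
        if np.std(sig) > 0 and np.std(v) > 0:
            c = np.corrcoef(v, sig)[0, 1]
            if c < 0:
                v = -v
        full = np.full(hi - lo, np.nan)
        full[good] = v
        e1[lo:hi] = full
        var_frac[chrom] = frac
        low_conf[chrom] = frac < LOW_CONFIDENCE_VARIANCE
    ref = "vector" if isinstance(active, np.ndarray) else "feature_track"
    return CompartmentTrack(binning, e1, var_frac, ref, low_conf)


def compartment_strength(
    oe: OEMatrix, track: CompartmentTrack, q: float = 0.2,
    min_separation: int = 2,
) -> SaddleResult:
    """Saddle strength AA*BB/AB^2 over the extreme E1 quantiles.

    Bins are ranked genome-wide by E1; AA pools intra-chromosomal O/E among
    the top-q fraction, BB among the bottom-q, AB across, using only pairs
    separated by more than ``min_separation`` bins.
    """
    if not (0 < q < 0.5):
        raise ValueError("quantile fraction q must be in (0, 0.5)")
    if not track.binning.same_binning(oe.binning):
        raise ValueError("track and O/E binnings differ")
    e1 = track.e1
    unmasked = np.isfinite(e1)
    ranked = np.argsort(e1[unmasked], kind="stable")
    ids = np.nonzero(unmasked)[0][ranked]
    k = max(1, int(np.floor(q * len(ids))))
    bottom = set(ids[:k].tolist())
    top = set(ids[-k:].tolist())

    n = oe.binning.n_bins
    in_top = np.zeros(n, dtype=bool)
    in_top[ids[-k:]] = True
    in_bot = np.zeros(n, dtype=bool)
    in_bot[ids[:k]] = True
    coo = oe.matrix.tocoo()
    chrom_idx = oe.binning.chrom_of_bins()
    sel = (
        (coo.row < coo.col)
        & (chrom_idx[coo.row] == chrom_idx[coo.col])
        & (coo.col - coo.row > min_separation)
    )
    r, c, v = coo.row[sel], coo.col[sel], coo.data[sel]
    is_aa = in_top[r] & in_top[c]
    is_bb = in_bot[r] & in_bot[c]
    is_ab = (in_top[r] & in_bot[c]) | (in_bot[r] & in_top[c])
    sums = {"AA": float(v[is_aa].sum()), "BB": float(v[is_bb].sum()),
            "AB": float(v[is_ab].sum())}
    counts = {"AA": 0, "BB": 0, "AB": 0}

    # zero O/E pairs are implicit in the sparse matrix: count all eligible
    # pairs in each group so the means are over pairs, not stored entries
    def group_pairs(s1: set, s2: set, same: bool) -> int:
        a1 = np.fromiter(s1, dtype=int)
        a2 = np.fromiter(s2, dtype=int)
        total = 0
        for c in range(len(oe.binning.chrom_names)):
            b1 = a1[chrom_idx[a1] == c]
            b2 = a2[chrom_idx[a2] == c]
            if len(b1) == 0 or len(b2) == 0:
                continue
            diff = np.abs(np.subtract.outer(b1, b2))
            n_pairs = int((diff > min_separation).sum())
            total += n_pairs // 2 if same else n_pairs
        return total

    n_aa = group_pairs(top, top, True)
    n_bb = group_pairs(bottom, bottom, True)
    n_ab = group_pairs(top, bottom, False)
    for key, n in (("AA", n_aa), ("BB", n_bb), ("AB", n_ab)):
        if n == 0 or sums[key] <= 0:
            raise ValueError(f"no usable pairs for {key} quantile block")
        counts[key] = n
    return SaddleResult(
        aa=sums["AA"] / counts["AA"],
        bb=sums["BB"] / counts["BB"],
        ab=sums["AB"] / counts["AB"],
    )


def switch_regions(track1: CompartmentTrack, track2: CompartmentTrack) -> SwitchRegions:
    """Merged runs of bins A in condition 1/B in condition 2, and converse.

    Masked bins in either track break runs and belong to neither set.
    """
    if not track1.binning.same_binning(track2.binning):
        raise ValueError("tracks have different binnings")
    binning = track1.binning
    l1, l2 = track1.label, track2.label
    a_mask = (l1 == "A") & (l2 == "B")
    b_mask = (l1 == "B") & (l2 == "A")

    def merge(mask: np.ndarray) -> list[GenomicInterval]:
        out = []
        for chrom in binning.chrom_names:
            lo, hi = binning.chrom_bin_range(chrom)
            m = mask[lo:hi]
            edges = np.diff(np.concatenate([[0], m.astype(int), [0]]))
            starts = np.nonzero(edges == 1)[0]
            ends = np.nonzero(edges == -1)[0]
            for s, e in zip(starts, ends):
                start_bp = s * binning.bin_size
                end_bp = min(e * binning.bin_size, binning.chrom_lengths[chrom])
                out.append(GenomicInterval(chrom, start_bp, end_bp))
        return out

    return SwitchRegions(restricted_a=merge(a_mask), restricted_b=merge(b_mask))


def _tss_in_regions(genes: list[GeneAnnotation],
                    regions: list[GenomicInterval]) -> list[int]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in regions:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    idx = []
    for gi, g in enumerate(genes):
        tss = g.tss
        for s, e in by_chrom.get(g.interval.chrom, ()):
            if s <= tss < e:
                idx.append(gi)
                break
    return idx


def region_expression_shift(
    regions: list[GenomicInterval],
    genes: list[GeneAnnotation],
    tpm1: np.ndarray,
    tpm2: np.ndarray,
    epsilon: float = 0.1,
) -> tuple[int, float, TestResult]:
    """Expression shift of genes whose TSS falls inside the regions.

    Per-gene fold change is (TPM1 + eps) / (TPM2 + eps) on the per-condition
    mean TPM; returns (gene count, median fold change, two-sided signed-rank
    test of log fold changes against zero).
    """
    idx = _tss_in_regions(genes, regions)
    if not idx:
        raise ValueError("no genes with TSS inside the regions")
    fc = (np.asarray(tpm1)[idx] + epsilon) / (np.asarray(tpm2)[idx] + epsilon)
    try:
        test = signed_rank_one_sample(np.log(fc))
    except ValueError:
        # all fold changes unity (or too few non-unit): no detectable shift
        test = TestResult(0.0, 1.0, "signed_rank_degenerate", (len(idx),))
    return len(idx), float(np.median(fc)), test


def peak_region_enrichment(
    peaks: FeatureTrack,
    regions: list[GenomicInterval],
    binning: GenomeBinning,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Fold enrichment of peak midpoints in regions, permutation-tested.

    fold = (fraction of peaks inside regions) / (region Mb / genome Mb);
    the null redistributes peaks by an independent circular shift of each
    chromosome's peak set, preserving spacing; p is add-one corrected.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if len(peaks) == 0:
        raise ValueError("no peaks")
    region_bp = sum(len(iv) for iv in regions)
    genome_bp = binning.genome_length
    frac_genome = region_bp / genome_bp
    if frac_genome == 0:
        raise ValueError("regions are empty")

    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in regions:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))

    mids: dict[str, np.ndarray] = {}
    for iv, _ in peaks:
        mids.setdefault(iv.chrom, [])
    for iv, _ in peaks:
        mids[iv.chrom].append(iv.midpoint())
    mids = {c: np.asarray(v) for c, v in mids.items()}

    def frac_in(mid_map: dict[str, np.ndarray]) -> float:
        hits = 0
        total = 0
        for chrom, pos in mid_map.items():
            total += len(pos)
            ivs = by_chrom.get(chrom)
            if not ivs:
                continue
            for s, e in ivs:
                hits += int(np.count_nonzero((pos >= s) & (pos < e)))
        return hits / total

    obs_fold = frac_in(mids) / frac_genome
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        shifted = {}
        for chrom, pos in mids.items():
            L = binning.chrom_lengths[chrom]
            shifted[chrom] = (pos + rng.integers(0, L)) % L
        if frac_in(shifted) / frac_genome >= obs_fold:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return float(obs_fold), float(p)
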