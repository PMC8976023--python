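"""TAD calling by insulation score, boundary sharing, intra-TAD strength,
and rescaled average-TAD pileups.

The insulation score at bin i is log2 of the mean balanced contact in the
w x w diamond spanning the bin, over the chromosome-wide mean of that
quantity; boundaries are local insulation minima with prominence at least
``delta_threshold``, and TADs are the intervals between consecutive
boundaries (minimum 5 bins). Intra-TAD strength is the log2 ratio of mean
contact within a TAD to distance-matched contact between the TAD and its
same-size flanking windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .genome_model import GenomeBinning, GenomicInterval
from .contacts import ContactMatrix

__all__ = [
    "InsulationProfile",
    "TadSet",
    "TadStrengthResult",
    "insulation_score",
    "call_boundaries",
    "boundary_sharing",
    "intra_tad_strength",
    "tad_pileup",
]

MIN_TAD_BINS = 5


@dataclass
class InsulationProfile:
    binning: GenomeBinning
    score: np.ndarray  # per global bin; NaN where the diamond does not fit
    window_bp: int

    @property
    def window_bins(self) -> int:
        return self.window_bp // self.binning.bin_size


@dataclass
class TadSet:
    """Ordered boundary bins and derived domain intervals per chromosome."""

    binning: GenomeBinning
    boundaries: dict[str, np.ndarray]  # chrom -> local bin indices
    tads: dict[str, list[GenomicInterval]]

    def all_tads(self) -> list[GenomicInterval]:
        return [iv for chrom in self.binning.chrom_names
                for iv in self.tads.get(chrom, [])]

    def n_boundaries(self) -> int:
        return int(sum(len(b) for b in self.boundaries.values()))

    def global_boundaries(self) -> np.ndarray:
        out = []
        for chrom in self.binning.chrom_names:
            off = self.binning.chrom_offsets[chrom]
            out.extend((self.boundaries.get(chrom, np.array([], int)) + off).tolist())
        return np.asarray(out, dtype=int)


@dataclass
class TadStrengthResult:
    per_tad: list[tuple[GenomicInterval, float]]

    @property
    def mean(self) -> float:
        vals = [v for _, v in self.per_tad if np.isfinite(v)]
        if not vals:
            return float("nan")
        return float(np.mean(vals))


def insulation_score(m: ContactMatrix, window_bp: int = 300_000) -> InsulationProfile:
    """Diamond insulation: log2(diamond mean / chromosome mean of diamonds)."""
    binning = m.binning
    w = window_bp // binning.bin_size
    if w < 5:
        raise ValueError("window must span >= 5 bins")
    score = np.full(binning.n_bins, np.nan)
    for chrom in binning.chrom_names:
        lo, hi = binning.chrom_bin_range(chrom)
        nb = hi - lo
        if w >= nb:
            raise ValueError(f"window larger than chromosome {chrom}")
        dense = m.balanced_dense_chrom(chrom)
        diam = np.full(nb, np.nan)
        # the diamond shrinks symmetrically near chromosome ends (arm >= 3
        # bins) so edge-proximal boundaries remain callable
        for i in range(3, nb - 3):
            wi = min(w, i, nb - 1 - i)
            block = dense[i - wi : i, i + 1 : i + 1 + wi]
            if np.isfinite(block).any():
                diam[i] = np.nanmean(block)
        with np.errstate(invalid="ignore"):
            valid = np.isfinite(diam) & (diam > 0)
        if valid.sum() == 0:
            continue
        chrom_mean = diam[valid].mean()
        vals = np.full(nb, np.nan)
        vals[valid] = np.log2(diam[valid] / chrom_mean)
        score[lo:hi] = vals
    return InsulationProfile(binning, score, window_bp)


def call_boundaries(
    profile: InsulationProfile, delta_threshold: float = 0.1,
    min_tad_bins: int = MIN_TAD_BINS,
) -> TadSet:
    """Boundaries = insulation minima with prominence >= delta_threshold."""
    binning = profile.binning
    boundaries: dict[str, np.ndarray] = {}
    tads: dict[str, list[GenomicInterval]] = {}
    for chrom in binning.chrom_names:
        lo, hi = binning.chrom_bin_range(chrom)
        s = profile.score[lo:hi]
        finite = np.isfinite(s)
        filled = np.where(finite, s, np.nanmax(s) if finite.any() else 0.0)
        idx, _ = find_peaks(-filled, prominence=delta_threshold)
        idx = idx[finite[idx]]
        boundaries[chrom] = idx.astype(int)
        ivs: list[GenomicInterval] = []
        edges = [0, *idx.tolist(), hi - lo]
        for a, b in zip(edges[:-1], edges[1:]):
            if b - a < min_tad_bins:
                continue
            start = a * binning.bin_size
            end = min(b * binning.bin_size, binning.chrom_lengths[chrom])
            ivs.append(GenomicInterval(chrom, start, end))
        tads[chrom] = ivs
    return TadSet(binning, boundaries, tads)


def boundary_sharing(tads1: TadSet, tads2: TadSet, slack_bins: int = 1) -> dict:
    """Fraction of boundaries shared within +/- slack, both ways and mean."""
    if not tads1.binning.same_binning(tads2.binning):
        raise ValueError("boundary sets use different binnings")
    b1 = tads1.global_boundaries()
    b2 = tads2.global_boundaries()
    if len(b1) == 0 or len(b2) == 0:
        raise ValueError("empty boundary set")

    def frac(a: np.ndarray, b: np.ndarray) -> float:
        hit = np.min(np.abs(a[:, None] - b[None, :]), axis=1) <= slack_bins
        return float(hit.mean())

    f12, f21 = frac(b1, b2), frac(b2, b1)
    return {"shared_1_in_2": f12, "shared_2_in_1": f21,
            "mean": (f12 + f21) / 2}


def intra_tad_strength(m: ContactMatrix, tads: TadSet) -> TadStrengthResult:
    """Per-TAD log2(intra / inter) with strict distance matching.

    For a TAD of s bins, intra pairs are within the TAD and inter pairs link
    the TAD to its immediate same-size flanking windows; only separations
    d <= s present in both sets contribute, compared as per-distance means
    so distance decay cancels. TADs at chromosome ends without a full flank
    are skipped with a warning.
    """
    binning = m.binning
    per_tad: list[tuple[GenomicInterval, float]] = []
    any_ok = False
    for chrom in binning.chrom_names:
        ivs = tads.tads.get(chrom, [])
        if not ivs:
            continue
        dense = m.balanced_dense_chrom(chrom)
        nb = dense.shape[0]
        for iv in ivs:
            a = iv.start // binning.bin_size
            b = -(-iv.end // binning.bin_size)  # ceil
            s = b - a
            if a - s < 0 or b + s > nb:
                warnings.warn(
                    f"TAD {chrom}:{iv.start}-{iv.end} lacks a full flank; skipped",
                    stacklevel=2,
                )
                continue
            intra_by_d: dict[int, list[float]] = {}
            inter_by_d: dict[int, list[float]] = {}
            block = dense[a:b, a:b]
            for d in range(1, s):
                vals = np.diagonal(block, d)
                vals = vals[np.isfinite(vals)]
                if len(vals):
                    intra_by_d[d] = vals
            left = dense[a - s : a, a:b]   # (flank bin i, tad bin j)
            right = dense[a:b, b : b + s]
            for d in range(1, s + 1):
                vals = []
                # left flank: separation = (a + j) - (a - s + i) = j - i + s
                ii, jj = np.nonzero(
                    np.subtract.outer(np.arange(s), np.arange(s)) == s - d
                )
                # careful: sep = jj - ii + s  => want sep == d  => jj - ii == d - s
                v1 = left[ii, jj]
                v2 = right[ii, jj] if d <= s else np.array([])
                both = np.concatenate([v1, v2])
                both = both[np.isfinite(both)]
                if len(both):
                    inter_by_d[d] = both
            common = sorted(set(intra_by_d) & set(inter_by_d))
            if not common:
                per_tad.append((iv, float("nan")))
                continue
            intra_mean = np.mean([np.mean(intra_by_d[d]) for d in common])
            inter_mean = np.mean([np.mean(inter_by_d[d]) for d in common])
            if intra_mean <= 0 or inter_mean <= 0:
                per_tad.append((iv, float("nan")))
                continue
            per_tad.append((iv, float(np.log2(intra_mean / inter_mean))))
            any_ok = True
    if not any_ok:
        raise ValueError("no TAD with both flanks present")
    return TadStrengthResult(per_tad)


def tad_pileup(m: ContactMatrix, tads: TadSet, target_size: int = 30) -> np.ndarray:
    """Average O/E-normalized map of all TADs rescaled (with one flank each
    side) to a common ``3*target_size`` grid by area-weighted interpolation."""
    if target_size < 10:
        raise ValueError("target_size must be >= 10")
    all_tads = tads.all_tads()
    if len(all_tads) < 5:
        raise ValueError("need >= 5 TADs for a pileup")
    binning = m.binning
    grid = 3 * target_size
    acc = np.zeros((grid, grid))
    nacc = np.zeros((grid, grid))
    for chrom in binning.chrom_names:
        ivs = tads.tads.get(chrom, [])
        if not ivs:
            continue
        dense = m.balanced_dense_chrom(chrom)
        nb = dense.shape[0]
        # per-distance expectation for O/E normalization of the window
        exp_by_d = np.array([
            np.nanmean(np.diagonal(dense, d)) if np.isfinite(
                np.diagonal(dense, d)).any() else np.nan
            for d in range(nb)
        ])
        for iv in ivs:
            a = iv.start // binning.bin_size
            b = -(-iv.end // binning.bin_size)
            s = b - a
            if a - s < 0 or b + s > nb:
                continue
            win = dense[a - s : b + s, a - s : b + s].copy()
            d = np.abs(np.subtract.outer(np.arange(3 * s), np.arange(3 * s)))
            with np.errstate(invalid="ignore", divide="ignore"):
                win = win / exp_by_d[d]
            resc = _rescale_area(win, grid)
            ok = np.isfinite(resc)
            acc[ok] += resc[ok]
            nacc[ok] += 1
    with np.errstate(invalid="ignore"):
        out = acc / nacc
    return (out + out.T) / 2


def _rescale_area(mat: np.ndarray, target: int) -> np.ndarray:
    """Area-weighted rescaling of a square matrix to target x target."""
    n = mat.shape[0]
    # overlap weights between source cells [i, i+1) and target cells scaled
    edges_src = np.linspace(0.0, 1.0, n + 1)
    edges_tgt = np.linspace(0.0, 1.0, target + 1)
    w = np.zeros((target, n))
    for t in range(target):
        lo, hi = edges_tgt[t], edges_tgt[t + 1]
        left = np.clip(edges_src[1:], lo, hi)
        right = np.clip(edges_src[:-1], lo, hi)
        w[t] = np.maximum(left - right, 0.0)
    w /= w.sum(axis=1, keepdims=True)
    filled = np.nan_to_num(mat, nan=0.0)
    weight = np.isfinite(mat).astype(float)
    num = w @ filled @ w.T
    den = w @ weight @ w.T
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)
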