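"""Contact-map Von Neumann entropy, 3D genome reconstruction, and the
Shannon chromosome-intermingling index.

Von Neumann entropy treats each chromosome's contact structure as a density
operator: the Pearson correlation matrix of the intra-chromosomal O/E map
(masked bins removed) is symmetrized, negative eigenvalues clipped to zero,
the spectrum renormalized to sum 1, and the entropy is
-sum(lambda * ln(lambda)). A strongly compartmentalized chromosome has a
near-low-rank correlation structure and hence low entropy; disordered,
structureless chromatin gives a flat spectrum and high entropy. Entropy on
the correlation of O/E (rather than the balanced counts directly) is what
makes the statistic respond to organisation instead of to distance decay,
which dominates the spectrum of the balanced map itself.

Reconstruction converts contacts to distances d = c^(-1/2), completes
missing distances by shortest path, and embeds with classical
multidimensional scaling (deterministic, no random initialization). The
intermingle index of a bead is the Shannon diversity of chromosome
identities among its k nearest neighbors in 3D; a bead with H >= ln 2 (at
least two chromosomes equally represented) counts as extensively
intermingled, and the per-1-Mb-window smoothed fraction of such beads gives
the genome-wide intermingling probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial import cKDTree

from .genome_model import GenomeBinning
from .contacts import ContactMatrix
from .stats_report import TestResult, wilcoxon_rank_sum

__all__ = [
    "EntropyResult",
    "Structure3D",
    "IntermingleProfile",
    "von_neumann_entropy",
    "reconstruct_structure",
    "intermingle_index",
    "compare_entropy",
]

EXTENSIVE_THRESHOLD = float(np.log(2.0))


@dataclass
class EntropyResult:
    per_chromosome: dict[str, float]
    n_bins: dict[str, int]
    log_base: str = "e"

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.per_chromosome.values())))


@dataclass
class Structure3D:
    binning: GenomeBinning
    bin_ids: np.ndarray      # global ids of embedded (unmasked) bins
    coords: np.ndarray       # (n, 3), centered at the origin
    stress: float


@dataclass
class IntermingleProfile:
    binning: GenomeBinning
    bin_ids: np.ndarray
    shannon: np.ndarray           # per-bead Shannon index H
    window_probability: np.ndarray  # smoothed per-bead extensive probability
    k_neighbors: int

    @property
    def mean_probability(self) -> float:
        return float(np.mean(self.window_probability))


def _vne_dense(mat: np.ndarray) -> float:
    """VNE of one symmetric matrix: PSD-project, trace-normalize, -sum l ln l."""
    sym = (mat + mat.T) / 2
    vals = np.linalg.eigvalsh(sym)
    vals = np.clip(vals, 0.0, None)
    total = vals.sum()
    if total <= 0:
        raise ValueError("matrix has no positive spectrum")
    lam = vals / total
    lam = lam[lam > 0]
    return float(-(lam * np.log(lam)).sum())


def von_neumann_entropy(m, min_bins: int = 10) -> EntropyResult:
    """Per-chromosome VNE of the O/E correlation structure; map level mean.

    Accepts an :class:`~archcomp.contacts.OEMatrix` or a balanced
    :class:`~archcomp.contacts.ContactMatrix` (converted to O/E internally).
    """
    from .contacts import OEMatrix, expected_by_distance, observed_over_expected

    if isinstance(m, ContactMatrix):
        oe = observed_over_expected(m, expected_by_distance(m))
    elif isinstance(m, OEMatrix):
        oe = m
    else:
        raise TypeError(f"expected ContactMatrix or OEMatrix, got {type(m)}")
    per: dict[str, float] = {}
    nb: dict[str, int] = {}
    for chrom in oe.binning.chrom_names:
        dense = oe.dense_chrom(chrom)
        good = np.isfinite(dense).any(axis=1) & ~oe.mask[
            slice(*oe.binning.chrom_bin_range(chrom))
        ]
        sub = dense[np.ix_(good, good)]
        if sub.shape[0] < min_bins:
            raise ValueError(f"{chrom}: fewer than {min_bins} unmasked bins")
        if not np.any(sub > 0):
            raise ValueError(f"{chrom}: all-zero matrix")
        sub = np.nan_to_num(sub, nan=0.0)
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub)
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 1.0)
        per[chrom] = _vne_dense(corr)
        nb[chrom] = sub.shape[0]
    return EntropyResult(per_chromosome=per, n_bins=nb)


def reconstruct_structure(m: ContactMatrix) -> Structure3D:
    """Deterministic 3D embedding of the genome-wide balanced contact map.

    d_ij = c_ij^(-1/2) for positive balanced contacts, missing distances
    completed by graph shortest path, then classical MDS to 3 dimensions.
    """
    if len(m.binning.chrom_names) < 2:
        raise ValueError("reconstruction needs >= 2 chromosomes")
    if m.weights is None:
        raise ValueError("balance the matrix first")
    mask = m.mask
    keep = ~mask
    ids = np.nonzero(keep)[0]
    n = len(ids)
    coo = m.matrix.tocoo()
    w = m.weights
    bal = coo.data * w[coo.row] * w[coo.col]
    ok = np.isfinite(bal) & (bal > 0) & (coo.row != coo.col)
    remap = -np.ones(m.binning.n_bins, dtype=int)
    remap[ids] = np.arange(n)
    i, j = remap[coo.row[ok]], remap[coo.col[ok]]
    good = (i >= 0) & (j >= 0)
    dist = bal[ok][good] ** -0.5
    graph = sp.coo_matrix((dist, (i[good], j[good])), shape=(n, n)).tocsr()
    graph = graph.maximum(graph.T)  # symmetric (upper-triangle input)

    n_comp, labels = connected_components(graph, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"contact graph is disconnected: {n_comp} components with sizes "
            f"{sorted(sizes.tolist(), reverse=True)[:5]}"
        )
    D = shortest_path(graph, method="D", directed=False)

    # classical MDS (Torgerson): double-center -D^2/2, top-3 spectrum
    D2 = D**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh(B)
    top = np.argsort(vals)[::-1][:3]
    lam = np.clip(vals[top], 0.0, None)
    coords = vecs[:, top] * np.sqrt(lam)[None, :]
    coords = coords - coords.mean(axis=0, keepdims=True)

    emb = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    denom = (D**2).sum()
    stress = float(np.sqrt(((emb - D) ** 2).sum() / denom)) if denom > 0 else 0.0
    return Structure3D(m.binning, ids, coords, stress)


def intermingle_index(
    s: Structure3D, k_neighbors: int = 20, window_bp: int = 1_000_000,
) -> IntermingleProfile:
    """Shannon diversity of chromosome identity among k nearest 3D neighbors.

    H >= ln 2 marks extensive intermingling; the probability track is the
    per-bead extensive indicator smoothed by a 1-Mb running window along
    each chromosome.
    """
    if k_neighbors <= 0:
        raise ValueError("k_neighbors must be positive")
    n = len(s.bin_ids)
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be smaller than the bead count")
    chrom_idx = s.binning.chrom_of_bins()[s.bin_ids]
    tree = cKDTree(s.coords)
    _, nbr = tree.query(s.coords, k=k_neighbors + 1)
    nbr = nbr[:, 1:]  # drop self
    n_chroms = len(s.binning.chrom_names)
    H = np.zeros(n)
    for b in range(n):
        counts = np.bincount(chrom_idx[nbr[b]], minlength=n_chroms)
        p = counts[counts > 0] / k_neighbors
        H[b] = -(p * np.log(p)).sum()
    extensive = (H >= EXTENSIVE_THRESHOLD).astype(float)

    win_bins = max(1, window_bp // s.binning.bin_size)
    prob = np.empty(n)
    for chrom in s.binning.chrom_names:
        lo, hi = s.binning.chrom_bin_range(chrom)
        sel = (s.bin_ids >= lo) & (s.bin_ids < hi)
        e = extensive[sel]
        if len(e) == 0:
            continue
        kernel = np.ones(min(win_bins, len(e)))
        num = np.convolve(e, kernel, mode="same")
        den = np.convolve(np.ones_like(e), kernel, mode="same")
        prob[sel] = num / den
    return IntermingleProfile(s.binning, s.bin_ids, H, prob, k_neighbors)


def compare_entropy(
    maps1: list[ContactMatrix], maps2: list[ContactMatrix],
) -> tuple[list[float], list[float], TestResult]:
    """Map-level VNE per condition plus a two-sided rank-sum comparison."""
    if len(maps1) < 2 or len(maps2) < 2:
        raise ValueError("need >= 2 maps per condition")
    v1 = [von_neumann_entropy(m).mean for m in maps1]
    v2 = [von_neumann_entropy(m).mean for m in maps2]
    return v1, v2, wilcoxon_rank_sum(v1, v2)
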