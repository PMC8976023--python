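"""Contact-matrix storage, ICE balancing, distance-decay expected, and O/E.

Raw counts are held as a sparse upper-triangle (i <= j); symmetry is implied.
Balancing is ICE-style iterative correction: per-bin weights w_i such that
the marginals of ``w_i c_ij w_j`` over unmasked bins are all 1. Low-coverage
bins are masked by a median-absolute-deviation filter on log coverage before
correction. The distance-decay expected profile pools all intra-chromosomal
unmasked pairs at each bin separation, with log-spaced smoothing at long
range; observed/expected divides the balanced matrix by this expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .genome_model import GenomeBinning

__all__ = [
    "ContactMatrix",
    "ExpectedProfile",
    "OEMatrix",
    "read_contacts_coo",
    "read_bin_table",
    "write_bin_table",
    "write_contacts_coo",
    "ice_balance",
    "expected_by_distance",
    "observed_over_expected",
    "trans_fraction",
]


class BalanceError(RuntimeError):
    """Iterative correction failed to converge; carries the last residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass
class ContactMatrix:
    """Binned symmetric genome-wide raw contact counts.

    ``matrix`` is upper-triangular sparse (i <= j). ``weights`` is set by
    :func:`ice_balance`; masked bins carry NaN weights.
    """

    binning: GenomeBinning
    matrix: sp.csr_matrix
    weights: np.ndarray | None = None
    name: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        n = self.binning.n_bins
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match {n} bins"
            )
        coo = self.matrix.tocoo()
        if np.any(coo.data < 0):
            raise ValueError("negative contact counts")
        if np.any(coo.row > coo.col):
            # fold lower triangle onto upper
            i = np.minimum(coo.row, coo.col)
            j = np.maximum(coo.row, coo.col)
            self.matrix = sp.coo_matrix((coo.data, (i, j)), shape=(n, n)).tocsr()
        self.matrix.sum_duplicates()

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where bin is masked (no weight)."""
        if self.weights is None:
            return np.zeros(self.binning.n_bins, dtype=bool)
        return ~np.isfinite(self.weights)

    def symmetric(self) -> sp.csr_matrix:
        """Full symmetric raw matrix (diagonal counted once)."""
        m = self.matrix
        return m + m.T - sp.diags(m.diagonal())

    def total(self) -> float:
        return float(self.matrix.sum())

    def balanced_dense_chrom(self, chrom: str) -> np.ndarray:
        """Dense balanced submatrix for one chromosome; masked bins NaN.

        Dense conversion is allowed only per chromosome to bound memory.
        """
        if self.weights is None:
            raise ValueError("matrix has no balancing weights; run ice_balance")
        lo, hi = self.binning.chrom_bin_range(chrom)
        sub = self.symmetric()[lo:hi, lo:hi].toarray().astype(float)
        w = self.weights[lo:hi]
        out = sub * w[:, None] * w[None, :]
        bad = ~np.isfinite(w)
        out[bad, :] = np.nan
        out[:, bad] = np.nan
        return out

    def scale_counts(self, k: float) -> "ContactMatrix":
        return ContactMatrix(
            self.binning, (self.matrix * k).tocsr(), None, self.name, self.condition
        )


@dataclass
class ExpectedProfile:
    """Mean balanced contact per bin separation, plus a flat trans level."""

    expected: np.ndarray  # indexed by separation d; d=0 entry is NaN
    trans_expected: float
    binning: GenomeBinning = None

    def at(self, d: np.ndarray) -> np.ndarray:
        return self.expected[np.asarray(d)]


@dataclass
class OEMatrix:
    """Sparse observed/expected matrix (balanced / distance expectation)."""

    binning: GenomeBinning
    matrix: sp.csr_matrix  # symmetric, explicit entries only where defined
    mask: np.ndarray

    def dense_chrom(self, chrom: str) -> np.ndarray:
        """Dense O/E for one chromosome; zeros stay 0, masked bins NaN."""
        lo, hi = self.binning.chrom_bin_range(chrom)
        out = self.matrix[lo:hi, lo:hi].toarray().astype(float)
        bad = self.mask[lo:hi]
        out[bad, :] = np.nan
        out[:, bad] = np.nan
        return out


# ---------------------------------------------------------------------------
# COO text IO
# ---------------------------------------------------------------------------


def read_bin_table(path) -> GenomeBinning:
    """Rebuild a GenomeBinning from a ``bin_id chrom start end`` table."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None,
                     names=["bin_id", "chrom", "start", "end"])
    if (df["bin_id"].to_numpy() != np.arange(len(df))).any():
        raise ValueError(f"{path}: bin ids are not dense 0..N-1")
    sizes: dict[str, int] = {}
    widths = set()
    for row in df.itertuples(index=False):
        sizes[row.chrom] = int(row.end)
        widths.add(int(row.end) - int(row.start))
    bin_size = max(widths)  # terminal bins may be short
    from .genome_model import build_binning

    binning = build_binning(sizes, bin_size)
    if not binning.bin_table().reset_index(drop=True).equals(
            df[["chrom", "start", "end"]].reset_index(drop=True)):
        raise ValueError(f"{path}: table does not describe a uniform tiling")
    return binning


def read_contacts_coo(matrix_path, bins) -> ContactMatrix:
    """Read ``bin1<TAB>bin2<TAB>count`` triples; (j,i) folded, duplicates summed.

    ``bins`` is a GenomeBinning or the path of a bin table written by
    :func:`write_bin_table`.
    """
    binning = bins if isinstance(bins, GenomeBinning) else read_bin_table(bins)
    n = binning.n_bins
    data = np.loadtxt(matrix_path, dtype=float, ndmin=2)
    if data.size == 0:
        return ContactMatrix(binning, sp.csr_matrix((n, n)))
    i, j, c = data[:, 0].astype(int), data[:, 1].astype(int), data[:, 2]
    if np.any(c < 0):
        raise ValueError(f"{matrix_path}: negative counts")
    if np.any((i < 0) | (i >= n) | (j < 0) | (j >= n)):
        raise ValueError(f"{matrix_path}: bin id out of range (n={n})")
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    m = sp.coo_matrix((c, (lo, hi)), shape=(n, n)).tocsr()
    m.sum_duplicates()
    return ContactMatrix(binning, m)


def write_contacts_coo(m: ContactMatrix, matrix_path) -> None:
    coo = m.matrix.tocoo()
    order = np.lexsort((coo.col, coo.row))
    with open(matrix_path, "w") as fh:
        for i, j, c in zip(coo.row[order], coo.col[order], coo.data[order]):
            fh.write(f"{i}\t{j}\t{c:.17g}\n")


def write_bin_table(binning: GenomeBinning, path) -> None:
    binning.bin_table().to_csv(path, sep="\t", header=False)


# ---------------------------------------------------------------------------
# ICE balancing
# ---------------------------------------------------------------------------


def ice_balance(
    m: ContactMatrix,
    max_iter: int = 500,
    tol: float = 1e-5,
    mad_max: float = 5.0,
    ignore_diags: int = 1,
) -> np.ndarray:
    """Iterative correction: weights making unmasked marginals equal to 1.

    Bins with zero coverage, and bins whose log coverage falls more than
    ``mad_max`` median absolute deviations below the median, are masked
    (NaN weight). Convergence is measured as the relative variance of the
    unmasked marginals; failure raises :class:`BalanceError` with the last
    residual. The weight vector is stored on ``m`` and returned.
    """
    if m.matrix.nnz == 0:
        raise ValueError("empty contact matrix")
    n = m.binning.n_bins
    sym = m.symmetric().tocsr().astype(float)
    if ignore_diags:
        sym = sym.tolil()
        offs = m.binning.chrom_of_bins()
        # zero the first ignore_diags diagonals (self-ligation artifacts)
        for d in range(ignore_diags):
            idx = np.arange(n - d)
            same = offs[idx] == offs[idx + d]
            sym[idx[same], idx[same] + d] = 0.0
            sym[idx[same] + d, idx[same]] = 0.0
        sym = sym.tocsr()
        sym.eliminate_zeros()

    coverage = np.asarray(sym.sum(axis=1)).ravel()
    masked = coverage <= 0
    if mad_max is not None and np.any(~masked):
        logcov = np.log(coverage[~masked])
        med = np.median(logcov)
        mad = np.median(np.abs(logcov - med))
        if mad > 0:
            cut = med - mad_max * mad
            low = np.zeros(n, dtype=bool)
            low[~masked] = logcov < cut
            masked |= low
    active = ~masked
    if not np.any(active):
        raise ValueError("all bins masked during balancing")

    w = np.zeros(n)
    w[active] = 1.0
    residual = np.inf
    for _ in range(max_iter):
        marg = np.asarray((sym.multiply(w[:, None]).multiply(w[None, :])).sum(axis=1)).ravel()
        ma = marg[active]
        mean = ma.mean()
        residual = float(ma.var() / mean**2) if mean > 0 else np.inf
        if residual < tol:
            break
        # divide out the deviation of each marginal from the mean
        adj = np.ones(n)
        adj[active] = ma / mean
        w = w / np.sqrt(adj)
    else:
        raise BalanceError(
            f"ICE did not converge in {max_iter} iterations "
            f"(residual {residual:.3e}, tol {tol:.1e})",
            residual,
        )

    # final rescale so unmasked marginals are exactly ~1 on average
    marg = np.asarray((sym.multiply(w[:, None]).multiply(w[None, :])).sum(axis=1)).ravel()
    scale = marg[active].mean()
    w = w / np.sqrt(scale)
    weights = np.full(n, np.nan)
    weights[active] = w[active]
    m.weights = weights
    return weights


# ---------------------------------------------------------------------------
# Expected profile and O/E
# ---------------------------------------------------------------------------

_SMOOTH_RAW_MAX = 20  # raw per-diagonal means up to this separation
_SMOOTH_RATIO = 1.05  # log-bin ratio beyond


def _log_bin_index(d: np.ndarray) -> np.ndarray:
    """Smoothing group per separation: identity <= 20, log-spaced beyond."""
    d = np.asarray(d)
    out = d.astype(int).copy()
    far = d > _SMOOTH_RAW_MAX
    if np.any(far):
        k = np.floor(
            np.log(d[far] / _SMOOTH_RAW_MAX) / np.log(_SMOOTH_RATIO)
        ).astype(int)
        out[far] = _SMOOTH_RAW_MAX + 1 + k
    return out


def expected_by_distance(m: ContactMatrix) -> ExpectedProfile:
    """Mean balanced contact at each bin separation, pooled over chromosomes.

    Zero entries of the sparse matrix count toward the means (the expected
    value is total balanced signal at separation d over the number of
    unmasked pairs at d). Separations above 20 bins share log-spaced
    smoothing bins (ratio 1.05). d = 0 is excluded.
    """
    if m.weights is None:
        raise ValueError("balance the matrix before computing expected")
    binning = m.binning
    active = ~m.mask
    max_n = max(binning.n_bins_per_chrom.values())

    sums = np.zeros(max_n)
    counts = np.zeros(max_n)
    coo = m.matrix.tocoo()
    w = m.weights
    chrom_idx = binning.chrom_of_bins()
    cis = chrom_idx[coo.row] == chrom_idx[coo.col]
    d_cis = (coo.col - coo.row)[cis]
    val = coo.data[cis] * w[coo.row[cis]] * w[coo.col[cis]]
    ok = np.isfinite(val) & (d_cis > 0)
    np.add.at(sums, d_cis[ok], val[ok])

    # number of unmasked intra-chromosomal pairs at each separation
    for chrom in binning.chrom_names:
        lo, hi = binning.chrom_bin_range(chrom)
        act = active[lo:hi].astype(float)
        nb = hi - lo
        if act.sum() == 0:
            continue
        # pair counts at separation d via correlation of the active indicator
        corr = np.correlate(act, act, mode="full")[nb:]  # d = 1..nb-1
        counts[1 : nb] += corr[: nb - 1]

    valid = counts > 0
    if not np.any(valid[1:]):
        raise ValueError("no unmasked intra-chromosomal pairs at any distance")

    d_all = np.arange(max_n)
    groups = _log_bin_index(d_all)
    gsum = np.bincount(groups, weights=sums)
    gcnt = np.bincount(groups, weights=counts)
    gmean = np.divide(gsum, gcnt, out=np.full_like(gsum, np.nan), where=gcnt > 0)
    expected = gmean[groups]
    expected[0] = np.nan
    expected[~valid & (d_all > 0)] = np.nan

    # flat trans expectation
    trans = ~cis
    tval = coo.data[trans] * w[coo.row[trans]] * w[coo.col[trans]]
    tsum = float(np.nansum(tval))
    n_act = np.array([active[slice(*binning.chrom_bin_range(c))].sum()
                      for c in binning.chrom_names])
    tot = n_act.sum()
    n_trans_pairs = (tot**2 - np.sum(n_act**2)) / 2
    trans_expected = tsum / n_trans_pairs if n_trans_pairs > 0 else 0.0
    return ExpectedProfile(expected=expected, trans_expected=trans_expected,
                           binning=binning)


def observed_over_expected(m: ContactMatrix, profile: ExpectedProfile) -> OEMatrix:
    """Balanced / expected for every stored entry; masked bins dropped."""
    if profile.binning is not None and not m.binning.same_binning(profile.binning):
        raise ValueError("profile binning does not match matrix binning")
    if m.weights is None:
        raise ValueError("balance the matrix before O/E")
    coo = m.matrix.tocoo()
    w = m.weights
    chrom_idx = m.binning.chrom_of_bins()
    bal = coo.data * w[coo.row] * w[coo.col]
    cis = chrom_idx[coo.row] == chrom_idx[coo.col]
    d = coo.col - coo.row
    exp = np.where(cis, profile.expected[np.where(cis, d, 0)],
                   profile.trans_expected)
    with np.errstate(invalid="ignore", divide="ignore"):
        oe = bal / exp
    keep = np.isfinite(oe) & (d != 0)
    n = m.binning.n_bins
    upper = sp.coo_matrix((oe[keep], (coo.row[keep], coo.col[keep])), shape=(n, n))
    full = (upper + upper.T).tocsr()
    return OEMatrix(binning=m.binning, matrix=full, mask=m.mask.copy())


def trans_fraction(m: ContactMatrix) -> float:
    """Interchromosomal counts as a fraction of all counts."""
    if len(m.binning.chrom_names) < 2:
        raise ValueError("trans fraction undefined for a single chromosome")
    coo = m.matrix.tocoo()
    chrom_idx = m.binning.chrom_of_bins()
    total = coo.data.sum()
    if total == 0:
        return 0.0
    trans = coo.data[chrom_idx[coo.row] != chrom_idx[coo.col]].sum()
    return float(trans / total)
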