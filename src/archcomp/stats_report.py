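"""Shared statistics (Wilcoxon, Spearman, BH FDR, TPM, a light DE test) and
the machine-readable two-condition comparison report.

Tests are two-sided throughout. Rank-sum and signed-rank p-values are exact
(full enumeration) for small tie-free samples and use the normal
approximation with tie and continuity corrections otherwise, matching common
statistical practice for these tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "CorrelationResult",
    "ExpressionMatrix",
    "wilcoxon_rank_sum",
    "signed_rank_one_sample",
    "spearman",
    "bh_fdr",
    "tpm",
    "de_lite",
    "ComparisonReport",
    "build_report",
]

EXACT_N_MAX = 12  # exact enumeration cutoff for rank tests


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    method: str
    n: tuple[int, ...]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U).

    Exact null enumeration when n1 + n2 <= 12 with no ties; otherwise the
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    if x.size + y.size <= EXACT_N_MAX and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = st.mannwhitneyu(x, y, alternative="two-sided", method=method,
                          use_continuity=True)
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      f"wilcoxon_rank_sum_{method}", (x.size, y.size))


def signed_rank_one_sample(d) -> TestResult:
    """Two-sided one-sample Wilcoxon signed-rank against zero.

    Exact for n <= 12 nonzero differences without tied magnitudes.
    """
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    if d.size < 5:
        raise ValueError("need >= 5 nonzero differences")
    mags = np.abs(d)
    has_ties = len(np.unique(mags)) < mags.size
    method = "exact" if (d.size <= EXACT_N_MAX and not has_ties) else "approx"
    res = st.wilcoxon(d, alternative="two-sided", method=method,
                      correction=(method == "approx"))
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      f"signed_rank_{method}", (d.size,))


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with the t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need paired vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector has no rank correlation")
    rho, p = st.spearmanr(x, y)
    return CorrelationResult(float(rho), float(p), int(x.size))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ExpressionMatrix:
    """Genes x samples counts with lengths and derived TPM."""

    counts: pd.DataFrame
    lengths: pd.Series
    tpm: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.tpm = tpm(self.counts, self.lengths)


def tpm(counts: pd.DataFrame, lengths) -> pd.DataFrame:
    """Transcripts per million: length-normalized, column sums 1e6."""
    lengths = pd.Series(lengths).reindex(counts.index)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    rate = counts.div(lengths, axis=0)
    colsum = rate.sum(axis=0)
    if (colsum == 0).any():
        bad = colsum.index[colsum == 0].tolist()
        raise ValueError(f"all-zero samples: {bad}")
    return rate.div(colsum, axis=1) * 1e6


def de_lite(
    log2_expr1: pd.DataFrame,
    log2_expr2: pd.DataFrame,
    shrink: float = 0.5,
) -> pd.DataFrame:
    """Moderated two-group t-test on log2 expression, BH-adjusted.

    Per-gene pooled variance is shrunk toward the mean per-gene variance with
    weight ``shrink``; log2FC is the difference of group means (group 1 minus
    group 2). Returns a DataFrame with log2fc, p, q indexed by gene.
    """
    if log2_expr1.shape[1] < 2 or log2_expr2.shape[1] < 2:
        raise ValueError("need >= 2 replicates per group")
    x1 = log2_expr1.to_numpy(dtype=float)
    x2 = log2_expr2.to_numpy(dtype=float)
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v2 = x2.var(axis=1, ddof=1)
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    shrunk = (1 - shrink) * pooled + shrink * pooled.mean()
    se = np.sqrt(shrunk * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / se
    df = n1 + n2 - 2
    p = 2 * st.t.sf(np.abs(t), df)
    p = np.clip(p, np.nextafter(0, 1), 1.0)
    q = bh_fdr(p)
    return pd.DataFrame(
        {"log2fc": m1 - m2, "p": p, "q": q}, index=log2_expr1.index
    )


# ---------------------------------------------------------------------------
# Comparison report
# ---------------------------------------------------------------------------

REPORT_SCHEMA = "archcomp-report/1"


@dataclass
class ComparisonReport:
    """Schema-versioned aggregate of every per-condition scalar the pipeline
    produces, plus the test p-values, configuration echo, and seeds."""

    schema: str
    conditions: tuple[str, str]
    metrics: dict
    tests: dict
    config: dict
    seeds: dict

    def to_json(self) -> str:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in sorted(obj.items())}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, np.ndarray):
                return clean(obj.tolist())
            return obj

        return json.dumps(clean(asdict(self)), indent=2, sort_keys=True)


def build_report(
    metrics: Mapping,
    tests: Mapping,
    config: Mapping,
    seeds: Mapping,
    conditions: Sequence[str] = ("condition1", "condition2"),
) -> ComparisonReport:
    """Assemble the machine-readable comparison report.

    ``metrics`` and ``tests`` are nested mappings of scalars; serialization
    is deterministic (sorted keys), so regenerating from identical inputs
    yields a byte-identical document.
    """
    if not metrics:
        raise ValueError("report requires at least one stage output")
    return ComparisonReport(
        schema=REPORT_SCHEMA,
        conditions=tuple(conditions),
        metrics=dict(metrics),
        tests=dict(tests),
        config=dict(config),
        seeds=dict(seeds),
    )
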