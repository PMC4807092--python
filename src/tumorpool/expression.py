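"""Between-sample expression comparison: filtering, TMM, correlations,
fold-change fractions.

The comparison follows the standard count-based workflow: genes with a
maximum read count of 20 or less across all samples are dropped; library
scaling factors are computed by trimmed mean of M-values (TMM: log2
count ratios against a reference sample, trimmed 30% on M and 5% on A,
precision-weighted by binomial delta-method variances); pairwise Pearson
correlations are taken on log2(normalized + 1); and for every sample pair
the fraction of genes exceeding a 2/3/4-fold difference is reported,
split into region-vs-region and region-vs-pooled comparisons.

The factors returned here are *effective* normalization factors: the
compositional TMM factor multiplied by the library size and rescaled so
the geometric mean over samples is 1.  Dividing counts by them puts every
sample on the geometric-mean library scale, so a sample whose counts are
uniformly doubled gets an effective factor twice its twin's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "ExpressionComparison",
    "filter_low_expression",
    "tmm_factors",
    "normalize_counts",
    "pairwise_correlation",
    "foldchange_fractions",
    "compare_expression",
]


@dataclass
class ExpressionComparison:
    """Result bundle of one expression comparison."""

    genes: list[str]
    factors: pd.Series
    correlations: pd.DataFrame
    foldchanges: pd.DataFrame

    def to_aggregate(self) -> dict:
        off = self.correlations.to_numpy()[
            ~np.eye(len(self.correlations), dtype=bool)
        ]
        fc = {
            f"{row.group}|{row.sample_a}|{row.sample_b}|{int(row.threshold)}": float(row.fraction)
            for row in self.foldchanges.itertuples(index=False)
        }
        return {
            "n_genes_retained": len(self.genes),
            "factors": {k: float(v) for k, v in self.factors.items()},
            "mean_offdiag_correlation": float(off.mean()) if off.size else None,
            "foldchange_fractions": fc,
        }


def filter_low_expression(counts: pd.DataFrame, min_max_count: int = 20) -> pd.DataFrame:
    """Keep genes whose maximum count across samples is strictly > 20."""
    return counts.loc[counts.max(axis=1) > min_max_count]


def _tmm_pair(
    x: np.ndarray,
    ref: np.ndarray,
    lib_x: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Compositional TMM factor of sample x against the reference."""
    mask = (x > 0) & (ref > 0)
    if not mask.any():
        raise ValueError("sample shares no expressed genes with the reference")
    xx = x[mask] / lib_x
    rr = ref[mask] / lib_ref
    M = np.log2(xx / rr)
    A = 0.5 * np.log2(xx * rr)
    # inverse of the binomial delta-method variance of M
    w = (lib_x - x[mask]) / (lib_x * x[mask]) + (lib_ref - ref[mask]) / (
        lib_ref * ref[mask]
    )
    if np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = M.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = _stats.rankdata(M)
    rank_a = _stats.rankdata(A)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(
    counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> pd.Series:
    """Effective TMM normalization factors, geometric mean 1.

    The reference is the sample whose upper-quartile count (scaled by
    library size) is closest to the mean upper-quartile.  Each sample's
    compositional factor is the precision-weighted mean of its trimmed
    log2 ratios against the reference; the effective factor multiplies in
    the library size.
    """
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    mat = counts.to_numpy(float)
    lib = mat.sum(axis=0)
    if (lib <= 0).any():
        bad = counts.columns[np.flatnonzero(lib <= 0)[0]]
        raise ValueError(f"sample {bad!r} has zero library size")
    uq = np.quantile(mat, 0.75, axis=0) / lib
    ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    comp = np.array(
        [
            1.0
            if j == ref_j
            else _tmm_pair(mat[:, j], mat[:, ref_j], lib[j], lib[ref_j], trim_m, trim_a)
            for j in range(mat.shape[1])
        ]
    )
    eff = comp * lib
    eff = eff / np.exp(np.mean(np.log(eff)))
    return pd.Series(eff, index=counts.columns, name="tmm_factor")


def normalize_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Scale each sample by its effective TMM factor."""
    if factors is None:
        factors = tmm_factors(counts)
    return counts.div(factors, axis=1)


def pairwise_correlation(normalized: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Pearson r of log2(normalized + pseudocount) for every sample pair."""
    logged = np.log2(normalized.to_numpy(float) + pseudocount)
    r = np.corrcoef(logged.T)
    return pd.DataFrame(r, index=normalized.columns, columns=normalized.columns)


def foldchange_fractions(
    normalized: pd.DataFrame,
    pooled_id: str | None = None,
    thresholds: tuple[float, ...] = (2.0, 3.0, 4.0),
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Fraction of genes beyond each fold threshold, for every sample pair.

    Pairs involving ``pooled_id`` form the region-vs-pooled group (four
    comparisons for a 4-region design); the rest are region-vs-region (six
    comparisons).  The fraction denominator is the retained gene count.
    """
    cols = list(normalized.columns)
    logged = {c: np.log2(normalized[c].to_numpy(float) + pseudocount) for c in cols}
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            group = (
                "region_vs_pooled"
                if pooled_id is not None and pooled_id in (a, b)
                else "region_vs_region"
            )
            d = np.abs(logged[a] - logged[b])
            for t in thresholds:
                rows.append(
                    {
                        "sample_a": a,
                        "sample_b": b,
                        "group": group,
                        "threshold": float(t),
                        "fraction": float((d > np.log2(t)).mean()),
                    }
                )
    return pd.DataFrame(rows)


def compare_expression(
    counts: pd.DataFrame,
    pooled_id: str | None = None,
    thresholds: tuple[float, ...] = (2.0, 3.0, 4.0),
    min_max_count: int = 20,
) -> ExpressionComparison:
    """Full comparison: filter, TMM-normalize, correlate, fold-change table."""
    kept = filter_low_expression(counts, min_max_count)
    factors = tmm_factors(kept)
    norm = normalize_counts(kept, factors)
    corr = pairwise_correlation(norm)
    fc = foldchange_fractions(norm, pooled_id=pooled_id, thresholds=thresholds)
    return ExpressionComparison(
        genes=list(kept.index), factors=factors, correlations=corr, foldchanges=fc
    )
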