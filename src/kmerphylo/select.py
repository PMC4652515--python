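"""Informative k-mer feature selection.

Two stages, both on the compositional (TSS) matrix:

1. unsupervised minimum-IQR filter — drop k-mers whose interquartile range
   across samples falls in the first quartile of all k-mer IQRs (the least
   variable ~25% carry no signal);
2. two-sided Wilcoxon rank-sum differential-abundance test between the two
   class labels, Bonferroni-corrected at a family-wise alpha (default
   0.1%).

The rank-sum test follows R's ``wilcox.test`` switching rule: the exact
null distribution when both groups have fewer than 50 observations and the
pooled values are tie-free, otherwise the tie-corrected normal
approximation with continuity correction. The exact branch matters at
moderate sample sizes: with 20 cells per class the normal approximation
bottoms out near 7e-8 and could never clear a Bonferroni threshold of
0.001/m for m beyond ~15,000 k-mers, while the exact floor is
2/C(40,20) ~ 1.5e-11.

Quantile convention: linear interpolation between order statistics; rows
with IQR <= Q1 are removed (inclusive at the boundary).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import AbundanceMatrix


@dataclass
class SelectionResult:
    kept_kmers: list[str]
    n_before: int
    n_after: int
    threshold: float
    p_values: np.ndarray | None = None

    def __post_init__(self):
        if self.n_after != len(self.kept_kmers):
            raise ValueError("n_after must equal |kept_kmers|")
        if self.n_after > self.n_before:
            raise ValueError("kept set larger than tested set")


def as_label_series(labels, samples: list[str]) -> pd.Series:
    """Normalize a dict/Series of sample -> class into a Series aligned with
    ``samples``; every sample must be labeled."""
    series = pd.Series(labels)
    missing = [s for s in samples if s not in series.index]
    if missing:
        raise ValueError(f"samples without labels: {missing}")
    extra = [s for s in series.index if s not in samples]
    if extra:
        raise ValueError(f"labels for unknown samples: {extra}")
    return series.loc[samples]


def iqr_filter(a: AbundanceMatrix) -> tuple[AbundanceMatrix, SelectionResult]:
    """Remove k-mers whose IQR lies in the first quartile of all IQRs."""
    if a.n_kmers < 4:
        raise ValueError("need >= 4 k-mers for IQR filtering")
    q75, q25 = np.percentile(a.values, [75, 25], axis=1)
    iqrs = q75 - q25
    q1 = np.percentile(iqrs, 25)
    if np.all(iqrs == iqrs[0]):
        warnings.warn("all k-mer IQRs identical; nothing removed", stacklevel=2)
        keep = np.ones(a.n_kmers, dtype=bool)
    else:
        keep = iqrs > q1
    out = a.subset_rows(keep)
    result = SelectionResult(
        kept_kmers=list(out.kmers),
        n_before=a.n_kmers,
        n_after=out.n_kmers,
        threshold=float(q1),
    )
    return out, result


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null distribution when both groups have < 50 observations and
    there are no ties (the R wilcox.test rule); otherwise the tie-corrected
    normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 1 or y.size < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    exact_ok = x.size < 50 and y.size < 50 and not has_ties
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if exact_ok else "asymptotic",
        use_continuity=True,
    )
    return float(min(res.pvalue, 1.0))


def _rank_sum_pvalues(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise two-sided rank-sum p-values with the exact/asymptotic
    switch applied per row (exact only where the pooled row is tie-free)."""
    n_rows = x.shape[0]
    pvals = np.ones(n_rows)
    pooled = np.concatenate([x, y], axis=1)
    srt = np.sort(pooled, axis=1)
    tied = (np.diff(srt, axis=1) == 0).any(axis=1)
    constant = (pooled == pooled[:, :1]).all(axis=1)
    exact_ok = x.shape[1] < 50 and y.shape[1] < 50

    groups = [(~tied, "exact")] if exact_ok else [(~tied, "asymptotic")]
    groups.append((tied & ~constant, "asymptotic"))
    for rows, method in groups:
        if rows.any():
            res = stats.mannwhitneyu(
                x[rows], y[rows], alternative="two-sided", method=method,
                use_continuity=True, axis=1,
            )
            pvals[rows] = np.minimum(
                np.asarray(res.pvalue, dtype=np.float64), 1.0
            )
    pvals[constant] = 1.0
    return pvals


def select_differential(
    a: AbundanceMatrix,
    labels,
    alpha: float = 0.001,
    bonferroni: bool = True,
) -> tuple[AbundanceMatrix, SelectionResult]:
    """Keep k-mers differentially abundant between the two classes.

    Bonferroni: keep raw p <= alpha / m with m = rows tested here (the
    IQR-filtered set). ``bonferroni=False`` switches to Benjamini-Hochberg
    FDR at the same alpha, as a convenience.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    series = as_label_series(labels, a.samples)
    classes = sorted(series.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    mask = (series == classes[0]).to_numpy()
    if mask.sum() < 2 or (~mask).sum() < 2:
        warnings.warn("a class has < 2 samples; test power is degenerate",
                      stacklevel=2)
    x = a.values[:, mask]
    y = a.values[:, ~mask]
    pvals = _rank_sum_pvalues(x, y)

    m = a.n_kmers
    if bonferroni:
        threshold = alpha / m
        nx, ny = int(mask.sum()), int((~mask).sum())
        if nx < 50 and ny < 50:
            from math import comb

            floor = 2.0 / comb(nx + ny, nx)
            if threshold < floor:
                warnings.warn(
                    f"Bonferroni threshold {threshold:.3g} lies below the "
                    f"smallest attainable exact rank-sum p-value "
                    f"{floor:.3g} for {nx} vs {ny} samples; no k-mer can "
                    "be selected at this alpha / sample size",
                    stacklevel=2,
                )
        keep = pvals <= threshold
    else:
        order = np.argsort(pvals)
        ranked = pvals[order]
        below = ranked <= alpha * np.arange(1, m + 1) / m
        cutoff_rank = np.flatnonzero(below).max() + 1 if below.any() else 0
        threshold = float(ranked[cutoff_rank - 1]) if cutoff_rank else 0.0
        keep = pvals <= threshold if cutoff_rank else np.zeros(m, dtype=bool)

    out = a.subset_rows(keep)
    result = SelectionResult(
        kept_kmers=list(out.kmers),
        n_before=m,
        n_after=out.n_kmers,
        threshold=float(threshold),
        p_values=pvals,
    )
    return out, result
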