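"""Permutation test for class separation in a distance structure.

The separation statistic is the ratio of the mean pairwise distance within
classes to the mean pairwise distance between classes; values below 1 mean
cells of the same class sit closer together than cells of different
classes. Significance comes from permuting the label vector: under the
null hypothesis that labels are exchangeable the statistic concentrates
near 1, and the one-sided p-value is the (add-one smoothed) fraction of
permutations at or below the observed value:

    p = (1 + #{null <= observed}) / (1 + n_permutations)

so p can never be zero and bottoms out at 1/(n_permutations + 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .distance import DistanceMatrix
from .select import as_label_series


@dataclass
class PartitionTestResult:
    observed_statistic: float
    null_mean: float
    null_sd: float
    n_permutations: int
    p_value: float
    seed: int | None

    def __post_init__(self):
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("p_value must be in (0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")

    def to_json(self) -> str:
        return json.dumps(vars(self), indent=2)


def _pair_arrays(d: DistanceMatrix, labels):
    series = as_label_series(labels, d.samples)
    codes = series.astype("category").cat.codes.to_numpy()
    if np.unique(codes).size < 2:
        raise ValueError("need >= 2 classes")
    iu = np.triu_indices(d.n_samples, k=1)
    dvec = d.values[iu]
    return codes, iu, dvec


def _statistic(codes, iu, dvec, raw_sums: bool) -> float:
    same = codes[iu[0]] == codes[iu[1]]
    if not same.any():
        raise ValueError("no within-class pairs (all classes are singletons)")
    if same.all():
        raise ValueError("no between-class pairs")
    within = dvec[same]
    between = dvec[~same]
    if raw_sums:
        denom = between.sum()
    else:
        denom = between.mean()
    if denom == 0:
        raise ValueError("between-class distances are all zero")
    return float((within.sum() if raw_sums else within.mean()) / denom)


def separation_statistic(d: DistanceMatrix, labels,
                         raw_sums: bool = False) -> float:
    """Mean within-class / mean between-class pairwise distance (pooled over
    all classes). ``raw_sums=True`` uses raw sums instead of means, which
    is size-biased for unequal classes."""
    codes, iu, dvec = _pair_arrays(d, labels)
    return _statistic(codes, iu, dvec, raw_sums)


def permutation_test(
    d: DistanceMatrix,
    labels,
    n_permutations: int = 10_000,
    seed: int | None = None,
    raw_sums: bool = False,
) -> PartitionTestResult:
    """One-sided permutation test (small statistic = classes are clustered)."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    codes, iu, dvec = _pair_arrays(d, labels)
    observed = _statistic(codes, iu, dvec, raw_sums)
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for t in range(n_permutations):
        null[t] = _statistic(rng.permutation(codes), iu, dvec, raw_sums)
    p = (1 + int((null <= observed).sum())) / (1 + n_permutations)
    sd = float(null.std(ddof=1)) if n_permutations > 1 else 0.0
    return PartitionTestResult(
        observed_statistic=observed,
        null_mean=float(null.mean()),
        null_sd=sd,
        n_permutations=n_permutations,
        p_value=p,
        seed=seed,
    )
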