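"""Noise correction and normalization of the k-mer count matrix.

Pipeline order: sparse-occurrence filter (sequencing-error k-mers appear at
low multiplicity) -> presence filter (WGA amplifies regions unevenly, so
only k-mers observed in all samples are comparable) -> duplicate-sample
removal (identical raw count vectors indicate a resequenced cell) -> Total
Sum Scaling to compositional relative abundances.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .matrix import AbundanceMatrix, CountMatrix


@dataclass
class FilterReport:
    """Bookkeeping for the k-mer space reduction; counts reconcile exactly:
    n_input_kmers = n_removed_sparse + n_removed_not_ubiquitous + n_retained.
    """

    n_input_kmers: int = 0
    n_removed_sparse: int = 0
    n_removed_not_ubiquitous: int = 0
    n_retained: int = 0
    removed_duplicate_samples: list[str] = field(default_factory=list)

    def __post_init__(self):
        total = (self.n_removed_sparse + self.n_removed_not_ubiquitous
                 + self.n_retained)
        if self.n_input_kmers != total:
            raise ValueError(
                f"filter bookkeeping does not reconcile: {self.n_input_kmers} "
                f"input != {total} accounted"
            )

    def to_json(self) -> str:
        return json.dumps(vars(self), indent=2)


def filter_sparse(
    m: CountMatrix, min_count: int = 2
) -> tuple[CountMatrix, FilterReport]:
    """Zero out entries below ``min_count`` per sample and drop rows that
    become empty — the sequencing-error correction."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    values = m.values.copy()
    if values.nnz:
        values.data[values.data < min_count] = 0
        values.eliminate_zeros()
    keep = np.diff(values.indptr) > 0
    report = FilterReport(
        n_input_kmers=m.n_kmers,
        n_removed_sparse=int((~keep).sum()),
        n_retained=int(keep.sum()),
    )
    out = CountMatrix(m.kmer_codes[keep], list(m.samples), values[keep], m.k)
    return out, report


def filter_ubiquitous(
    m: CountMatrix, presence_fraction: float = 1.0
) -> tuple[CountMatrix, FilterReport]:
    """Retain k-mers present (count > 0) in at least ``presence_fraction`` of
    samples; the default 1.0 keeps only k-mers occurring in *all* samples,
    the strict WGA criterion. Lower fractions give the relaxed filter for
    amplification-free protocols."""
    if m.n_samples < 1:
        raise ValueError("need at least one sample")
    if not 0.0 < presence_fraction <= 1.0:
        raise ValueError("presence_fraction must be in (0, 1]")
    need = math.ceil(presence_fraction * m.n_samples)
    present_in = np.diff(m.values.indptr)  # CSR: nnz per row
    keep = present_in >= need
    report = FilterReport(
        n_input_kmers=m.n_kmers,
        n_removed_not_ubiquitous=int((~keep).sum()),
        n_retained=int(keep.sum()),
    )
    if report.n_retained < 2:
        warnings.warn(
            f"presence filter retained {report.n_retained} k-mers; "
            "downstream stages need >= 2 features",
            stacklevel=2,
        )
    out = CountMatrix(m.kmer_codes[keep], list(m.samples), m.values[keep], m.k)
    return out, report


def detect_duplicates(m: CountMatrix) -> list[tuple[str, str]]:
    """All unordered sample pairs with exactly identical raw count vectors."""
    if m.n_samples < 2:
        raise ValueError("need >= 2 samples to compare")
    csc = m.values.tocsc()
    keys: dict[bytes, list[str]] = {}
    for j, sample in enumerate(m.samples):
        col = csc[:, j]
        key = col.indices.tobytes() + b"|" + col.data.tobytes()
        keys.setdefault(key, []).append(sample)
    pairs = []
    for group in keys.values():
        group = sorted(group)
        for a in range(len(group)):
            for b in range(a + 1, len(group)):
                pairs.append((group[a], group[b]))
    return sorted(pairs)


def drop_duplicate_samples(
    m: CountMatrix,
) -> tuple[CountMatrix, list[str]]:
    """Drop the lexicographically later member(s) of each duplicate group."""
    pairs = detect_duplicates(m)
    dropped = sorted({b for _a, b in pairs})
    keep = [s for s in m.samples if s not in dropped]
    return m.subset_samples(keep), dropped


def tss_normalize(m: CountMatrix) -> AbundanceMatrix:
    """Total Sum Scaling: divide each count by its sample's total over the
    k-mers considered, yielding compositional columns that sum to 1."""
    sums = m.column_sums().astype(np.float64)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        bad = ", ".join(m.samples[j] for j in zero)
        raise ValueError(f"zero-sum sample(s), cannot TSS-normalize: {bad}")
    values = np.asarray(m.values.todense(), dtype=np.float64) / sums[None, :]
    return AbundanceMatrix(m.kmer_codes, list(m.samples), values, m.k)


def prepare_matrix(
    m: CountMatrix,
    min_count: int = 2,
    presence_fraction: float = 1.0,
    drop_duplicates: bool = True,
) -> tuple[AbundanceMatrix, FilterReport]:
    """Full normalization pipeline with reconciled bookkeeping."""
    filtered, rep1 = filter_sparse(m, min_count=min_count)
    ubiq, rep2 = filter_ubiquitous(filtered, presence_fraction=presence_fraction)
    dropped: list[str] = []
    if drop_duplicates and ubiq.n_samples >= 2:
        ubiq, dropped = drop_duplicate_samples(ubiq)
    abundance = tss_normalize(ubiq)
    report = FilterReport(
        n_input_kmers=m.n_kmers,
        n_removed_sparse=rep1.n_removed_sparse,
        n_removed_not_ubiquitous=rep2.n_removed_not_ubiquitous,
        n_retained=rep2.n_retained,
        removed_duplicate_samples=dropped,
    )
    return abundance, report


def abundance_histogram(a: AbundanceMatrix, path, bins: int = 80) -> None:
    """Histogram of log10 relative abundances (plot artifact only): on WGA
    single-cell data the pooled compositional values look log-Laplacian."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = a.values[a.values > 0]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(np.log10(vals), bins=bins, color="steelblue")
    ax.set_xlabel("log10 relative abundance")
    ax.set_ylabel("k-mer entries")
    ax.set_title(f"{a.k}-mer relative abundances")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
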