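"""End-to-end convenience wrappers used by the CLI and analysis scripts."""

from __future__ import annotations

from .counting import count_kmers, merge_spectra
from .distance import compute_distances
from .matrix import AbundanceMatrix, CountMatrix
from .prep import FilterReport, prepare_matrix


def count_dataset(fastq_by_sample: dict, k: int,
                  canonical: bool = False) -> CountMatrix:
    """Count k-mers per FASTQ file and merge into one count matrix."""
    spectra = [
        count_kmers(path, k, sample_id=str(sample), canonical=canonical)
        for sample, path in sorted(fastq_by_sample.items())
    ]
    return merge_spectra(spectra)


def preprocess(
    m: CountMatrix,
    min_count: int = 2,
    presence_fraction: float = 1.0,
    drop_duplicates: bool = True,
) -> tuple[AbundanceMatrix, FilterReport]:
    """Filters + TSS normalization (see :mod:`kmerphylo.prep`)."""
    return prepare_matrix(m, min_count=min_count,
                          presence_fraction=presence_fraction,
                          drop_duplicates=drop_duplicates)


def abundances_from_fastqs(
    fastq_by_sample: dict,
    k: int,
    min_count: int = 2,
    presence_fraction: float = 1.0,
    drop_duplicates: bool = True,
) -> tuple[AbundanceMatrix, FilterReport]:
    """FASTQ files -> filtered, TSS-normalized abundance matrix."""
    counts = count_dataset(fastq_by_sample, k)
    return preprocess(counts, min_count=min_count,
                      presence_fraction=presence_fraction,
                      drop_duplicates=drop_duplicates)


def distances_from_fastqs(fastq_by_sample: dict, k: int,
                          metric: str = "euclidean", **prep_kwargs):
    """FASTQ files -> distance matrix on the normalized k-mer abundances."""
    abundance, report = abundances_from_fastqs(fastq_by_sample, k,
                                               **prep_kwargs)
    return compute_distances(abundance, metric), abundance, report
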