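"""Per-cell k-mer spectra from FASTQ and their assembly into a count matrix.

Every length-k window of every read over {A,C,G,T} is counted once; windows
containing any other symbol are skipped. A k-mer and its reverse complement
are distinct keys by default (``canonical=True`` folds them to the
lexicographically smaller encoding), matching a plain k-mer-counter
invocation without canonicalization.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .encoding import decode_kmers, encode_kmer, revcomp_codes, window_codes
from .matrix import CountMatrix


@dataclass
class KmerSpectrum:
    """One sample's k-mer occurrence counts.

    Stored as parallel arrays of packed k-mer codes (sorted, unique) and
    positive counts; behaves as a read-only mapping from k-mer string to
    count for convenience at small scale.
    """

    k: int
    sample_id: str
    codes: np.ndarray
    counts: np.ndarray
    n_skipped_windows: int = 0

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.codes.shape != self.counts.shape:
            raise ValueError("codes and counts must be parallel arrays")
        if self.counts.size and self.counts.min() < 1:
            raise ValueError("stored counts must be >= 1")
        if np.any(np.diff(self.codes) <= 0):
            raise ValueError("codes must be sorted and unique")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __len__(self) -> int:
        return self.codes.size

    def __contains__(self, kmer: str) -> bool:
        code = encode_kmer(kmer)
        i = np.searchsorted(self.codes, code)
        return bool(i < self.codes.size and self.codes[i] == code)

    def __getitem__(self, kmer: str) -> int:
        code = encode_kmer(kmer)
        i = np.searchsorted(self.codes, code)
        if i < self.codes.size and self.codes[i] == code:
            return int(self.counts[i])
        raise KeyError(kmer)

    def get(self, kmer: str, default: int = 0) -> int:
        try:
            return self[kmer]
        except KeyError:
            return default

    def items(self):
        for kmer, count in zip(decode_kmers(self.codes, self.k), self.counts):
            yield kmer, int(count)

    def to_dict(self) -> dict[str, int]:
        return dict(self.items())

    @classmethod
    def from_dict(cls, counts: dict[str, int], k: int,
                  sample_id: str) -> "KmerSpectrum":
        codes = np.array([encode_kmer(s) for s in counts], dtype=np.int64)
        vals = np.array(list(counts.values()), dtype=np.int64)
        order = np.argsort(codes)
        return cls(k, sample_id, codes[order], vals[order])


def _iter_sequences(reads, k: int):
    """Yield read sequences from a path, file-like, or iterable of strings."""
    if isinstance(reads, (str, Path)):
        path = str(reads)
        handle = gzip.open(path, "rt") if path.endswith(".gz") else open(path)
        with handle:
            yield from _iter_fastq(handle)
    elif hasattr(reads, "read"):
        yield from _iter_fastq(reads)
    else:
        for item in reads:
            yield str(item)


def _iter_fastq(handle):
    record_index = 0
    try:
        for _title, seq, _qual in FastqGeneralIterator(handle):
            record_index += 1
            yield seq
    except ValueError as exc:
        raise ValueError(
            f"malformed FASTQ near record {record_index + 1}: {exc}"
        ) from exc


def count_kmers(reads, k: int, sample_id: str = "sample",
                canonical: bool = False,
                chunk_size: int = 100_000) -> KmerSpectrum:
    """Count all valid k-mer windows of a read set.

    ``reads`` may be a FASTQ(.gz) path, an open FASTQ handle, or an iterable
    of sequence strings. Counting is order-invariant and streaming (reads
    are processed in chunks).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    chunks: list[np.ndarray] = []
    buf: list[str] = []
    n_reads = 0
    n_skipped = 0

    def flush():
        nonlocal n_skipped
        if not buf:
            return
        codes, skipped = window_codes(buf, k)
        n_skipped += skipped
        if canonical and codes.size:
            codes = np.minimum(codes, revcomp_codes(codes, k))
        if codes.size:
            chunks.append(codes)
        buf.clear()

    for seq in _iter_sequences(reads, k):
        n_reads += 1
        buf.append(seq)
        if len(buf) >= chunk_size:
            flush()
    flush()
    if n_reads == 0:
        raise ValueError("empty read set")
    if not chunks:
        warnings.warn(
            f"sample {sample_id!r}: no length-{k} windows "
            "(k exceeds every read length?); empty spectrum",
            stacklevel=2,
        )
        return KmerSpectrum(k, sample_id, np.empty(0, np.int64),
                            np.empty(0, np.int64), n_skipped)
    codes, counts = np.unique(np.concatenate(chunks), return_counts=True)
    return KmerSpectrum(k, sample_id, codes, counts, n_skipped)


def merge_spectra(spectra: list[KmerSpectrum]) -> CountMatrix:
    """Union the spectra's k-mer keys into a sparse k-mers x samples matrix.

    Missing entries are zero; column marginals equal each spectrum's total.
    """
    if not spectra:
        raise ValueError("no spectra to merge")
    ks = {s.k for s in spectra}
    if len(ks) != 1:
        raise ValueError(f"mixed k values: {sorted(ks)}")
    ids = [s.sample_id for s in spectra]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids among spectra")

    union = np.unique(np.concatenate([s.codes for s in spectra]))
    cols = []
    for s in spectra:
        rows = np.searchsorted(union, s.codes)
        cols.append(
            sp.csc_matrix(
                (s.counts, (rows, np.zeros(len(s.codes), dtype=np.int64))),
                shape=(union.size, 1),
            )
        )
    values = sp.hstack(cols, format="csr")
    return CountMatrix(union, ids, values, ks.pop())


def expected_unique_kmers(n: int, k: int) -> int:
    """Unique k-mers of a length-N non-repetitive genome: N - k + 1."""
    if n < k:
        raise ValueError(f"genome size {n} smaller than k={k}")
    return n - k + 1


def kmer_space_size(k: int) -> int:
    """Number of distinct DNA k-mers, 4**k (exact arbitrary precision)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return 4**k
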