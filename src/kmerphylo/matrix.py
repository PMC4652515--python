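"""K-mer feature matrices.

``CountMatrix`` holds raw integer counts (k-mers x samples) in a scipy CSR
matrix keyed by packed k-mer codes: at k >= 15 the sequencing-error tail
produces millions of singleton rows, so sparse storage comes first and
strings are decoded only on demand. ``AbundanceMatrix`` holds the dense
relative abundances that survive filtering.

On-disk dialect: tab-separated with a ``#kmerphylo`` header line recording k.
The sparse form is three columns (kmer, sample, count); the dense form has
one column per sample.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .encoding import decode_kmers, encode_kmer

_MAGIC = "#kmerphylo"


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _check_labels(samples) -> list[str]:
    samples = [str(s) for s in samples]
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids")
    return samples


@dataclass
class CountMatrix:
    """Sparse k-mers x samples table of raw occurrence counts."""

    kmer_codes: np.ndarray
    samples: list[str]
    values: sp.csr_matrix
    k: int

    def __post_init__(self):
        self.kmer_codes = np.asarray(self.kmer_codes, dtype=np.int64)
        self.samples = _check_labels(self.samples)
        self.values = sp.csr_matrix(self.values)
        if self.values.shape != (self.kmer_codes.size, len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{self.kmer_codes.size} k-mers x {len(self.samples)} samples"
            )
        if self.kmer_codes.size != np.unique(self.kmer_codes).size:
            raise ValueError("duplicate k-mer rows")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("negative counts")

    @property
    def n_kmers(self) -> int:
        return self.kmer_codes.size

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def kmers(self) -> np.ndarray:
        """Row labels as ACGT strings (decoded lazily; can be large)."""
        return decode_kmers(self.kmer_codes, self.k)

    def column_sums(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=0)).ravel()

    def subset_rows(self, index) -> "CountMatrix":
        return CountMatrix(self.kmer_codes[index], list(self.samples),
                           self.values[index], self.k)

    def subset_samples(self, keep: list[str]) -> "CountMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in keep]
        return CountMatrix(self.kmer_codes, list(keep),
                           self.values[:, idx], self.k)

    def to_frame(self) -> pd.DataFrame:
        """Dense pandas view (k-mer strings as index); small matrices only."""
        return pd.DataFrame(self.values.toarray(), index=self.kmers,
                            columns=self.samples)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, k: int | None = None) -> "CountMatrix":
        kmers = [str(i) for i in df.index]
        if k is None:
            k = len(kmers[0]) if kmers else 1
        codes = np.array([encode_kmer(s) for s in kmers], dtype=np.int64)
        order = np.argsort(codes)
        vals = sp.csr_matrix(df.to_numpy()[order])
        return cls(codes[order], list(df.columns), vals, k)

    def write_tsv(self, path, dense: bool = False) -> None:
        with _open_text(path, "wt") as fh:
            fmt = "dense" if dense else "sparse"
            fh.write(f"{_MAGIC}\tcount-matrix\tk={self.k}\tformat={fmt}\n")
            if dense:
                fh.write("kmer\t" + "\t".join(self.samples) + "\n")
                dense_vals = self.values.toarray()
                for kmer, row in zip(self.kmers, dense_vals):
                    fh.write(kmer + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
            else:
                fh.write("kmer\tsample\tcount\n")
                coo = self.values.tocoo()
                kmers = self.kmers
                for i, j, v in zip(coo.row, coo.col, coo.data):
                    fh.write(f"{kmers[i]}\t{self.samples[j]}\t{int(v)}\n")

    @classmethod
    def read_tsv(cls, path) -> "CountMatrix":
        with _open_text(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if not header or header[0] != _MAGIC:
                raise ValueError(f"{path}: missing {_MAGIC} header line")
            meta = dict(f.split("=", 1) for f in header[1:] if "=" in f)
            k = int(meta["k"])
            body = fh.read()
        df = pd.read_csv(io.StringIO(body), sep="\t")
        if meta.get("format") == "dense":
            return cls.from_frame(df.set_index("kmer"), k=k)
        wide = df.pivot_table(index="kmer", columns="sample", values="count",
                              fill_value=0, aggfunc="sum")
        return cls.from_frame(wide, k=k)


@dataclass
class AbundanceMatrix:
    """Dense k-mers x samples table of relative abundances in [0, 1].

    Columns of a freshly TSS-normalized matrix sum to 1; downstream row
    filtering (IQR, differential selection) removes rows without
    renormalizing, so only non-negativity is enforced here.
    """

    kmer_codes: np.ndarray
    samples: list[str]
    values: np.ndarray
    k: int

    def __post_init__(self):
        self.kmer_codes = np.asarray(self.kmer_codes, dtype=np.int64)
        self.samples = _check_labels(self.samples)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.kmer_codes.size, len(self.samples)):
            raise ValueError("values shape inconsistent with labels")
        if self.values.size and self.values.min() < -1e-12:
            raise ValueError("negative abundances")

    n_kmers = CountMatrix.n_kmers
    n_samples = CountMatrix.n_samples
    kmers = CountMatrix.kmers

    def column_sums(self) -> np.ndarray:
        return self.values.sum(axis=0)

    def subset_rows(self, index) -> "AbundanceMatrix":
        return AbundanceMatrix(self.kmer_codes[index], list(self.samples),
                               self.values[index], self.k)

    def subset_samples(self, keep: list[str]) -> "AbundanceMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in keep]
        return AbundanceMatrix(self.kmer_codes, list(keep),
                               self.values[:, idx], self.k)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.kmers, columns=self.samples)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, k: int | None = None) -> "AbundanceMatrix":
        kmers = [str(i) for i in df.index]
        if k is None:
            k = len(kmers[0]) if kmers else 1
        codes = np.array([encode_kmer(s) for s in kmers], dtype=np.int64)
        order = np.argsort(codes)
        return cls(codes[order], list(df.columns), df.to_numpy()[order], k)

    def write_tsv(self, path) -> None:
        with _open_text(path, "wt") as fh:
            fh.write(f"{_MAGIC}\tabundance-matrix\tk={self.k}\tformat=dense\n")
            fh.write("kmer\t" + "\t".join(self.samples) + "\n")
            for kmer, row in zip(self.kmers, self.values):
                fh.write(kmer + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")

    @classmethod
    def read_tsv(cls, path) -> "AbundanceMatrix":
        with _open_text(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if not header or header[0] != _MAGIC:
                raise ValueError(f"{path}: missing {_MAGIC} header line")
            meta = dict(f.split("=", 1) for f in header[1:] if "=" in f)
            df = pd.read_csv(fh, sep="\t").set_index("kmer")
        return cls.from_frame(df, k=int(meta["k"]))
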