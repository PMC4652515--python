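"""Sample dissimilarity matrices from k-mer relative abundances.

Euclidean distances between compositional columns feed the neighbor-joining
trees; Bray-Curtis dissimilarities (bounded in [0,1], the molecular-ecology
standard for compositional data) serve exploratory ordination. For TSS
columns Bray-Curtis reduces to half the L1 distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .matrix import AbundanceMatrix

_METRICS = ("euclidean", "bray-curtis")


@dataclass
class DistanceMatrix:
    """Symmetric non-negative sample x sample dissimilarities."""

    samples: list[str]
    values: np.ndarray
    metric: str = "euclidean"

    def __post_init__(self):
        self.samples = [str(s) for s in self.samples]
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValueError(f"expected {n}x{n} matrix, got {self.values.shape}")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-8):
            raise ValueError("distance matrix diagonal is not zero")
        if self.values.min() < -1e-12:
            raise ValueError("negative distances")
        if self.metric == "bray-curtis" and self.values.max() > 1 + 1e-9:
            raise ValueError("bray-curtis dissimilarities must be <= 1")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def submatrix(self, keep: list[str]) -> "DistanceMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        idx = [pos[s] for s in keep]
        return DistanceMatrix(list(keep), self.values[np.ix_(idx, idx)],
                              self.metric)

    # ---- PHYLIP square format ------------------------------------------
    def write_phylip(self, path, name_map_path=None) -> None:
        """Square PHYLIP distance format; sample names are shortened to
        S1..Sn (<= 10 chars) with the mapping in a sidecar TSV."""
        path = Path(path)
        short = [f"S{i + 1}" for i in range(self.n_samples)]
        with open(path, "w") as fh:
            fh.write(f"    {self.n_samples}\n")
            for name, row in zip(short, self.values):
                fh.write(name.ljust(10) +
                         " ".join(f"{v:.9f}" for v in row) + "\n")
        if name_map_path is None:
            name_map_path = path.with_suffix(path.suffix + ".names")
        with open(name_map_path, "w") as fh:
            for s, full in zip(short, self.samples):
                fh.write(f"{s}\t{full}\n")

    @classmethod
    def read_phylip(cls, path, name_map_path=None,
                    metric: str = "euclidean") -> "DistanceMatrix":
        with open(path) as fh:
            n = int(fh.readline().split()[0])
            names, rows = [], []
            for _ in range(n):
                parts = fh.readline().split()
                names.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        if name_map_path is None:
            candidate = Path(str(path) + ".names")
            name_map_path = candidate if candidate.exists() else None
        if name_map_path is not None:
            mapping = {}
            with open(name_map_path) as fh:
                for line in fh:
                    short, full = line.rstrip("\n").split("\t")
                    mapping[short] = full
            names = [mapping.get(s, s) for s in names]
        return cls(names, np.array(rows), metric)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("sample\t" + "\t".join(self.samples) + "\n")
            for s, row in zip(self.samples, self.values):
                fh.write(s + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def euclidean_distances(a: AbundanceMatrix) -> DistanceMatrix:
    """d(i,j) = sqrt(sum_f (a[f,i] - a[f,j])^2) over the retained features."""
    if a.n_samples < 2:
        raise ValueError("need >= 2 samples")
    d = squareform(pdist(a.values.T, metric="euclidean"))
    return DistanceMatrix(list(a.samples), d, "euclidean")


def bray_curtis(a: AbundanceMatrix) -> DistanceMatrix:
    """d(i,j) = sum_f |a[f,i] - a[f,j]| / sum_f (a[f,i] + a[f,j])."""
    if a.n_samples < 2:
        raise ValueError("need >= 2 samples")
    sums = a.column_sums()
    zero = [s for s, t in zip(a.samples, sums) if t == 0]
    if zero:
        raise ValueError(
            f"Bray-Curtis undefined for all-zero sample(s): {zero}"
        )
    d = squareform(pdist(a.values.T, metric="braycurtis"))
    return DistanceMatrix(list(a.samples), d, "bray-curtis")


def compute_distances(a: AbundanceMatrix, metric: str) -> DistanceMatrix:
    if metric in ("euclidean",):
        return euclidean_distances(a)
    if metric in ("bray-curtis", "braycurtis"):
        return bray_curtis(a)
    raise ValueError(f"unknown metric {metric!r}; choose from {_METRICS}")
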