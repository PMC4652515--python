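"""Synthetic single-cell WGA read simulator.

Emulates the statistical structure of single-nucleus tumor sequencing for
pipeline testing: clones differ by integer copy-number profiles over genome
segments, whole-genome amplification (WGA) unevenly amplifies segments per
cell, and sequencing introduces per-base substitution errors. Reads are
short (48 bp default), single-end, with constant quality strings because no
downstream stage consumes qualities.

The generative model is an artifact choice — no trusted simulation model
exists for single-cell WGA data — and is documented in docs/methods.md:

* cell genome = concatenation of each reference segment repeated by its
  clone copy number;
* per cell and per reference segment an amplification factor
  exp(Normal(0, wga_sigma)) multiplies that segment's read-sampling weight;
* read counts per segment copy are multinomial over weights proportional to
  (segment length - read length + 1) x amplification factor, start
  positions uniform within the copy (reads never span copy junctions);
* each base substituted uniformly to one of the other three with
  probability error_rate; each read reverse-complemented with probability
  0.5 when reverse_complement is on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGT", b"TGCA"):
    _COMP[_a] = _b

QUALITY_CHAR = "I"  # constant placeholder phred symbol


@dataclass(frozen=True)
class ReferenceGenome:
    """Uniform-random genome partitioned into contiguous segments."""

    sequence: str
    segment_boundaries: tuple[tuple[int, int], ...]

    def __post_init__(self):
        n = len(self.sequence)
        expect = 0
        for start, stop in self.segment_boundaries:
            if start != expect or stop <= start:
                raise ValueError("segments must contiguously partition [0, N)")
            expect = stop
        if expect != n:
            raise ValueError("segments must cover the whole sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def n_segments(self) -> int:
        return len(self.segment_boundaries)


@dataclass(frozen=True)
class CloneProfile:
    """Per-segment integer copy numbers of one clone; ``parent`` records the
    clone-tree edge (None for the root clone)."""

    clone_id: str
    copy_number: tuple[int, ...]
    parent: str | None = None

    def __post_init__(self):
        if any(c < 0 for c in self.copy_number):
            raise ValueError("copy numbers must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults: 20 cells per clone, 48 bp reads, 20x coverage, 0.5% per-base
    substitution error, log-normal WGA sigma 0.2 (per-cell segment
    amplification swings of roughly +/-50% at two sigma — material
    unevenness while keeping a 3-fold copy-number change statistically
    detectable across 20-cell clones, the regime the method targets).
    """

    n_cells_per_clone: int = 20
    read_length: int = 48
    target_coverage: float = 20.0
    error_rate: float = 0.005
    wga_sigma: float = 0.2
    reverse_complement: bool = True
    rng_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0, 1]")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.target_coverage <= 0:
            raise ValueError("target_coverage must be > 0")
        if self.wga_sigma < 0:
            raise ValueError("wga_sigma must be >= 0")
        if self.n_cells_per_clone < 1:
            raise ValueError("n_cells_per_clone must be >= 1")


def make_reference(length: int, n_segments: int, seed: int) -> ReferenceGenome:
    """Uniform-random ACGT genome cut into ``n_segments`` near-equal segments."""
    if n_segments < 1 or length < n_segments:
        raise ValueError(
            f"need length >= n_segments >= 1, got length={length}, "
            f"n_segments={n_segments}"
        )
    rng = np.random.default_rng(seed)
    seq = _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
    cuts = np.linspace(0, length, n_segments + 1).round().astype(int)
    bounds = tuple((int(a), int(b)) for a, b in zip(cuts[:-1], cuts[1:]))
    return ReferenceGenome(seq, bounds)


def cell_segment_layout(
    ref: ReferenceGenome, clone: CloneProfile
) -> list[tuple[int, int, int]]:
    """Intervals (start, stop, reference_segment_index) of the cell genome.

    The cell genome concatenates each reference segment repeated by its copy
    number, so every copy is a separate interval tagged with its source
    segment.
    """
    if len(clone.copy_number) != ref.n_segments:
        raise ValueError(
            f"clone {clone.clone_id!r} has {len(clone.copy_number)} copy "
            f"numbers for {ref.n_segments} segments"
        )
    layout = []
    offset = 0
    for seg_idx, ((a, b), cn) in enumerate(
        zip(ref.segment_boundaries, clone.copy_number)
    ):
        for _ in range(cn):
            layout.append((offset, offset + (b - a), seg_idx))
            offset += b - a
    return layout


def simulate_cell_genome(ref: ReferenceGenome, clone: CloneProfile) -> str:
    """Realize one cell's genome from its clone copy-number profile."""
    parts = []
    for (a, b), cn in zip(ref.segment_boundaries, clone.copy_number):
        parts.append(ref.sequence[a:b] * cn)
    genome = "".join(parts)
    if not genome:
        warnings.warn(
            f"clone {clone.clone_id!r} has all-zero copy numbers: empty genome",
            stacklevel=2,
        )
    return genome


def n_reads_for(genome_length: int, cfg: SimConfig) -> int:
    """Read-count contract: round(coverage * genome_length / read_length)."""
    return int(round(cfg.target_coverage * genome_length / cfg.read_length))


def simulate_reads(
    genome: str,
    cfg: SimConfig,
    *,
    layout: list[tuple[int, int, int]] | None = None,
    wga_factors: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Draw reads from one cell genome.

    ``layout`` gives the segment-copy intervals (defaults to one interval
    covering the whole genome) and ``wga_factors`` the per-reference-segment
    amplification factors (drawn here from the configured log-normal when
    not supplied). Returns read sequences; FASTQ serialization is handled by
    :func:`write_fastq`.
    """
    if not genome:
        raise ValueError("cannot sequence an empty genome")
    if cfg.read_length > len(genome):
        raise ValueError(
            f"read_length {cfg.read_length} exceeds genome length {len(genome)}"
        )
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    if layout is None:
        layout = [(0, len(genome), 0)]
    usable = [iv for iv in layout if iv[1] - iv[0] >= cfg.read_length]
    if not usable:
        raise ValueError("no segment copy is long enough to hold a read")
    n_segments = max(iv[2] for iv in layout) + 1
    if wga_factors is None:
        wga_factors = np.exp(rng.normal(0.0, cfg.wga_sigma, size=n_segments))

    starts_per_iv = np.array([b - a - cfg.read_length + 1 for a, b, _ in usable])
    weights = starts_per_iv * wga_factors[[s for _, _, s in usable]]
    weights = weights / weights.sum()
    n_reads = n_reads_for(len(genome), cfg)
    per_iv = rng.multinomial(n_reads, weights)

    arr = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
    read_rows = []
    for (a, _b, _s), count, n_starts in zip(usable, per_iv, starts_per_iv):
        if count == 0:
            continue
        starts = a + rng.integers(0, n_starts, size=count)
        read_rows.append(arr[starts[:, None] + np.arange(cfg.read_length)])
    reads = (
        np.concatenate(read_rows)
        if read_rows
        else np.empty((0, cfg.read_length), dtype=np.uint8)
    )

    if cfg.error_rate > 0 and reads.size:
        err = rng.random(reads.shape) < cfg.error_rate
        # substitute to one of the *other* three bases, uniformly
        shift = rng.integers(1, 4, size=int(err.sum()), dtype=np.uint8)
        code = _base_to_code(reads[err])
        reads[err] = _BASES[(code + shift) % 4]
    if cfg.reverse_complement and reads.size:
        flip = rng.random(len(reads)) < 0.5
        reads[flip] = _COMP[reads[flip][:, ::-1]]
    return [row.tobytes().decode("ascii") for row in reads]


_CODE_OF_BASE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_OF_BASE[_b] = _i


def _base_to_code(bases: np.ndarray) -> np.ndarray:
    return _CODE_OF_BASE[bases]


def write_fastq(reads: list[str], cell_id: str, path) -> None:
    """Write 4-line FASTQ; qualities are a constant placeholder symbol."""
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{cell_id}.{i}\n{seq}\n+\n{QUALITY_CHAR * len(seq)}\n")


def simulate_dataset(
    ref: ReferenceGenome,
    clones: list[CloneProfile],
    cfg: SimConfig,
    out_dir,
) -> tuple[dict[str, Path], pd.DataFrame]:
    """Simulate one FASTQ per cell plus a truth label table.

    Returns (cell_id -> FASTQ path, labels DataFrame with columns
    cell_id/clone_id). Also writes ``labels.tsv`` and a flat key-value
    ``sim_config.txt`` into ``out_dir``. Fixed seed => byte-identical files.
    """
    if len(clones) < 2:
        raise ValueError("need >= 2 clones for two-class downstream analyses")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(cfg.rng_seed)
    cell_seeds = root.spawn(len(clones) * cfg.n_cells_per_clone)

    paths: dict[str, Path] = {}
    rows = []
    i = 0
    for clone in clones:
        genome = simulate_cell_genome(ref, clone)
        layout = cell_segment_layout(ref, clone)
        for j in range(cfg.n_cells_per_clone):
            cell_id = f"{clone.clone_id}_{j:03d}"
            rng = cell_seeds[i]
            i += 1
            wga = np.exp(rng.normal(0.0, cfg.wga_sigma, size=ref.n_segments))
            reads = simulate_reads(genome, cfg, layout=layout,
                                   wga_factors=wga, rng=rng)
            path = out_dir / f"{cell_id}.fastq"
            try:
                write_fastq(reads, cell_id, path)
            except OSError as exc:
                raise OSError(f"failed writing {path}: {exc}") from exc
            paths[cell_id] = path
            rows.append({"cell_id": cell_id, "clone_id": clone.clone_id})

    labels = pd.DataFrame(rows)
    labels.to_csv(out_dir / "labels.tsv", sep="\t", index=False)
    with open(out_dir / "sim_config.txt", "w") as fh:
        for key, val in vars(cfg).items():
            fh.write(f"{key}={val}\n")
        fh.write(f"ref_length={ref.length}\nn_segments={ref.n_segments}\n")
    return paths, labels


def two_clone_profiles(
    n_segments: int,
    n_gain_segments: int,
    gain_copy_number: int = 3,
    base_copy_number: int = 1,
) -> list[CloneProfile]:
    """Convenience pair of clones: ancestral flat profile vs a derived clone
    with ``gain_copy_number`` copies on the first ``n_gain_segments``."""
    if n_gain_segments > n_segments:
        raise ValueError("more gained segments than segments")
    base = (base_copy_number,) * n_segments
    gained = (gain_copy_number,) * n_gain_segments + (
        base_copy_number,
    ) * (n_segments - n_gain_segments)
    return [
        CloneProfile("cloneA", base, parent=None),
        CloneProfile("cloneB", gained, parent="cloneA"),
    ]
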