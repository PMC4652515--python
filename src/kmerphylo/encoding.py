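"""Two-bit k-mer encoding.

K-mers over {A,C,G,T} are packed into int64 codes (A=0, C=1, G=2, T=3,
big-endian in the sequence direction), so a whole spectrum is two numpy
arrays instead of millions of Python strings. k <= 31 fits in a signed
64-bit integer; the package targets k <= 25.
"""

from __future__ import annotations

import numpy as np

MAX_K = 31

# byte -> 2-bit code lookup; 255 marks anything outside ACGT (case-insensitive)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode_bases(seq: str) -> np.ndarray:
    """Per-base 2-bit codes for ``seq``; non-ACGT bases become 255."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def encode_kmer(kmer: str) -> int:
    """Pack a single ACGT string into its integer code."""
    codes = encode_bases(kmer)
    if codes.size == 0 or codes.size > MAX_K or (codes >= 4).any():
        raise ValueError(f"not an ACGT k-mer of length <= {MAX_K}: {kmer!r}")
    val = 0
    for c in codes:
        val = (val << 2) | int(c)
    return val


def decode_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """Unpack integer codes back to an array of ACGT strings."""
    codes = np.asarray(codes, dtype=np.int64)
    shifts = 2 * np.arange(k - 1, -1, -1, dtype=np.int64)
    digits = (codes[:, None] >> shifts[None, :]) & 3
    chars = np.ascontiguousarray(_BASES[digits])
    return chars.view(f"S{k}").ravel().astype(str)


def revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement packed k-mer codes (A<->T, C<->G, order reversed)."""
    codes = np.asarray(codes, dtype=np.int64)
    out = np.zeros_like(codes)
    work = codes.copy()
    for _ in range(k):
        out = (out << 2) | (3 - (work & 3))
        work >>= 2
    return out


def window_codes(seqs: list[str], k: int) -> tuple[np.ndarray, int]:
    """All valid length-k window codes across ``seqs``.

    A read of length L contributes max(0, L-k+1) windows; windows containing
    any non-ACGT base are skipped. Returns (codes, n_skipped) where codes is
    one entry per *occurrence* (not yet aggregated) in read order within each
    length group.
    """
    if not 1 <= k <= MAX_K:
        raise ValueError(f"k must be in [1, {MAX_K}], got {k}")
    by_len: dict[int, list[str]] = {}
    for s in seqs:
        by_len.setdefault(len(s), []).append(s)

    chunks: list[np.ndarray] = []
    n_skipped = 0
    for length in sorted(by_len):
        if length < k:
            continue
        group = by_len[length]
        raw = np.frombuffer("".join(group).encode("ascii"), dtype=np.uint8)
        codes = _CODE[raw].reshape(len(group), length)
        w = length - k + 1
        bad = codes >= 4
        # windows touching a bad base, via cumulative bad-count differences
        cum = np.zeros((len(group), length + 1), dtype=np.int32)
        np.cumsum(bad, axis=1, out=cum[:, 1:])
        window_bad = (cum[:, k:] - cum[:, :-k]) > 0
        vals = np.zeros((len(group), w), dtype=np.int64)
        for j in range(k):
            vals += codes[:, j : j + w].astype(np.int64) << (2 * (k - 1 - j))
        keep = ~window_bad
        n_skipped += int(window_bad.sum())
        chunks.append(vals[keep])
    if not chunks:
        return np.empty(0, dtype=np.int64), n_skipped
    return np.concatenate(chunks), n_skipped
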