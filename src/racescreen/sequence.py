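"""Nucleotide encoding helpers shared by the simulator and the read filters.

Sequences are held as uint8 code matrices (A=0, C=1, G=2, T=3, N=4) so that
filtering and counting over tens of millions of reads stays vectorized.
Fixed-length motifs are additionally packed into base-4 integers ("codes"):
the leftmost base is the most significant digit, so a 15mer spanning +2..+16
packs +2 into the top two bits.
"""

from __future__ import annotations

import numpy as np

A, C, G, T, N = 0, 1, 2, 3, 4

_BASES = "ACGTN"
_ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = np.array([T, G, C, A, N], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to a uint8 code vector (N for anything odd)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` for one code vector."""
    return "".join(_BASES[c] for c in np.asarray(codes))


def decode_matrix(mat: np.ndarray) -> list[str]:
    """Decode each row of an (n, L) code matrix to a string."""
    lut = np.frombuffer(_BASES.encode(), dtype=np.uint8)
    as_bytes = lut[mat]
    return [bytes(row).decode("ascii") for row in as_bytes]


def revcomp_str(seq: str) -> str:
    return decode(_COMPLEMENT[encode(seq)][::-1])


def revcomp_matrix(mat: np.ndarray) -> np.ndarray:
    """Reverse-complement every row of a code matrix (no N allowed)."""
    return _COMPLEMENT[mat[:, ::-1]]


def pack(mat: np.ndarray) -> np.ndarray:
    """Pack an (n, k) code matrix (k <= 15, ACGT only) into base-4 integers."""
    k = mat.shape[1]
    out = np.zeros(mat.shape[0], dtype=np.int64)
    for j in range(k):
        out = (out << 2) | mat[:, j].astype(np.int64)
    return out


def unpack(codes: np.ndarray, k: int) -> np.ndarray:
    """Inverse of :func:`pack`: (n,) integers -> (n, k) code matrix."""
    codes = np.asarray(codes, dtype=np.int64)
    out = np.empty((codes.shape[0], k), dtype=np.uint8)
    for j in range(k):
        out[:, k - 1 - j] = (codes >> (2 * j)) & 3
    return out


def pack_str(seq: str) -> int:
    codes = encode(seq)
    if (codes >= 4).any():
        raise ValueError(f"non-ACGT character in {seq!r}")
    return int(pack(codes[None, :])[0])


def unpack_str(code: int, k: int) -> str:
    return decode(unpack(np.array([code]), k)[0])


def all_kmers(k: int) -> list[str]:
    """All 4**k k-mers in code (lexicographic ACGT) order."""
    return decode_matrix(unpack(np.arange(4**k), k))


def subcode(codes: np.ndarray, k: int, start: int, length: int) -> np.ndarray:
    """Extract a packed sub-motif from packed k-mers.

    ``start`` is the 0-based offset of the sub-motif within the k-mer
    (e.g. the +4..+8 5mer inside a +2..+16 15mer has start=2, length=5).
    """
    shift = 2 * (k - start - length)
    mask = (1 << (2 * length)) - 1
    return (np.asarray(codes, dtype=np.int64) >> shift) & mask


def max_run_length(seq: str) -> int:
    """Length of the longest homopolymer run in a string."""
    best = run = 0
    prev = ""
    for ch in seq:
        run = run + 1 if ch == prev else 1
        prev = ch
        best = max(best, run)
    return best
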