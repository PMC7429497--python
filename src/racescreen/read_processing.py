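"""Read filtering for 5'RACE-Seq libraries.

Stage order (as the screening protocol applies them): contaminant removal,
15mer–UMI deduplication, structural 5'-end filter (C at read position 16,
AA/CA/CC at 17–18, then a poly(A) tail), reverse-complementation into RNA
sense, and a constant-sequence cross-contamination filter on the +2..+11
10mer (Hamming distance ≤ 1 against any window of the library constants,
both strands). Read positions are 1-based; promoter positions are TSS
coordinates with +1 the first transcribed base.

All filters run on uint8 code matrices; scalar convenience wrappers are
provided for single reads.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .config import ScreenConfig
from .sequence import (
    A, C, G, T, N,
    decode_matrix, encode, pack, pack_str, revcomp_matrix, unpack,
)

VALID_1718 = ("AA", "CA", "CC")  # whitelist at read positions 17-18


# --------------------------------------------------------------------------
# Result containers
# --------------------------------------------------------------------------

@dataclass
class FilteredReads:
    """Accepted reads: RNA-sense +2..+16 15mer, extra-C count, UMI."""

    motif_codes: np.ndarray  # packed sense 15mers
    extra_c: np.ndarray  # 0/1/2 per read
    umi_codes: np.ndarray  # packed UMIs
    umi_len: int = 5

    def __len__(self) -> int:
        return self.motif_codes.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "motif15": decode_matrix(unpack(self.motif_codes, 15)),
                "extra_c": self.extra_c.astype(int),
                "umi": decode_matrix(unpack(self.umi_codes, self.umi_len)),
            }
        )

    def save_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# accepted 5'RACE reads; motif15 is RNA-sense +2..+16\n")
            self.to_dataframe().to_csv(fh, sep="\t", index=False)

    @classmethod
    def load_tsv(cls, path) -> "FilteredReads":
        df = pd.read_csv(path, sep="\t", comment="#")
        motifs = np.array([pack_str(m) for m in df["motif15"]])
        umis = np.array([pack_str(u) for u in df["umi"]])
        umi_len = len(df["umi"].iloc[0]) if len(df) else 5
        return cls(
            motif_codes=motifs,
            extra_c=df["extra_c"].to_numpy(np.uint8),
            umi_codes=umis,
            umi_len=umi_len,
        )


@dataclass
class FilterStats:
    """Telescoping per-stage read counts."""

    input: int = 0
    contaminant_removed: int = 0
    dedup_removed: int = 0
    structure_failed: int = 0
    polyA_failed: int = 0
    constant_match_removed: int = 0
    accepted: int = 0

    def telescopes(self) -> bool:
        removed = (
            self.contaminant_removed + self.dedup_removed + self.structure_failed
            + self.polyA_failed + self.constant_match_removed
        )
        return self.input == self.accepted + removed

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


# --------------------------------------------------------------------------
# Contaminant (PhiX-like) k-mer filter
# --------------------------------------------------------------------------

class ContaminantIndex:
    """Exact k-mer index over contaminant sequences, both strands."""

    def __init__(self, sequences, k: int = 21):
        if k < 11:
            raise ValueError("k must be >= 11")
        self.k = k
        kmers: set[int] = set()
        for seq in sequences:
            for s in (seq, _revcomp_str(seq)):
                codes = encode(s)
                for i in range(len(s) - k + 1):
                    window = codes[i : i + k]
                    if (window >= 4).any():
                        continue
                    kmers.add(int(pack(window[None, :])[0]))
        self._sorted = np.array(sorted(kmers), dtype=np.int64)

    def __len__(self) -> int:
        return self._sorted.shape[0]

    def hits(self, mat: np.ndarray) -> np.ndarray:
        """Number of indexed k-mers per read of an (n, L) code matrix."""
        n, L = mat.shape
        k = self.k
        if L < k or len(self) == 0:
            return np.zeros(n, dtype=np.int32)
        has_n = (mat >= 4).any(axis=1)  # N never matches; mask those reads out
        m64 = mat.astype(np.int64)
        code = np.zeros(n, dtype=np.int64)
        for j in range(k):
            code = (code << 2) | m64[:, j]
        mask = (1 << (2 * (k - 1))) - 1
        hits = np.zeros(n, dtype=np.int32)
        for start in range(L - k + 1):
            if start > 0:
                code = ((code & mask) << 2) | m64[:, start + k - 1]
            idx = np.searchsorted(self._sorted, code)
            idx[idx == len(self._sorted)] = 0
            hits += self._sorted[idx] == code
        hits[has_n] = 0
        return hits


def _revcomp_str(seq: str) -> str:
    comp = str.maketrans("ACGTN", "TGCAN")
    return seq.translate(comp)[::-1]


def contaminant_filter(
    read1_seq: str, index: ContaminantIndex | None, min_hits: int = 1
) -> bool:
    """Keep? A read is a contaminant when >= min_hits of its k-mers hit."""
    if index is None:
        return True
    if len(index) == 0:
        raise ValueError("contaminant filtering enabled with an empty index")
    mat = encode(read1_seq)[None, :]
    return int(index.hits(mat)[0]) < min_hits


# --------------------------------------------------------------------------
# Dedup
# --------------------------------------------------------------------------

def _dedup_keep_mask(key15: np.ndarray, umi: np.ndarray) -> np.ndarray:
    """First-occurrence mask over (15mer, UMI) keys; order preserved."""
    keys = key15 << 20 | umi  # UMIs of <=10 nt pack into 20 bits
    _, first = np.unique(keys, return_index=True)
    keep = np.zeros(keys.shape[0], dtype=bool)
    keep[first] = True
    return keep


def dedup(pairs):
    """Drop later duplicates of identical (read1 15mer, UMI) combinations.

    ``pairs`` is a sequence of (read1_seq, umi_seq) strings; the survivors
    are returned in input order.
    """
    seen: set[tuple[str, str]] = set()
    out = []
    for r1, umi in pairs:
        key = (r1[:15], umi)
        if key not in seen:
            seen.add(key)
            out.append((r1, umi))
    return out


# --------------------------------------------------------------------------
# Structural 5'-end filter
# --------------------------------------------------------------------------

def _structural_filter_matrix(
    mat: np.ndarray, polya_window: int, polya_min_frac: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized structural rule.

    Returns (structure_ok, polya_ok, extra_c); ``polya_ok`` is only
    meaningful where ``structure_ok`` holds.
    """
    n, L = mat.shape
    if L < 18 + polya_window:
        raise ValueError(f"reads must be >= {18 + polya_window} nt")
    b16, b17, b18 = mat[:, 15], mat[:, 16], mat[:, 17]
    is_aa = (b17 == A) & (b18 == A)
    is_ca = (b17 == C) & (b18 == A)
    is_cc = (b17 == C) & (b18 == C)
    extra_c = np.select([is_ca, is_cc], [1, 2], default=0).astype(np.uint8)
    structure_ok = (b16 == C) & (is_aa | is_ca | is_cc)

    # poly(A) window anchored at the first tail base: position 17/18/19
    # (0-based 16/17/18) for AA/CA/CC; per-class passes keep memory at O(n·w)
    polya_ok = np.zeros(n, dtype=bool)
    for extra in (0, 1, 2):
        rows = np.flatnonzero(extra_c == extra)
        if rows.size == 0:
            continue
        start = 16 + extra
        n_a = (mat[rows, start : start + polya_window] == A).sum(axis=1)
        polya_ok[rows] = n_a >= polya_min_frac * polya_window
    return structure_ok, polya_ok, extra_c


def structural_filter(
    read1_seq: str, polya_window: int = 10, polya_min_frac: float = 0.9
) -> tuple[bool, int]:
    """(accept?, extra_c) for one read under the 5'-end structural rule."""
    mat = encode(read1_seq)[None, :]
    s_ok, p_ok, extra = _structural_filter_matrix(mat, polya_window, polya_min_frac)
    ok = bool(s_ok[0] and p_ok[0])
    return ok, int(extra[0]) if ok else 0


# --------------------------------------------------------------------------
# Orientation
# --------------------------------------------------------------------------

def to_sense(read1_seq: str) -> str | None:
    """RNA-sense +2..+16 15mer from Read1, or None when the 15mer has an N."""
    codes = encode(read1_seq[:15])
    if (codes >= 4).any():
        return None
    return "".join(decode_matrix(revcomp_matrix(codes[None, :])))


# --------------------------------------------------------------------------
# Constant-sequence cross-contamination filter
# --------------------------------------------------------------------------

def _hamming_ball(code: int, length: int, radius: int) -> set[int]:
    out = {code}
    frontier = {code}
    for _ in range(radius):
        new = set()
        for c in frontier:
            for pos in range(length):
                shift = 2 * (length - 1 - pos)
                for b in range(4):
                    new.add((c & ~(3 << shift)) | (b << shift))
        frontier = new - out
        out |= new
    return out


def build_constant_lut(
    constants, max_mismatch: int = 1, window: int = 10
) -> np.ndarray:
    """Boolean table over all 4^window 10mers within ``max_mismatch`` of any
    length-``window`` substring of any constant sequence (either strand)."""
    lut = np.zeros(4**window, dtype=bool)
    seqs = constants.values() if isinstance(constants, dict) else constants
    for seq in seqs:
        for s in (seq, _revcomp_str(seq)):
            codes = encode(s)
            for i in range(len(s) - window + 1):
                w = codes[i : i + window]
                if (w >= 4).any():
                    continue
                base = int(pack(w[None, :])[0])
                for c in _hamming_ball(base, window, max_mismatch):
                    lut[c] = True
    return lut


def constant_seq_filter(motif15: str, constants, max_mismatch: int = 1) -> bool:
    """Keep? Discard when the +2..+11 10mer matches a constant window."""
    seqs = list(constants.values() if isinstance(constants, dict) else constants)
    if not seqs:
        raise ValueError("constant filter requires at least one constant sequence")
    lut = build_constant_lut(seqs, max_mismatch)
    return not lut[pack_str(motif15[:10])]


# --------------------------------------------------------------------------
# FASTQ loading
# --------------------------------------------------------------------------

def _open_maybe_gz(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def load_fastq_matrix(path, length: int) -> np.ndarray:
    """Load a FASTQ file into an (n, length) code matrix (N-padded)."""
    seqs: list[str] = []
    with _open_maybe_gz(path) as fh:
        it = FastqGeneralIterator(fh)
        i = 0
        while True:
            try:
                rec = next(it, None)
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record {i} in {path}: {exc}") from exc
            if rec is None:
                break
            seqs.append(rec[1][:length].ljust(length, "N"))
            i += 1
    if not seqs:
        return np.empty((0, length), dtype=np.uint8)
    buf = "".join(seqs).encode("ascii")
    from .sequence import _ENCODE
    return _ENCODE[np.frombuffer(buf, dtype=np.uint8)].reshape(len(seqs), length)


# --------------------------------------------------------------------------
# Full pipeline
# --------------------------------------------------------------------------

def process_run(
    r1,
    r2,
    config: ScreenConfig,
    contaminant_index: ContaminantIndex | None = None,
) -> tuple[FilteredReads, FilterStats]:
    """Run the full filter cascade on a read pair set.

    ``r1``/``r2`` are FASTQ paths, or ``r1`` may be a simulated
    :class:`~racescreen.synthetic_screen.ReadSet` (then ``r2`` is ignored).
    Returns the accepted reads and telescoping per-stage statistics.
    """
    from .synthetic_screen import ReadSet  # avoid import cycle

    if isinstance(r1, ReadSet):
        mat = r1.read1
        umi = r1.umi.astype(np.int64)
    else:
        mat = load_fastq_matrix(r1, config.read1_len)
        r2_mat = load_fastq_matrix(r2, config.read2_len)
        if mat.shape[0] != r2_mat.shape[0]:
            raise ValueError(
                f"record counts differ: {mat.shape[0]} in Read1 vs "
                f"{r2_mat.shape[0]} in Read2"
            )
        umi_mat = r2_mat[:, : config.umi_len]
        # base-5 packing keeps Ns distinguishable in the dedup key
        umi = np.zeros(mat.shape[0], dtype=np.int64)
        for j in range(config.umi_len):
            umi = umi * 5 + umi_mat[:, j]

    stats = FilterStats(input=mat.shape[0])
    order = np.arange(mat.shape[0])

    # 1. contaminant removal
    if contaminant_index is not None and len(contaminant_index) > 0:
        hits = contaminant_index.hits(mat)
        keep = hits < config.contaminant_min_hits
        stats.contaminant_removed = int((~keep).sum())
        mat, umi, order = mat[keep], umi[keep], order[keep]

    key15 = np.zeros(mat.shape[0], dtype=np.int64)
    for j in range(15):
        key15 = key15 * 5 + mat[:, j]

    def _dedup_stage(mat, umi, key15, order):
        keep = _dedup_keep_mask(key15, umi)
        return mat[keep], umi[keep], key15[keep], order[keep], int((~keep).sum())

    # 2. duplicate removal (before the structural filter by default)
    if not config.dedup_after_structure:
        mat, umi, key15, order, removed = _dedup_stage(mat, umi, key15, order)
        stats.dedup_removed = removed

    # 3. structural 5'-end filter; reads with N in the 15mer cannot yield a
    # motif and are counted as structural failures
    s_ok, p_ok, extra = _structural_filter_matrix(
        mat, config.polya_window, config.polya_min_frac
    )
    has_n = (mat[:, :15] >= 4).any(axis=1)
    s_ok = s_ok & ~has_n
    stats.structure_failed = int((~s_ok).sum())
    stats.polyA_failed = int((s_ok & ~p_ok).sum())
    keep = s_ok & p_ok
    mat, umi, key15, order, extra = (
        mat[keep], umi[keep], key15[keep], order[keep], extra[keep]
    )

    if config.dedup_after_structure:
        keepm = _dedup_keep_mask(key15, umi)
        stats.dedup_removed = int((~keepm).sum())
        mat, umi, order, extra = mat[keepm], umi[keepm], order[keepm], extra[keepm]

    # 4. orientation: RNA-sense +2..+16
    motif_codes = pack(revcomp_matrix(mat[:, :15]))
    del mat, key15

    # 5. constant-sequence cross-contamination filter on the +2..+11 10mer
    if config.constant_seqs:
        lut = build_constant_lut(config.constant_seqs, config.constant_max_mismatch)
        code10 = motif_codes >> 10  # top 10 of 15 bases
        keep = ~lut[code10]
        stats.constant_match_removed = int((~keep).sum())
        motif_codes, umi, extra, order = (
            motif_codes[keep], umi[keep], extra[keep], order[keep]
        )

    stats.accepted = motif_codes.shape[0]
    umi_packed = _rebase_umi(umi, config.umi_len)
    return (
        FilteredReads(
            motif_codes=motif_codes,
            extra_c=extra.astype(np.uint8),
            umi_codes=umi_packed,
            umi_len=config.umi_len,
        ),
        stats,
    )


def _rebase_umi(umi_base5_or_packed: np.ndarray, umi_len: int) -> np.ndarray:
    """Normalize UMI keys to base-4 packing (N digits collapse to A)."""
    u = umi_base5_or_packed
    if u.size == 0 or u.max() < 4**umi_len:
        return u.astype(np.int64)
    out = np.zeros_like(u)
    for j in range(umi_len):
        digit = (u // 5 ** (umi_len - 1 - j)) % 5
        out = (out << 2) | np.minimum(digit, 3)
    return out
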