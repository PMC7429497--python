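"""Ground-truth simulator for a randomized-promoter 5'RACE-Seq screen.

The generative model mirrors the screen's chemistry: a +2..+16 randomized
promoter template library (with synthesis bias) is transcribed by a phage
polymerase whose per-molecule output is weighted by the +1..+8 motif; at
the 5' terminus the polymerase may slip on G-triplet starts and add one or
two extra Gs, and the reverse transcriptase may append one non-templated C.
Each cDNA is tagged with a UMI, poly(A)-tailed, PCR-duplicated at a set
rate, and sequenced as a 35 nt Read1 (antisense) / Read2 (UMI) pair with
i.i.d. substitution errors. An aliquot of the untranscribed template is
sequenced single-end as the background library.

Everything downstream of the transcript draw is vectorized over uint8 code
matrices so that 10^7-read screens simulate in seconds.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import ScreenConfig
from .sequence import (
    A, C, G, T,
    decode, decode_matrix, encode, pack, pack_str, subcode, unpack, unpack_str,
)

# Relative strength of the +1..+3 class effect for the T7-like model; the
# +2/3 dinucleotide modulates output on top of the +4..+8 motif effect,
# with the G triplet the strongest class on average.
T7_CLASS_FOLD = 4.0
# Weight of the AT-content tilt added to the log-uniform +4..+8 draw.
AT_TILT = 0.8

_DINUCS = [unpack_str(i, 2) for i in range(16)]
_GG = pack_str("GG")
_AA = pack_str("AA")


# --------------------------------------------------------------------------
# Activity model
# --------------------------------------------------------------------------

@dataclass
class ActivityModel:
    """Latent promoter activity plus 5'-end event probabilities.

    ``class_factor`` is indexed by the packed +2/+3 dinucleotide (16 values,
    +1 is fixed), ``itr_factor`` by the packed +4..+8 5mer (1024 values);
    the transcription weight of a +1..+8 motif is their product.
    ``p_extra_g1``/``p_extra_g2`` give, per +1..+3 class, the probability of
    one / two slipped Gs; ``p_rt_c`` is the class-independent probability of
    one non-templated C added by the reverse transcriptase.
    """

    mode: str
    class_factor: np.ndarray  # (16,)
    itr_factor: np.ndarray  # (1024,)
    p_extra_g1: np.ndarray  # (16,)
    p_extra_g2: np.ndarray  # (16,)
    p_rt_c: float
    seed: int
    plus1_base: str = "G"

    def __post_init__(self) -> None:
        self.class_factor = np.asarray(self.class_factor, dtype=float)
        self.itr_factor = np.asarray(self.itr_factor, dtype=float)
        self.p_extra_g1 = np.asarray(self.p_extra_g1, dtype=float)
        self.p_extra_g2 = np.asarray(self.p_extra_g2, dtype=float)
        if self.class_factor.shape != (16,) or self.itr_factor.shape != (1024,):
            raise ValueError("class_factor must be (16,), itr_factor (1024,)")
        if (self.class_factor <= 0).any() or (self.itr_factor <= 0).any():
            raise ValueError("all transcription weights must be positive")
        for p in (self.p_extra_g1, self.p_extra_g2):
            if ((p < 0) | (p > 1)).any():
                raise ValueError("slippage probabilities must be in [0, 1]")
        if ((self.p_extra_g1 + self.p_extra_g2) > 1 + 1e-12).any():
            raise ValueError("p_extra_g1 + p_extra_g2 must be <= 1 per class")
        if not 0 <= self.p_rt_c <= 1:
            raise ValueError("p_rt_c must be in [0, 1]")

    # -------------------------------------------------------------- weights
    def weight_codes(self, codes15: np.ndarray) -> np.ndarray:
        """Transcription weight of each packed +2..+16 15mer."""
        dinuc = subcode(codes15, 15, 0, 2)
        itr = subcode(codes15, 15, 2, 5)
        return self.class_factor[dinuc] * self.itr_factor[itr]

    def weight_of(self, motif8: str) -> float:
        """Weight of a +1..+8 motif given as an 8mer (first base = +1)."""
        if len(motif8) != 8:
            raise ValueError("motif must cover +1..+8 (8 nt)")
        if motif8[0] != self.plus1_base:
            raise ValueError(f"+1 base is fixed at {self.plus1_base}")
        return float(
            self.class_factor[pack_str(motif8[1:3])]
            * self.itr_factor[pack_str(motif8[3:8])]
        )

    @property
    def weights(self) -> dict[str, float]:
        """All 16384 +1..+8 motif weights (dict keyed by 8mer)."""
        dinuc = np.repeat(np.arange(16), 1024)
        itr = np.tile(np.arange(1024), 16)
        w = self.class_factor[dinuc] * self.itr_factor[itr]
        names = [
            self.plus1_base + unpack_str(d, 2) + unpack_str(i, 5)
            for d, i in zip(dinuc, itr)
        ]
        return dict(zip(names, w))

    def class_probs(self) -> dict[str, tuple[float, float]]:
        """(p_one_extra_G, p_two_extra_G) per +1..+3 class string."""
        return {
            self.plus1_base + d: (float(self.p_extra_g1[i]), float(self.p_extra_g2[i]))
            for i, d in enumerate(_DINUCS)
        }


def _rank_uniform(raw: np.ndarray) -> np.ndarray:
    """Map raw scores to evenly spaced values on [0, 1], preserving order.

    Exponentiating the result with base ``fold`` yields factors exactly
    log-uniform with max/min == fold; the raw scores only set the order.
    """
    order = np.argsort(raw, kind="stable")
    out = np.empty_like(raw, dtype=float)
    out[order] = np.linspace(0.0, 1.0, raw.shape[0])
    return out


def _class_prob_array(spec, default_ggg: float, plus1: str) -> np.ndarray:
    """Expand a per-class probability spec into a (16,) array.

    ``spec`` may be None (default: the G-triplet class gets ``default_ggg``,
    all others 0), a scalar, or a dict keyed by +1..+3 class strings.
    """
    out = np.zeros(16)
    if spec is None:
        if plus1 == "G":
            out[_GG] = default_ggg
        return out
    if np.isscalar(spec):
        out[:] = float(spec)
        return out
    for cls, p in spec.items():
        if len(cls) != 3 or cls[0] != plus1:
            raise ValueError(f"class {cls!r} must be 3 nt starting with {plus1}")
        out[pack_str(cls[1:])] = float(p)
    return out


def build_activity_model(
    mode: str,
    fold_range: float = 5.0,
    seed: int = 0,
    *,
    p_extra_g1=None,
    p_extra_g2=None,
    p_rt_c: float | None = None,
    plus1_base: str = "G",
) -> ActivityModel:
    """Construct the screen's latent activity model.

    Modes
    -----
    ``uniform``  all weights 1 (null screen); slippage/RT events off unless
                 given explicitly.
    ``t7_like``  +4..+8 motif factors drawn log-uniform so that max/min
                 equals ``fold_range`` exactly, with an AT-content tilt
                 (AT-rich motifs biased high); a +2/3 class factor spanning
                 ~4-fold with the G triplet on top.
    ``sp6_like`` activity depends on the +2/3 dinucleotide only (16 levels
                 spanning ``fold_range``, AA on top); +4..+8 has no effect.
    """
    if fold_range < 1:
        raise ValueError("fold_range must be >= 1")
    rng = np.random.default_rng(seed)
    ones16, ones1024 = np.ones(16), np.ones(1024)

    if mode == "uniform":
        class_factor, itr_factor = ones16, ones1024
        default_slip1 = default_slip2 = 0.0
        default_rt = 0.0
    elif mode == "t7_like":
        at = (
            unpack(np.arange(1024), 5) % 3 == 0
        ).mean(axis=1)  # A=0, T=3 are the AT bases
        score = _rank_uniform(rng.random(1024) + AT_TILT * (at - 0.5))
        itr_factor = fold_range ** score
        gc = (unpack(np.arange(16), 2) == G).mean(axis=1)
        raw = 0.5 * gc + 0.5 * rng.random(16)
        raw[_GG] = 1.0  # G triplet is the strongest class
        class_factor = T7_CLASS_FOLD ** _rank_uniform(raw)
        default_slip1, default_slip2, default_rt = 0.79, 0.02, 0.05
    elif mode == "sp6_like":
        at2 = (unpack(np.arange(16), 2) % 3 == 0).mean(axis=1)
        raw = 0.5 * at2 + 0.5 * rng.random(16)
        raw[_AA] = 1.0
        class_factor = fold_range ** _rank_uniform(raw)
        itr_factor = ones1024
        default_slip1, default_slip2, default_rt = 0.79, 0.02, 0.05
    else:
        raise ValueError(f"unknown activity model mode {mode!r}")

    return ActivityModel(
        mode=mode,
        class_factor=class_factor,
        itr_factor=itr_factor,
        p_extra_g1=_class_prob_array(p_extra_g1, default_slip1, plus1_base),
        p_extra_g2=_class_prob_array(p_extra_g2, default_slip2, plus1_base),
        p_rt_c=default_rt if p_rt_c is None else float(p_rt_c),
        seed=seed,
        plus1_base=plus1_base,
    )


# --------------------------------------------------------------------------
# Template library
# --------------------------------------------------------------------------

@dataclass
class TemplateLibrary:
    """The randomized dsDNA template pool: unique 15mers and copy numbers."""

    codes: np.ndarray  # unique packed +2..+16 15mers (sense)
    counts: np.ndarray  # copies per unique 15mer
    base_bias: np.ndarray  # (15, 4) per-position synthesis frequencies

    @property
    def n_molecules(self) -> int:
        return int(self.counts.sum())

    @property
    def molecule_counts(self) -> dict[str, int]:
        """Copy-number map keyed by 15mer string (intended for small pools)."""
        return dict(zip(decode_matrix(unpack(self.codes, 15)), self.counts.tolist()))


def _as_bias_matrix(base_bias, positions: int = 15) -> np.ndarray:
    bias = np.asarray(base_bias, dtype=float)
    if bias.ndim == 1:
        bias = np.tile(bias, (positions, 1))
    if bias.shape != (positions, 4):
        raise ValueError(f"base_bias must be (4,) or ({positions}, 4)")
    if not np.allclose(bias.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("base_bias rows must sum to 1")
    if (bias < 0).any():
        raise ValueError("base_bias must be non-negative")
    return bias


def simulate_template_library(
    config: ScreenConfig, n_molecules: int, base_bias=None, seed: int = 0
) -> TemplateLibrary:
    """Draw a template pool of i.i.d. 15mers from the synthesis bias."""
    if n_molecules <= 0:
        raise ValueError("n_molecules must be positive")
    bias = _as_bias_matrix(config.base_bias if base_bias is None else base_bias)
    rng = np.random.default_rng(seed)
    cdf = np.cumsum(bias, axis=1)
    cdf[:, -1] = 1.0
    raw = np.zeros(n_molecules, dtype=np.int64)
    for j in range(15):  # position-by-position keeps peak memory at O(n)
        b = np.searchsorted(cdf[j], rng.random(n_molecules), side="right")
        raw = (raw << 2) | b
    codes, counts = np.unique(raw, return_counts=True)
    return TemplateLibrary(codes=codes, counts=counts, base_bias=bias)


# --------------------------------------------------------------------------
# Transcription
# --------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Book-keeping emitted alongside simulated reads for recovery tests."""

    model: ActivityModel
    transcript_codes: np.ndarray  # packed +2..+16 15mer per transcript
    n_extra_g: np.ndarray  # slipped Gs per transcript (0/1/2)
    rt_c: np.ndarray  # whether RT added a non-templated C (bool)

    @property
    def n_transcripts(self) -> int:
        return self.transcript_codes.shape[0]

    def transcript_counts(self, span: tuple[int, int] = (2, 16)) -> np.ndarray:
        """Dense transcript counts over the packed sub-motif of ``span``."""
        lo, hi = span
        sub = subcode(self.transcript_codes, 15, lo - 2, hi - lo + 1)
        return np.bincount(sub, minlength=4 ** (hi - lo + 1))

    def to_dataframe(self):
        """Per-15mer table: weight, transcript count, extra-G breakdown."""
        import pandas as pd

        codes, inv = np.unique(self.transcript_codes, return_inverse=True)
        n = codes.shape[0]
        counts = np.bincount(inv, minlength=n)
        g0 = np.bincount(inv[self.n_extra_g == 0], minlength=n)
        g1 = np.bincount(inv[self.n_extra_g == 1], minlength=n)
        g2 = np.bincount(inv[self.n_extra_g == 2], minlength=n)
        return pd.DataFrame(
            {
                "motif15": decode_matrix(unpack(codes, 15)),
                "weight": self.model.weight_codes(codes),
                "transcripts": counts,
                "extra_g0": g0,
                "extra_g1": g1,
                "extra_g2": g2,
            }
        )


def transcribe(
    library: TemplateLibrary,
    model: ActivityModel,
    n_transcripts: int,
    seed: int = 0,
) -> GroundTruth:
    """Sample transcripts with probability ∝ copy number × motif weight."""
    if library.codes.shape[0] == 0:
        raise ValueError("empty template library")
    if n_transcripts <= 0:
        raise ValueError("n_transcripts must be positive")
    rng = np.random.default_rng(seed)
    w = library.counts * model.weight_codes(library.codes)
    cdf = np.cumsum(w / w.sum())
    cdf[-1] = 1.0
    idx = np.searchsorted(cdf, rng.random(n_transcripts), side="right")
    codes = library.codes[idx]

    dinuc = subcode(codes, 15, 0, 2)
    p1, p2 = model.p_extra_g1[dinuc], model.p_extra_g2[dinuc]
    u = rng.random(n_transcripts)
    n_extra = np.where(u < p2, 2, np.where(u < p1 + p2, 1, 0)).astype(np.uint8)
    rt_c = rng.random(n_transcripts) < model.p_rt_c
    return GroundTruth(model=model, transcript_codes=codes, n_extra_g=n_extra, rt_c=rt_c)


# --------------------------------------------------------------------------
# Library preparation and sequencing
# --------------------------------------------------------------------------

@dataclass
class ReadSet:
    """Simulated sequencing output held as code matrices.

    ``read1`` rows are [15 nt antisense 15mer][C complementing +1][extra Cs
    from 5' events][poly(A) fill]; ``umi`` holds Read2's packed UMI;
    ``transcript_index`` maps every read (duplicates included) back to its
    ground-truth transcript. ``bg_codes`` are the packed first-15 nt of the
    single-end background reads (sequencing errors applied).
    """

    read1: np.ndarray  # (n, read1_len) uint8
    umi: np.ndarray  # (n,) packed UMIs
    transcript_index: np.ndarray  # (n,) -> GroundTruth row
    is_duplicate: np.ndarray  # (n,) bool
    bg_codes: np.ndarray  # (m,) packed background 15mers
    config: ScreenConfig

    def __len__(self) -> int:
        return self.read1.shape[0]

    # ----------------------------------------------------------- FASTQ out
    def write_fastq(self, out_dir) -> dict[str, Path]:
        """Write r1/r2/background as gzipped 4-line FASTQ (quality 'I')."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cfg = self.config
        paths = {
            "r1": out_dir / "r1.fastq.gz",
            "r2": out_dir / "r2.fastq.gz",
            "background": out_dir / "background.fastq.gz",
        }
        r1_seqs = decode_matrix(self.read1)
        fill = (cfg.constant_seqs.get("rt_primer", "") + "A" * cfg.read2_len)
        r2_seqs = [
            decode(unpack(np.array([u]), cfg.umi_len)[0]) + fill[: cfg.read2_len - cfg.umi_len]
            for u in self.umi
        ]
        _write_fastq(paths["r1"], "r1", r1_seqs)
        _write_fastq(paths["r2"], "r2", r2_seqs)

        backbone = cfg.constant_seqs.get("template_backbone", "") + "A" * cfg.read1_len
        bg_seqs = [
            decode(row) + backbone[: cfg.read1_len - 15]
            for row in unpack(self.bg_codes, 15)
        ]
        _write_fastq(paths["background"], "bg", bg_seqs)
        return paths


def _write_fastq(path: Path, prefix: str, seqs) -> None:
    # mtime=0 keeps gzip output byte-identical across runs
    with gzip.GzipFile(filename=str(path), mode="wb", mtime=0) as fh:
        chunk: list[bytes] = []
        for i, s in enumerate(seqs):
            chunk.append(f"@{prefix}.{i}\n{s}\n+\n{'I' * len(s)}\n".encode())
            if len(chunk) >= 100_000:
                fh.write(b"".join(chunk))
                chunk = []
        fh.write(b"".join(chunk))


def _apply_substitution_errors(mat: np.ndarray, rate: float, rng) -> None:
    """Sprinkle i.i.d. substitution errors over a code matrix, in place."""
    if rate <= 0:
        return
    n_cells = mat.size
    n_err = rng.binomial(n_cells, rate)
    if n_err == 0:
        return
    flat = rng.integers(0, n_cells, size=n_err)
    # substitute with one of the three *other* bases
    shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
    mat.reshape(-1)[flat] = (mat.reshape(-1)[flat] + shift) % 4


def _max_g_run(mat: np.ndarray) -> np.ndarray:
    run = np.zeros(mat.shape[0], dtype=np.int16)
    best = np.zeros(mat.shape[0], dtype=np.int16)
    for j in range(mat.shape[1]):
        is_g = mat[:, j] == G
        run = (run + 1) * is_g
        np.maximum(best, run, out=best)
    return best


def make_reads(
    truth: GroundTruth,
    config: ScreenConfig,
    error_rate: float | None = None,
    dup_rate: float | None = None,
    seed: int = 0,
    library: TemplateLibrary | None = None,
    bg_depth: int = 0,
) -> ReadSet:
    """Turn transcripts into a paired read set plus background reads.

    PCR duplicates are exact re-emissions of a molecule's reads (same
    15mer, UMI and error pattern); substitution errors are i.i.d. at
    ``error_rate``; optional dark-cycle loss drops reads whose Read1
    carries a long G run. Background reads (``bg_depth`` draws from
    ``library``) model direct sequencing of the template.
    """
    cfg = config
    error_rate = cfg.error_rate if error_rate is None else error_rate
    dup_rate = cfg.dup_rate if dup_rate is None else dup_rate
    if not 0 <= error_rate < 1 or not 0 <= dup_rate < 1:
        raise ValueError("error_rate and dup_rate must be in [0, 1)")
    n = truth.n_transcripts
    rng = np.random.default_rng(seed)

    plus1_comp = np.uint8(3 - encode(cfg.plus1_base)[0])  # complement code
    dup = np.flatnonzero(rng.random(n) < dup_rate)  # drawn first: fixed order
    total = n + dup.shape[0]
    r1 = np.full((total, cfg.read1_len), A, dtype=np.uint8)
    mat15 = unpack(truth.transcript_codes, 15)
    r1[:n, :15] = 3 - mat15[:, ::-1]  # antisense: revcomp of +2..+16
    del mat15
    r1[:n, 15] = plus1_comp
    # visible extra Cs: slipped Gs then the RT C, written 5'->3' after pos 16
    extras = truth.n_extra_g.astype(np.int16) + truth.rt_c
    for k in (1, 2, 3):
        r1[np.flatnonzero(extras >= k), 15 + k] = C

    _apply_substitution_errors(r1[:n], error_rate, rng)
    umi = np.empty(total, dtype=np.int64)
    umi[:n] = rng.integers(0, 4 ** cfg.umi_len, size=n)
    tindex = np.empty(total, dtype=np.int64)
    tindex[:n] = np.arange(n)

    # PCR duplicates: exact copies appended after the originals
    r1[n:] = r1[dup]
    umi[n:] = umi[dup]
    tindex[n:] = tindex[dup]
    is_dup = np.zeros(total, dtype=bool)
    is_dup[n:] = True

    if cfg.dark_cycle_g_run is not None and cfg.dark_cycle_loss > 0:
        hit = _max_g_run(r1) >= cfg.dark_cycle_g_run
        drop = hit & (rng.random(r1.shape[0]) < cfg.dark_cycle_loss)
        keep = ~drop
        r1, umi, tindex, is_dup = r1[keep], umi[keep], tindex[keep], is_dup[keep]

    if bg_depth:
        if library is None:
            raise ValueError("background depth requested without a template library")
        cdf = np.cumsum(library.counts / library.counts.sum())
        cdf[-1] = 1.0
        idx = np.searchsorted(cdf, rng.random(bg_depth), side="right")
        bg_mat = unpack(library.codes[idx], 15)
        _apply_substitution_errors(bg_mat, error_rate, rng)
        bg_codes = pack(bg_mat)
    else:
        bg_codes = np.empty(0, dtype=np.int64)

    return ReadSet(
        read1=r1, umi=umi, transcript_index=tindex, is_duplicate=is_dup,
        bg_codes=bg_codes, config=cfg,
    )


def simulate_screen(
    config: ScreenConfig,
    model: ActivityModel,
    depth: int,
    bg_depth: int | None = None,
    library_size: int | None = None,
    base_bias=None,
    seed: int = 0,
) -> tuple[ReadSet, GroundTruth, TemplateLibrary]:
    """One-call screen simulation: library → transcription → reads.

    ``library_size`` and ``bg_depth`` default to ``depth``; ``base_bias``
    overrides the config's synthesis bias (a (15, 4) matrix allows
    position-specific, even degenerate, template composition). Child seeds
    for the three stages are spawned deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    s_lib, s_tx, s_reads = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3))
    library = simulate_template_library(
        config, library_size if library_size is not None else depth,
        base_bias=base_bias, seed=s_lib,
    )
    truth = transcribe(library, model, depth, seed=s_tx)
    reads = make_reads(
        truth, config, seed=s_reads, library=library,
        bg_depth=depth if bg_depth is None else bg_depth,
    )
    return reads, truth, library
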