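"""Motif-level statistics for the promoter-activity screen.

The central object is a *motif table*: a pandas DataFrame indexed by motif
(RNA-sense), with raw and background counts, the background-normalized
relative abundance rel = (c/total) / (c_bg/total_bg), its log2, a dense
rank over unflagged motifs, and the two exclusion flags (low background
coverage, homopolymer). The table's position span is kept in
``df.attrs["span"]`` as an inclusive TSS-coordinate interval.

Quantiles throughout use linear interpolation (numpy's default, type 7);
rank ties are broken lexicographically by motif so ranking is a
deterministic permutation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .read_processing import FilteredReads
from .sequence import all_kmers, pack_str, subcode, unpack, unpack_str

FULL_SPAN = (2, 16)


def _span_len(span) -> int:
    lo, hi = span
    return hi - lo + 1


def _check_span(span) -> None:
    lo, hi = span
    if not (FULL_SPAN[0] <= lo <= hi <= FULL_SPAN[1]):
        raise ValueError(f"span {span} must lie within +{FULL_SPAN[0]}..+{FULL_SPAN[1]}")


def _sub_counts(codes15: np.ndarray, span, context=None) -> np.ndarray:
    """Dense counts of the packed sub-motif of every 15mer, optionally
    restricted to reads matching ``context`` = (ctx_span, ctx_seq)."""
    _check_span(span)
    lo, hi = span
    if context is not None:
        (clo, chi), cseq = context
        _check_span((clo, chi))
        if len(cseq) != chi - clo + 1:
            raise ValueError("context sequence does not match its span")
        ctx = subcode(codes15, 15, clo - 2, chi - clo + 1)
        codes15 = codes15[ctx == pack_str(cseq)]
    sub = subcode(codes15, 15, lo - 2, hi - lo + 1)
    return np.bincount(sub, minlength=4 ** _span_len(span))


def count_motifs(reads, span=(2, 8), context=None) -> pd.Series:
    """Pool reads by identical sub-motif over ``span``.

    ``reads`` is a :class:`FilteredReads`, or an array of packed 15mer
    codes (e.g. background reads). ``context`` optionally restricts to
    reads matching a fixed sequence on another span, e.g.
    ``((2, 3), "GG")`` for the G-triplet class.
    """
    codes = reads.motif_codes if isinstance(reads, FilteredReads) else np.asarray(reads)
    k = _span_len(span)
    if k <= 10:  # dense over all 4^k motifs
        counts = _sub_counts(codes, span, context)
        s = pd.Series(counts, index=all_kmers(k), name="count")
    else:  # sparse: observed motifs only
        _check_span(span)
        lo, hi = span
        if context is not None:
            (clo, chi), cseq = context
            ctx = subcode(codes, 15, clo - 2, chi - clo + 1)
            codes = codes[ctx == pack_str(cseq)]
        sub = subcode(codes, 15, lo - 2, k)
        uniq, cnt = np.unique(sub, return_counts=True)
        from .sequence import decode_matrix, unpack
        s = pd.Series(cnt, index=decode_matrix(unpack(uniq, k)), name="count")
    s.attrs["span"] = tuple(span)
    return s


def normalize(counts: pd.Series, bg_counts: pd.Series, min_bg: int = 10) -> pd.DataFrame:
    """Background-normalize motif counts into a motif table.

    rel_abundance(m) = (count/total) / (bg_count/bg_total); motifs with
    fewer than ``min_bg`` background reads are flagged ``low_background``
    and excluded from ranking (their rel_abundance is NaN).
    """
    if not counts.index.equals(bg_counts.index):
        raise ValueError("foreground and background tables must share one motif index")
    total, bg_total = int(counts.sum()), int(bg_counts.sum())
    if total == 0 or bg_total == 0:
        raise ValueError("foreground and background totals must be positive")
    df = pd.DataFrame({"count": counts, "bg_count": bg_counts})
    df["low_background"] = df["bg_count"] < min_bg
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = (df["count"] / total) / (df["bg_count"] / bg_total)
        df["rel_abundance"] = rel.where(~df["low_background"])
        df["log2_rel"] = np.log2(df["rel_abundance"])
    df["homopolymer"] = False
    df.index.name = "motif"
    df.attrs["span"] = counts.attrs.get("span")
    _assign_ranks(df)
    return df


def _assign_ranks(df: pd.DataFrame) -> None:
    """Dense 1-based ranks by descending rel_abundance over unflagged rows;
    ties broken lexicographically by motif."""
    eligible = ~(df["low_background"] | df["homopolymer"]) & df["rel_abundance"].notna()
    sub = df[eligible]
    idx = sub.index.to_numpy()
    rel = sub["rel_abundance"].to_numpy()
    perm = np.lexsort((idx, -rel))
    ranks = pd.Series(np.arange(1, len(perm) + 1), index=idx[perm])
    df["rank"] = ranks.reindex(df.index).astype("Int64")


def homopolymer_filter(
    table: pd.DataFrame,
    min_run: int = 4,
    bases: str = "ACGT",
    plus1_base: str = "G",
) -> pd.DataFrame:
    """Flag motifs whose +1-prefixed sequence carries a homopolymer run.

    A motif is flagged when ``plus1_base + motif`` contains a run of at
    least ``min_run`` identical bases drawn from ``bases`` (dark-cycle
    sequencers under-call long G stretches; the screen drops all long runs
    by default). Flagged motifs lose their rank; ranks are recomputed.
    """
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    df = table.copy()
    df.attrs = dict(table.attrs)
    baseset = set(bases)
    flags = np.array(
        [_has_run(plus1_base + m, min_run, baseset) for m in df.index], dtype=bool
    )
    df["homopolymer"] = flags
    _assign_ranks(df)
    return df


def _has_run(seq: str, min_run: int, bases: set[str]) -> bool:
    run, prev = 0, ""
    for ch in seq:
        run = run + 1 if ch == prev else 1
        prev = ch
        if run >= min_run and ch in bases:
            return True
    return False


# --------------------------------------------------------------------------
# Position-wise composition
# --------------------------------------------------------------------------

def base_frequencies(codes15: np.ndarray) -> np.ndarray:
    """(15, 4) per-position base frequencies of packed 15mers (+2..+16)."""
    codes15 = np.asarray(codes15)
    if codes15.size == 0:
        raise ValueError("no reads")
    out = np.empty((15, 4))
    mat = unpack(codes15, 15)
    for j in range(15):
        out[j] = np.bincount(mat[:, j], minlength=4) / codes15.shape[0]
    return out


def composition(f_rna, f_bg) -> pd.DataFrame:
    """Background-normalized average nucleotide composition, +2..+16.

    Inputs are (15, 4) frequency matrices or packed 15mer code arrays.
    Per position, the RNA/background frequency ratio is renormalized so
    the four bases sum to 1; a uniform ratio therefore reads 0.25.
    """
    f_rna = f_rna if np.asarray(f_rna).ndim == 2 else base_frequencies(f_rna)
    f_bg = f_bg if np.asarray(f_bg).ndim == 2 else base_frequencies(f_bg)
    f_rna, f_bg = np.asarray(f_rna, float), np.asarray(f_bg, float)
    if f_rna.shape != (15, 4) or f_bg.shape != (15, 4):
        raise ValueError("frequency matrices must be (15, 4) over +2..+16")
    if (f_bg == 0).any():
        raise ValueError("zero background frequency; cannot normalize")
    ratio = f_rna / f_bg
    ratio /= ratio.sum(axis=1, keepdims=True)
    return pd.DataFrame(
        ratio,
        index=pd.Index([f"+{p}" for p in range(2, 17)], name="position"),
        columns=list("ACGT"),
    )


# --------------------------------------------------------------------------
# Dinucleotide grouping and extra-G report
# --------------------------------------------------------------------------

def group_by_dinucleotide(table: pd.DataFrame) -> pd.DataFrame:
    """Summarize a +2..+8 motif table per +2/+3 dinucleotide (16 groups).

    Quartiles use linear interpolation; whisker bounds sit 1.5×IQR beyond
    the first/third quartile. Flagged motifs are excluded.
    """
    span = table.attrs.get("span")
    if span is not None and tuple(span)[0] != 2:
        raise ValueError("dinucleotide grouping needs a table starting at +2")
    ok = table[~(table["low_background"] | table["homopolymer"])]
    rows = []
    for i in range(16):
        dinuc = unpack_str(i, 2)
        vals = ok.loc[[m for m in ok.index if m[:2] == dinuc], "rel_abundance"]
        vals = vals.dropna().to_numpy()
        if vals.size == 0:
            rows.append({"dinuc": dinuc, "n_motifs": 0, "q1": np.nan, "median": np.nan,
                         "q3": np.nan, "whisker_lo": np.nan, "whisker_hi": np.nan,
                         "median_log2": np.nan})
            continue
        q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
        iqr = q3 - q1
        rows.append({
            "dinuc": dinuc, "n_motifs": int(vals.size),
            "q1": q1, "median": med, "q3": q3,
            "whisker_lo": q1 - 1.5 * iqr, "whisker_hi": q3 + 1.5 * iqr,
            "median_log2": np.log2(med) if med > 0 else np.nan,
        })
    return pd.DataFrame(rows).set_index("dinuc")


def extra_g_fractions(reads: FilteredReads, plus1_base: str = "G") -> pd.DataFrame:
    """Per +1..+3 class: fraction of reads with >=1 / exactly 1 / exactly 2
    extra 5' Cs, with Wilson 95% intervals on frac_ge1 and frac_eq2.

    The extra-C count conflates polymerase G-sliding with the RT's
    non-templated C; the per-class layout makes the RT baseline visible in
    classes where sliding cannot occur.
    """
    dinuc = subcode(reads.motif_codes, 15, 0, 2)
    extra = reads.extra_c.astype(int)
    rows = []
    for i in range(16):
        cls = plus1_base + unpack_str(i, 2)
        sel = extra[dinuc == i]
        n = sel.size
        if n == 0:
            rows.append({"cls": cls, "n": 0, "frac_ge1": np.nan, "frac_eq1": np.nan,
                         "frac_eq2": np.nan, "ge1_lo": np.nan, "ge1_hi": np.nan,
                         "eq2_lo": np.nan, "eq2_hi": np.nan})
            continue
        k_ge1, k_eq1, k_eq2 = (sel >= 1).sum(), (sel == 1).sum(), (sel == 2).sum()
        ge1_lo, ge1_hi = proportion_confint(k_ge1, n, method="wilson")
        eq2_lo, eq2_hi = proportion_confint(k_eq2, n, method="wilson")
        rows.append({
            "cls": cls, "n": int(n),
            "frac_ge1": k_ge1 / n, "frac_eq1": k_eq1 / n, "frac_eq2": k_eq2 / n,
            "ge1_lo": ge1_lo, "ge1_hi": ge1_hi, "eq2_lo": eq2_lo, "eq2_hi": eq2_hi,
        })
    return pd.DataFrame(rows).set_index("cls")


# --------------------------------------------------------------------------
# Ranks, fold range, replicates, oversampling
# --------------------------------------------------------------------------

def rank_motifs(table: pd.DataFrame) -> pd.DataFrame:
    """Recompute deterministic dense ranks (descending rel_abundance,
    lexicographic tie-break) over the table's unflagged motifs."""
    if len(table) == 0:
        raise ValueError("empty motif table")
    df = table.copy()
    df.attrs = dict(table.attrs)
    _assign_ranks(df)
    return df


def activity_range(
    table: pd.DataFrame, low_q: float = 0.01, high_q: float = 0.99
) -> float:
    """Fold spread of relative abundances between two quantiles.

    With quantiles (0, 1) this is max/min. Flagged motifs are excluded;
    at least 10 unflagged motifs are required.
    """
    if not 0 <= low_q < high_q <= 1:
        raise ValueError("quantiles must satisfy 0 <= low_q < high_q <= 1")
    ok = table[~(table["low_background"] | table["homopolymer"])]
    vals = ok["rel_abundance"].dropna().to_numpy()
    if vals.size < 10:
        raise ValueError("need >= 10 unflagged motifs")
    lo, hi = np.quantile(vals, [low_q, high_q])
    if lo <= 0:
        raise ValueError("lower quantile is not positive")
    return float(hi / lo)


def replicate_correlation(table_a: pd.DataFrame, table_b: pd.DataFrame) -> dict:
    """Correlation of log2 relative abundances across two replicate tables."""
    a = table_a[~(table_a["low_background"] | table_a["homopolymer"])]["log2_rel"]
    b = table_b[~(table_b["low_background"] | table_b["homopolymer"])]["log2_rel"]
    joined = pd.concat([a, b], axis=1, join="inner", keys=["a", "b"]).replace(
        [np.inf, -np.inf], np.nan
    ).dropna()
    if len(joined) < 3:
        raise ValueError("need >= 3 shared unflagged motifs")
    pearson = float(np.corrcoef(joined["a"], joined["b"])[0, 1])
    spearman = float(sps.spearmanr(joined["a"], joined["b"]).statistic)
    return {"pearson_log2": pearson, "spearman": spearman, "n_common": len(joined)}


def oversampling(total_reads: int, span=(2, 8)) -> float:
    """Average reads per possible motif: total / 4^|span|."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    k = span if isinstance(span, int) else _span_len(span)
    return total_reads / 4**k
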