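"""Score and optimize promoter + initially-transcribed-region sequences.

The screen produces a motif-activity table (rel_abundance per +4..+8 or
+2..+8 motif); this module scores an arbitrary promoter construct against
such a table, exhaustively searches small edit budgets (insertions and
substitutions inside an editable window downstream of +1) for
higher-ranking variants — the screen's own design move was inserting a GA
dinucleotide at +3/+4 — and assembles annotated primer sequences with an
optional AT-rich upstream element at −21..−18.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import T7_CORE
from .motif_stats import _assign_ranks


@dataclass
class DesignQuery:
    """An editable construct: sequence, window and edit budgets.

    ``editable_window`` is an inclusive TSS-coordinate interval strictly
    downstream of +1; insertions may land before any window position or
    directly after the last one.
    """

    sequence: str
    editable_window: tuple[int, int] = (3, 8)
    max_insertions: int = 0
    max_substitutions: int = 0
    max_total_length: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.editable_window
        if lo < 2 or hi < lo:
            raise ValueError("editable_window must lie downstream of +1")
        if self.max_insertions < 0 or self.max_substitutions < 0:
            raise ValueError("edit budgets must be >= 0")


@dataclass
class DesignResult:
    """One scored construct."""

    sequence: str
    motif: str
    rel_abundance: float
    rank: int | None
    edits: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()

    @property
    def n_edits(self) -> int:
        return len(self.edits)


def load_motif_table(path) -> pd.DataFrame:
    """Load a motif table TSV (columns ``motif``, ``rel_abundance``).

    Ranks are recomputed deterministically (descending rel_abundance,
    lexicographic tie-break); flag columns default to False when absent.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("motif", "rel_abundance"):
        if col not in df.columns:
            raise ValueError(f"motif table is missing required column {col!r}")
    if df["motif"].duplicated().any():
        dups = df.loc[df["motif"].duplicated(), "motif"].tolist()
        raise ValueError(f"duplicate motifs in table: {dups[:5]}")
    lengths = df["motif"].str.len().unique()
    if len(lengths) != 1:
        raise ValueError("all motifs must share one length")
    if not df["motif"].str.fullmatch("[ACGT]+").all():
        raise ValueError("motifs must be over ACGT")
    df = df.set_index("motif")
    for flag in ("low_background", "homopolymer"):
        if flag not in df.columns:
            df[flag] = False
    # motif length implies the span: 5mers are +4..+8, 7mers +2..+8
    k = int(lengths[0])
    df.attrs["span"] = {5: (4, 8), 7: (2, 8)}.get(k, (4, 4 + k - 1))
    _assign_ranks(df)
    return df


def _locate_tss(sequence: str, core: str) -> int:
    """0-based index of +1 (the base after the −17..−1 core promoter)."""
    pos = sequence.find(core)
    if pos < 0:
        raise ValueError("core promoter not found in sequence")
    return pos + len(core)


def score_promoter(
    sequence: str,
    table: pd.DataFrame,
    core: str = T7_CORE,
    edits: tuple[str, ...] = (),
) -> DesignResult:
    """Extract the table-span motif downstream of +1 and look up its rank."""
    tss = _locate_tss(sequence, core)
    lo, hi = table.attrs.get("span", (4, 8))
    if len(sequence) - tss < 8:
        raise ValueError("need >= 8 nt downstream of +1")
    motif = sequence[tss + lo - 1 : tss + hi]
    if motif not in table.index:
        raise KeyError(f"motif {motif!r} absent from the activity table")
    row = table.loc[motif]
    warnings = ()
    if sequence[tss : tss + 3] != "GGG":
        warnings = ("+1..+3 is not GGG; table context may not apply",)
    rank = row["rank"]
    return DesignResult(
        sequence=sequence,
        motif=motif,
        rel_abundance=float(row["rel_abundance"]),
        rank=None if pd.isna(rank) else int(rank),
        edits=tuple(edits),
        warnings=warnings,
    )


def _enumerate_edits(query: DesignQuery, core: str) -> dict[str, tuple]:
    """All sequences reachable within the budgets, mapped to a minimal edit
    path. Complete enumeration; duplicates collapse to the fewest edits."""
    tss = _locate_tss(query.sequence, core)
    lo, hi = query.editable_window
    max_len = query.max_total_length or (len(query.sequence) + query.max_insertions)

    best: dict[str, tuple] = {query.sequence: ((), 0, 0)}  # seq -> (edits, ins, sub)
    frontier = dict(best)
    for _ in range(query.max_insertions + query.max_substitutions):
        new: dict[str, tuple] = {}
        for seq, (edits, ins, sub) in frontier.items():
            if sub < query.max_substitutions:
                for pos in range(lo, hi + 1):  # TSS coordinate of the base
                    i = tss + pos - 1
                    if i >= len(seq):
                        continue
                    for b in "ACGT":
                        if seq[i] == b:
                            continue
                        cand = seq[:i] + b + seq[i + 1 :]
                        _offer(new, best, cand, edits + (f"sub+{pos}{b}",), ins, sub + 1)
            if ins < query.max_insertions and len(seq) < max_len:
                for pos in range(lo, hi + 2):  # insert before +pos (or after +hi)
                    i = tss + pos - 1
                    for b in "ACGT":
                        cand = seq[:i] + b + seq[i:]
                        _offer(new, best, cand, edits + (f"ins+{pos}{b}",), ins + 1, sub)
        frontier = new
        if not frontier:
            break
    return best


def _offer(new, best, seq, edits, ins, sub):
    prev = best.get(seq)
    if prev is None or len(edits) < len(prev[0]):
        best[seq] = (edits, ins, sub)
        new[seq] = (edits, ins, sub)


def optimize_insert(
    query: DesignQuery, table: pd.DataFrame, core: str = T7_CORE
) -> list[DesignResult]:
    """Exhaustively search the edit budget for higher-ranking constructs.

    Candidates are scored on the table's motif span and sorted by rank,
    then by fewest edits, then lexicographically by sequence. Candidates
    whose motif is flagged or absent from the table are dropped.
    """
    reachable = _enumerate_edits(query, core)
    results: list[DesignResult] = []
    for seq, (edits, _ins, _sub) in reachable.items():
        try:
            res = score_promoter(seq, table, core=core, edits=edits)
        except (KeyError, ValueError):
            continue
        if res.rank is None:
            continue
        results.append(res)
    if not results:
        raise ValueError("no scorable candidate within the edit budget")
    results.sort(key=lambda r: (r.rank, r.n_edits, r.sequence))
    return results


# --------------------------------------------------------------------------
# Primer assembly
# --------------------------------------------------------------------------

@dataclass
class AnnotatedSequence:
    """A concatenated construct with TSS-coordinate annotations."""

    sequence: str
    annotations: tuple[tuple[str, int, int], ...]  # (name, start, end) inclusive
    at_fraction: float | None
    warnings: tuple[str, ...] = field(default=())


def assemble_primer(
    upstream_element: str,
    core: str,
    itr: str,
    tail: str = "",
    expected_core: str | None = T7_CORE,
) -> AnnotatedSequence:
    """Assemble upstream element + core promoter + ITR (+ tail).

    The upstream element sits immediately 5' of the −17..−1 core (e.g. at
    −21..−18 for a 4 nt element); an element with AT fraction < 0.75 draws
    a warning, since only AT-rich elements enhance polymerase recruitment.
    """
    for name, seq in (("upstream_element", upstream_element), ("core", core),
                      ("itr", itr), ("tail", tail)):
        if not set(seq) <= set("ACGT"):
            raise ValueError(f"{name} contains non-ACGT characters")
    if len(core) != 17:
        raise ValueError("core promoter must cover -17..-1 (17 nt)")
    if expected_core is not None and core != expected_core:
        raise ValueError("core does not match the configured consensus")

    warnings: list[str] = []
    at_fraction = None
    ann: list[tuple[str, int, int]] = []
    if upstream_element:
        at_fraction = sum(b in "AT" for b in upstream_element) / len(upstream_element)
        if at_fraction < 0.75:
            warnings.append(
                f"upstream element AT fraction {at_fraction:.2f} < 0.75; "
                "low-affinity element"
            )
        ann.append(("upstream_element", -17 - len(upstream_element), -18))
    ann.append(("core", -17, -1))
    if itr:
        ann.append(("itr", 1, len(itr)))
    if tail:
        ann.append(("tail", len(itr) + 1, len(itr) + len(tail)))
    return AnnotatedSequence(
        sequence=upstream_element + core + itr + tail,
        annotations=tuple(ann),
        at_fraction=at_fraction,
        warnings=tuple(warnings),
    )
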