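# racescreen

Promoter-activity screening for phage RNA polymerases by 5′RACE-Seq, as a
tested and reusable pipeline.

T7 (and SP6) RNA polymerase output does not depend only on the −17..−1 core
promoter: the *initially transcribed region* (ITR, the first ~8 transcribed
nucleotides) modulates yield as well. A randomized-promoter screen measures
this by transcribing a template library randomized from +2 to +16, reading
each transcript's exact 5′ end by 5′RACE-Seq, and normalizing motif counts
against direct sequencing of the untranscribed template. `racescreen`
implements that screen end to end *in silico*:

- **`synthetic_screen`** — a ground-truth generator for the library
  chemistry: biased template synthesis, motif-weighted transcription,
  polymerase G-sliding on G-triplet starts, non-templated C addition by
  reverse transcriptase, UMI tagging, poly(A) tailing, PCR duplication,
  sequencing errors, optional dark-cycle loss of G homopolymers.
- **`read_processing`** — the published filter cascade: contaminant k-mer
  removal, 15mer–UMI deduplication, the structural 5′-end rule (C at read
  position 16; AA/CA/CC at 17–18; poly(A) tail), reverse-complementation to
  RNA sense, and a one-mismatch constant-sequence cross-contamination
  filter on the +2..+11 10mer.
- **`motif_stats`** — background-normalized relative abundances
  rel(m) = (c(m)/N) / (c_bg(m)/N_bg), log₂ tables with deterministic ranks,
  position-wise composition, +2/+3 dinucleotide grouping, homopolymer
  flagging, extra-G fractions with Wilson intervals, activity fold ranges,
  replicate correlation, and oversampling arithmetic.
- **`promoter_design`** — score a promoter construct against a motif table
  and exhaustively search small insertion/substitution budgets inside an
  editable window for higher-ranking ITR variants; assemble annotated
  primers with an AT-rich −21..−18 upstream element.
- **`pipeline` / CLI** — one-command reproducible runs with manifests.

## Worked example

```python
import racescreen as rs

cfg = rs.default_config("T7")
model = rs.build_activity_model("t7_like", fold_range=5.0, seed=7)
reads, truth, lib = rs.simulate_screen(cfg, model, depth=2_000_000, seed=1)
filtered, stats = rs.process_run(reads, None, cfg)
print(stats)
```

```
FilterStats(input=2200064, contaminant_removed=0, dedup_removed=201389,
            structure_failed=5423, polyA_failed=70,
            constant_match_removed=8391, accepted=1984791)
```

The stage counts telescope: 2.2 M simulated read pairs (10% PCR
duplication) lose their duplicates, a few thousand structurally invalid or
constant-matching reads, and 1.98 M reads enter motif analysis. Ranking the
1024 +4..+8 motifs within the G-triplet (+1..+3 = GGG) context:

```python
fg = rs.count_motifs(filtered, span=(4, 8), context=((2, 3), "GG"))
bg = rs.count_motifs(reads.bg_codes, span=(4, 8), context=((2, 3), "GG"))
table = rs.homopolymer_filter(rs.normalize(fg, bg), plus1_base="GGG")
print(table.sort_values("rank").head(3)[["count", "bg_count", "rel_abundance", "rank"]])
print("fold:", rs.activity_range(table, 0.025, 0.975))
```

```
       count  bg_count  rel_abundance  rank
motif
ACGTT    491       110       2.517619     1
TCGTT    417       102       2.305882     2
ATATT    527       132       2.251842     3
fold: 5.046432774880541
```

The recovered 2.5%–97.5% activity fold (≈5) matches the generating model's
5-fold ITR effect. The extra-G report separates polymerase sliding from the
RT's non-templated C: G-triplet starts carry an extra 5′ C in ~82% of reads
(0.79 sliding once + 0.02 twice, compounded with the 5% RT baseline visible
in non-sliding classes such as GAT):

```python
print(rs.extra_g_fractions(filtered).loc[["GGG", "GAT"], ["n", "frac_ge1", "frac_eq2"]])
```

```
          n  frac_ge1  frac_eq2
cls
GGG  240431  0.819453  0.060604
GAT   87081  0.050321  0.000023
```

Finally, the design layer: scoring a construct whose +4..+8 motif ranks
poorly, then searching a two-insertion budget in the +3..+8 window, finds a
single-base insertion that lifts the ITR rank from 213 to 76 — the same
move (minimal insertion at the 5′ end of the ITR) used to optimize
IVT primers in practice:

```python
t = rs.load_motif_table("motif_table.tsv")          # motif, rel_abundance
seq = "AT" + rs.T7_CORE + "GGGTCCGC" + "AAAA"
print(rs.score_promoter(seq, t).rank)               # 213
best = rs.optimize_insert(
    rs.DesignQuery(sequence=seq, editable_window=(3, 8), max_insertions=2), t
)[0]
print(best.rank, best.edits)                        # 76 ('ins+7A',)
```

The same stages are available from the shell:

```bash
racescreen simulate --depth 100000 --seed 1 --out run/
racescreen process --r1 run/r1.fastq.gz --r2 run/r2.fastq.gz --config run/config.yaml --out run/
racescreen analyze --reads run/filtered_reads.tsv --bg run/background.fastq.gz --config run/config.yaml --out run/
racescreen run-all --depth 100000 --seed 1 --out run/   # all of the above
racescreen design optimize --seq ... --window 3:8 --max-ins 2 --table run/motif_table_+4_+8_byctx.tsv
```

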