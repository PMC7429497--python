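"""Parameter-recovery experiments run through the full pipeline.

Each experiment simulates a screen under stated generator conditions, pushes
the reads through the complete filter cascade and motif statistics, and
measures how well the pipeline recovers the generating parameters: the
+4..+8 fold range and motif ranking, the 5'-end event probabilities, the
null calibration of the background normalization, and replicate agreement.
These are the package's own quality gates; they are also what the
acceptance script reports.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from . import motif_stats as ms
from .config import ScreenConfig, default_config
from .read_processing import process_run
from .sequence import pack_str
from .synthetic_screen import build_activity_model, simulate_screen

GG_CONTEXT = ((2, 3), "GG")


def _child_seed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % 2**31)


def itr_recovery(
    seed: int,
    depth: int = 20_000_000,
    fold_range: float = 5.0,
    model_seed: int = 7,
    quantiles: tuple[float, float] = (0.025, 0.975),
) -> dict:
    """Recover the +4..+8 fold range and motif ranking in the G-triplet
    context from one T7-like screen.

    Returns the estimated activity fold between ``quantiles``, the Spearman
    correlation between estimated relative abundances and the generating
    weights (over unflagged motifs), and the read counts involved.
    """
    cfg = default_config("T7")
    model = build_activity_model("t7_like", fold_range=fold_range, seed=model_seed)
    reads, _, _ = simulate_screen(cfg, model, depth=depth, seed=seed)
    filtered, stats = process_run(reads, None, cfg)
    bg_codes = reads.bg_codes
    del reads

    fg = ms.count_motifs(filtered, span=(4, 8), context=GG_CONTEXT)
    bg = ms.count_motifs(bg_codes, span=(4, 8), context=GG_CONTEXT)
    table = ms.homopolymer_filter(
        ms.normalize(fg, bg, min_bg=cfg.min_bg),
        min_run=cfg.homopolymer_min_run, bases=cfg.homopolymer_bases,
        plus1_base=cfg.plus1_base + "GG",
    )
    ok = table[~(table["low_background"] | table["homopolymer"])]
    true_w = model.itr_factor[[pack_str(m) for m in ok.index]]
    spearman = float(sps.spearmanr(ok["rel_abundance"], true_w).statistic)
    out = {
        "fold_range": ms.activity_range(table, *quantiles),
        "spearman_vs_truth": spearman,
        "accepted_reads": stats.accepted,
        "context_reads": int(fg.sum()),
        "n_motifs": int(len(ok)),
    }
    # 5'-end event deconvolution: the baseline extra-C rate in classes where
    # sliding cannot occur estimates the RT C-addition probability; the
    # G-triplet excess then yields the slippage probabilities.
    eg = ms.extra_g_fractions(filtered, plus1_base=cfg.plus1_base)
    out.update(_deconvolve_extra_g(eg))
    return out


def _deconvolve_extra_g(eg) -> dict:
    """Estimate (p_slip1, p_slip2, p_rt_c) from the per-class extra-C table.

    With s = p1 + p2 the total sliding probability and r the RT rate,
    frac_ge1(GGG) = 1 - (1-s)(1-r) and frac_eq2(GGG) = p2 + p1*r
    (two slips always show the two-C pattern — a third extra C lands in
    the poly(A) window and still passes — and one slip plus the RT C
    shows it too).
    """
    non_slide = eg.drop(index="GGG")
    non_slide = non_slide[non_slide["n"] > 0]
    r = float(
        (non_slide["frac_ge1"] * non_slide["n"]).sum() / non_slide["n"].sum()
    )
    a = float(eg.loc["GGG", "frac_ge1"])
    b = float(eg.loc["GGG", "frac_eq2"])
    s = 1 - (1 - a) / (1 - r)  # total sliding probability p1 + p2
    p2 = (b - s * r) / (1 - r)  # b = p2 + (s - p2)*r
    p1 = s - p2
    return {
        "ggg_frac_ge1": a,
        "ggg_frac_eq2": b,
        "rt_c_rate": r,
        "slip1_prob": p1,
        "slip2_prob": p2,
    }


def extra_g_coverage(
    seed: int,
    n_replicates: int = 50,
    depth: int = 130_000,
    p1: float = 0.79,
    p2: float = 0.02,
    p_rt_c: float = 0.05,
) -> dict:
    """Wilson-interval coverage of the extra-G fractions over replicates.

    Each replicate simulates a GGG-restricted screen (degenerate +2/+3
    synthesis bias, sequencing errors off so the 5'-event estimate is a
    clean binomial) and checks whether the replicate's Wilson 95% interval
    covers the compound generating probability.
    """
    # compound probabilities actually visible in accepted reads
    s = p1 + p2
    true_ge1 = 1 - (1 - s) * (1 - p_rt_c)
    true_eq2 = p2 + p1 * p_rt_c

    bias = np.full((15, 4), 0.25)
    bias[0] = bias[1] = [0.0, 0.0, 1.0, 0.0]  # +2/+3 fixed at GG
    cfg = ScreenConfig(error_rate=0.0, base_bias=(0.25,) * 4)
    model = build_activity_model(
        "t7_like", 5.0, seed=11,
        p_extra_g1={"GGG": p1}, p_extra_g2={"GGG": p2}, p_rt_c=p_rt_c,
    )
    cover_ge1 = cover_eq2 = 0
    est_ge1 = []
    n_ggg = 0
    for rep in range(n_replicates):
        rep_seed = _child_seed(seed, rep)
        reads, _, _ = simulate_screen(
            cfg, model, depth=depth, bg_depth=1, base_bias=bias, seed=rep_seed
        )
        filtered, _ = process_run(reads, None, cfg)
        eg = ms.extra_g_fractions(filtered)
        row = eg.loc["GGG"]
        n_ggg = int(row["n"])
        est_ge1.append(row["frac_ge1"])
        cover_ge1 += row["ge1_lo"] <= true_ge1 <= row["ge1_hi"]
        cover_eq2 += row["eq2_lo"] <= true_eq2 <= row["eq2_hi"]
    return {
        "coverage_ge1": cover_ge1 / n_replicates,
        "coverage_eq2": cover_eq2 / n_replicates,
        "mean_frac_ge1": float(np.mean(est_ge1)),
        "true_frac_ge1": true_ge1,
        "true_frac_eq2": true_eq2,
        "n_ggg_reads": n_ggg,
        "n_replicates": n_replicates,
    }


def null_calibration(seed: int, depth: int = 12_000_000) -> dict:
    """Foreground and background drawn from one template distribution.

    Under the null (uniform activity), per-motif log2 relative abundances
    should scatter around zero within binomial error: the fraction of
    +2..+8 motifs beyond 3 standard errors (delta method in log2 space)
    should stay near the nominal 0.27%, and the 1%–99% activity fold near 1.
    """
    cfg = default_config("T7")
    model = build_activity_model("uniform", 1.0, seed=0)
    reads, _, _ = simulate_screen(cfg, model, depth=depth, seed=seed)
    filtered, _ = process_run(reads, None, cfg)
    fg = ms.count_motifs(filtered, span=(2, 8))
    bg = ms.count_motifs(reads.bg_codes, span=(2, 8))
    table = ms.normalize(fg, bg, min_bg=cfg.min_bg)
    ok = table[~table["low_background"]].dropna(subset=["log2_rel"])
    se = np.sqrt(1 / ok["count"] + 1 / ok["bg_count"]) / np.log(2)
    z = ok["log2_rel"] / se
    return {
        "outlier_fraction": float((z.abs() > 3).mean()),
        "activity_range": ms.activity_range(table, 0.01, 0.99),
        "n_motifs": int(len(ok)),
    }


def replicate_agreement(
    seed: int, depth: int = 10_000_000, model_seed: int = 7
) -> dict:
    """Two independent screens of one T7-like model; correlation of their
    background-normalized +2..+8 log2 relative abundances."""
    cfg = default_config("T7")
    model = build_activity_model("t7_like", 5.0, seed=model_seed)
    tables = []
    for rep in (1, 2):
        rep_seed = _child_seed(seed, 100 + rep)
        reads, _, _ = simulate_screen(cfg, model, depth=depth, seed=rep_seed)
        filtered, _ = process_run(reads, None, cfg)
        fg = ms.count_motifs(filtered, span=(2, 8))
        bg = ms.count_motifs(reads.bg_codes, span=(2, 8))
        del reads
        tables.append(
            ms.homopolymer_filter(
                ms.normalize(fg, bg, min_bg=cfg.min_bg),
                min_run=cfg.homopolymer_min_run, bases=cfg.homopolymer_bases,
                plus1_base=cfg.plus1_base,
            )
        )
    return ms.replicate_correlation(tables[0], tables[1])
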