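"""End-to-end orchestration: simulate → process → analyze, with a manifest.

Every run writes deterministic outputs (gzip members carry mtime=0) so that
re-running with one seed reproduces byte-identical files; the manifest
records the config hash, seeds and a SHA-256 checksum per output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import motif_stats as ms
from .config import ScreenConfig, default_config
from .read_processing import FilteredReads, FilterStats, process_run
from .synthetic_screen import (
    ActivityModel, build_activity_model, simulate_screen,
)

FIXTURE_SCALES = {"tiny": (1_000, 7), "demo": (1_000_000, 11)}


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: list = field(default_factory=list)
    checksums: dict = field(default_factory=dict)

    def add_files(self, files: dict) -> None:
        for name, path in files.items():
            self.checksums[name] = _sha256(path)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "stages": self.stages,
                    "checksums": self.checksums,
                },
                fh, indent=2,
            )


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path, header_comment: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t")


# --------------------------------------------------------------------------
# Analysis stage
# --------------------------------------------------------------------------

def analyze(
    reads: FilteredReads,
    bg_codes: np.ndarray,
    config: ScreenConfig,
) -> dict:
    """Compute all motif-level outputs for one processed run.

    Returns a dict with the +2..+8 motif table, per-context +4..+8 tables,
    the composition matrix, dinucleotide group summaries, the extra-G
    report and a scalar summary (oversampling, activity ranges).
    """
    hp = dict(
        min_run=config.homopolymer_min_run,
        bases=config.homopolymer_bases,
    )
    fg = ms.count_motifs(reads, span=(2, 8))
    bg = ms.count_motifs(bg_codes, span=(2, 8))
    table28 = ms.homopolymer_filter(
        ms.normalize(fg, bg, min_bg=config.min_bg),
        plus1_base=config.plus1_base, **hp,
    )

    # +4..+8 tables within each +2/+3 context (the G-triplet context is the
    # one the screen's design work uses)
    by_ctx = {}
    for i in range(16):
        dinuc = ms.unpack_str(i, 2)
        ctx = ((2, 3), dinuc)
        fg_c = ms.count_motifs(reads, span=(4, 8), context=ctx)
        bg_c = ms.count_motifs(bg_codes, span=(4, 8), context=ctx)
        if fg_c.sum() == 0 or bg_c.sum() == 0:
            continue
        tbl = ms.homopolymer_filter(
            ms.normalize(fg_c, bg_c, min_bg=config.min_bg),
            plus1_base=config.plus1_base + dinuc, **hp,
        )
        by_ctx[config.plus1_base + dinuc] = tbl

    comp = ms.composition(reads.motif_codes, bg_codes)
    groups = ms.group_by_dinucleotide(table28)
    extra_g = ms.extra_g_fractions(reads, plus1_base=config.plus1_base)

    summary = {
        "accepted_reads": len(reads),
        "background_reads": int(np.asarray(bg_codes).shape[0]),
        "oversampling_2_8": ms.oversampling(len(reads), (2, 8)),
    }
    try:  # needs enough background-covered motifs; shallow runs skip it
        summary["activity_range_2_8"] = ms.activity_range(table28)
    except ValueError:
        pass
    ggg = config.plus1_base + "GG"
    if ggg in by_ctx:
        try:
            summary["activity_range_4_8_GGG"] = ms.activity_range(by_ctx[ggg])
        except ValueError:
            pass
    return {
        "table_2_8": table28,
        "tables_by_context": by_ctx,
        "composition": comp,
        "groups": groups,
        "extra_g": extra_g,
        "summary": summary,
    }


def write_analysis(results: dict, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    def tsv(name, df, comment):
        path = out / name
        _write_tsv(df, path, comment)
        files[name] = path

    tsv("motif_table_+2_+8.tsv", results["table_2_8"],
        "motif span +2..+8 (RNA-sense); rel_abundance is background-normalized")
    if results["tables_by_context"]:
        ctx_frames = []
        for cls, tbl in results["tables_by_context"].items():
            t = tbl.copy()
            t.insert(0, "context", cls)
            ctx_frames.append(t)
        tsv("motif_table_+4_+8_byctx.tsv", pd.concat(ctx_frames),
            "motif span +4..+8, ranked within each +1..+3 context")
    tsv("composition.tsv", results["composition"],
        "background-normalized base composition, positions +2..+16")
    tsv("groups_dinuc.tsv", results["groups"],
        "rel_abundance summaries per +2/+3 dinucleotide (type-7 quantiles)")
    tsv("extra_g.tsv", results["extra_g"],
        "extra 5' C fractions per +1..+3 class (Wilson 95% intervals)")
    with open(out / "summary.json", "w") as fh:
        json.dump(results["summary"], fh, indent=2)
    files["summary.json"] = out / "summary.json"
    return files


# --------------------------------------------------------------------------
# run_all
# --------------------------------------------------------------------------

def run_all(
    config: ScreenConfig,
    seed: int,
    out_dir,
    depth: int = 100_000,
    model: ActivityModel | None = None,
    fold_range: float = 5.0,
    via_fastq: bool = True,
) -> RunManifest:
    """Simulate, process and analyze one screen into ``out_dir``.

    ``via_fastq=True`` routes the processing stage through the written
    FASTQ files (the full file contract); ``False`` keeps reads in memory,
    which is what large recovery runs use.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_yaml = out / "config.yaml"
    config.to_yaml(cfg_yaml)
    manifest = RunManifest(config_hash=_sha256(cfg_yaml), seed=seed)

    if model is None:
        mode = "t7_like" if config.polymerase_mode == "T7" else "sp6_like"
        model = build_activity_model(mode, fold_range=fold_range, seed=seed)

    stage = "simulate"
    try:
        reads, truth, library = simulate_screen(config, model, depth=depth, seed=seed)
        fastq_paths = reads.write_fastq(out)
        gt_path = out / "ground_truth.tsv"
        _write_tsv(truth.to_dataframe().set_index("motif15"), gt_path,
                   "ground truth: per-15mer weight, transcript and extra-G counts")
        manifest.stages.append(stage)
        manifest.add_files({"config.yaml": cfg_yaml, "ground_truth.tsv": gt_path,
                            **{k + ".fastq.gz": v for k, v in fastq_paths.items()}})

        stage = "process"
        if via_fastq:
            filtered, stats = process_run(
                fastq_paths["r1"], fastq_paths["r2"], config
            )
            from .read_processing import load_fastq_matrix
            from .sequence import pack
            bg_mat = load_fastq_matrix(fastq_paths["background"], config.read1_len)
            bg15 = bg_mat[:, :15]
            ok = ~(bg15 >= 4).any(axis=1)
            bg_codes = pack(bg15[ok])
        else:
            filtered, stats = process_run(reads, None, config)
            bg_codes = reads.bg_codes
        fr_path = out / "filtered_reads.tsv"
        filtered.save_tsv(fr_path)
        stats.to_json(out / "filter_stats.json")
        manifest.stages.append(stage)
        manifest.add_files({"filtered_reads.tsv": fr_path,
                            "filter_stats.json": out / "filter_stats.json"})

        stage = "analyze"
        results = analyze(filtered, bg_codes, config)
        files = write_analysis(results, out)
        manifest.stages.append(stage)
        manifest.add_files(files)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.to_json(out / "manifest.json")
    return manifest


def make_fixture(scale: str, out_dir, mode: str = "T7") -> RunManifest:
    """Package a fixed-seed synthetic dataset (tiny: 10^3 reads for unit
    tests; demo: 10^6 reads for full-scale runs)."""
    if scale not in FIXTURE_SCALES:
        raise ValueError(f"unknown fixture scale {scale!r}; use tiny or demo")
    depth, seed = FIXTURE_SCALES[scale]
    return run_all(default_config(mode), seed=seed, out_dir=out_dir, depth=depth,
                   via_fastq=(scale == "tiny"))
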