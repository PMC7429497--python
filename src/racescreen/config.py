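"""Run configuration for the 5'RACE-Seq screen.

One :class:`ScreenConfig` carries every constant the pipeline depends on:
read geometry, the fixed +1 base, the core promoter, the constant sequences
used by the cross-contamination filter, and all filter parameters. Promoter
positions use TSS coordinates (+1 is the first transcribed base; there is
no position 0); read positions are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

# -17..-1 core promoter consensus recognised by each polymerase. The T7
# consensus is canonical; both are user-overridable.
T7_CORE = "TAATACGACTCACTATA"
SP6_CORE = "ATTTAGGTGACACTATA"

# Synthetic stand-ins for the library's constant sequences (template backbone
# downstream of +16, sequencing adapters, RT primer). Arbitrary fixed ACGT
# strings: the pipeline only needs *some* known constants to filter against.
DEFAULT_CONSTANTS: dict[str, str] = {
    "template_backbone": "CTTCGGAGAACTGTCCATCGTGGACAATCCTCAGGCATCG",
    "p5_adapter": "AATGATACGGCGACCACCGAGATCTACAC",
    "rt_primer": "GTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT",
}

# Mild per-position synthesis bias of the randomized template (A, C, G, T).
DEFAULT_BASE_BIAS = (0.28, 0.22, 0.26, 0.24)


@dataclass
class ScreenConfig:
    """Parameters of one screen run (simulation + processing + analysis)."""

    polymerase_mode: str = "T7"  # "T7" or "SP6"
    randomized_span: tuple[int, int] = (2, 16)  # TSS coordinates, inclusive
    plus1_base: str = "G"
    read1_len: int = 35
    read2_len: int = 35
    umi_len: int = 5
    upstream_core: str = T7_CORE
    constant_seqs: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CONSTANTS)
    )

    # generator
    base_bias: tuple[float, float, float, float] = DEFAULT_BASE_BIAS
    error_rate: float = 0.001
    dup_rate: float = 0.1
    dark_cycle_g_run: int | None = None  # drop reads with a G-run >= this ...
    dark_cycle_loss: float = 0.0  # ... with this probability

    # read filters
    contaminant_k: int = 21
    contaminant_min_hits: int = 1
    polya_window: int = 10
    polya_min_frac: float = 0.9
    constant_max_mismatch: int = 1
    dedup_after_structure: bool = False

    # motif statistics
    min_bg: int = 10
    homopolymer_min_run: int = 4
    homopolymer_bases: str = "ACGT"

    def __post_init__(self) -> None:
        lo, hi = self.randomized_span
        if hi - lo + 1 != 15:
            raise ValueError("randomized_span must cover 15 positions")
        if lo <= 1:
            raise ValueError("randomized span must start downstream of +1")
        if self.polymerase_mode not in ("T7", "SP6"):
            raise ValueError(f"unknown polymerase_mode {self.polymerase_mode!r}")
        if self.plus1_base not in "ACGT":
            raise ValueError("plus1_base must be one of ACGT")
        if self.umi_len < 1:
            raise ValueError("umi_len must be >= 1")
        # Read1 must hold the antisense 15mer, the +1 complement, the 17/18
        # dinucleotide and the poly(A) window.
        min_r1 = 15 + 1 + 2 + self.polya_window
        if self.read1_len < min_r1:
            raise ValueError(f"read1_len must be >= {min_r1}")
        if self.read2_len < self.umi_len:
            raise ValueError("read2_len must be >= umi_len")
        for name, seq in self.constant_seqs.items():
            if not set(seq) <= set("ACGT"):
                raise ValueError(f"constant sequence {name!r} not over ACGT")
        if not set(self.upstream_core) <= set("ACGT"):
            raise ValueError("upstream_core not over ACGT")
        if abs(sum(self.base_bias) - 1.0) > 1e-6:
            raise ValueError("base_bias must sum to 1")
        if self.homopolymer_min_run < 2:
            raise ValueError("homopolymer_min_run must be >= 2")

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        d = asdict(self)
        d["randomized_span"] = list(self.randomized_span)
        d["base_bias"] = list(self.base_bias)
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "ScreenConfig":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        if "randomized_span" in d:
            d["randomized_span"] = tuple(d["randomized_span"])
        if "base_bias" in d:
            d["base_bias"] = tuple(d["base_bias"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(mode: str = "T7") -> ScreenConfig:
    """Config preset for a polymerase mode (sets the matching core promoter)."""
    core = {"T7": T7_CORE, "SP6": SP6_CORE}.get(mode)
    if core is None:
        raise ValueError(f"unknown polymerase mode {mode!r}")
    return ScreenConfig(polymerase_mode=mode, upstream_core=core)
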