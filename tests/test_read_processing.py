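"""Filter-cascade tests, each checked against an independent brute-force rule."""

import collections
import gzip
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import racescreen as rs
from racescreen.read_processing import (
    ContaminantIndex, build_constant_lut, load_fastq_matrix,
)
from racescreen.sequence import pack_str, revcomp_str, unpack_str


# ------------------------------------------------------- structural filter

def brute_structural(seq: str, window: int = 10, min_frac: float = 0.9):
    """Literal re-statement of the 5'-end rule, evaluated on strings."""
    if len(seq) < 18 + window:
        raise ValueError("too short")
    if seq[15] != "C":
        return False, 0
    pair = seq[16:18]
    if pair not in ("AA", "CA", "CC"):
        return False, 0
    extra = {"AA": 0, "CA": 1, "CC": 2}[pair]
    tail = seq[16 + extra : 16 + extra + window]
    if sum(b == "A" for b in tail) >= min_frac * window:
        return True, extra
    return False, 0


class TestStructuralFilter:
    PREFIX = "ACGTACGTACGTACG"  # read positions 1-15
    SUFFIX = "A" * 14  # positions 22-35

    def test_exhaustive_positions_16_to_21_match_brute_force(self):
        for combo in itertools.product("ACGT", repeat=6):
            seq = self.PREFIX + "".join(combo) + self.SUFFIX
            assert rs.structural_filter(seq) == brute_structural(seq), seq

    @pytest.mark.parametrize(
        "mid,tail,expected",
        [
            ("CAA", "AAAAAAAAAA", (True, 0)),  # canonical pass
            ("CCC", "AAAAAAAAAA", (True, 2)),  # C16 + "CC" at 17-18
            ("CAC", "AAAAAAAAAA", (False, 0)),  # "AC" not whitelisted
            ("GAA", "AAAAAAAAAA", (False, 0)),  # no C at 16
            ("CCA", "AAAAAAAATA", (True, 1)),  # 9/10 A passes at 0.9
            ("CCA", "AAAAAAATTA", (False, 0)),  # 8/10 A fails
        ],
    )
    def test_documented_cases(self, mid, tail, expected):
        seq = (self.PREFIX + mid + tail + "A" * 35)[:35]
        assert rs.structural_filter(seq) == expected

    def test_short_read_rejected_with_error(self):
        with pytest.raises(ValueError):
            rs.structural_filter("ACGT" * 5)

    @given(st.text(alphabet="ACGT", min_size=35, max_size=35))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force_on_random_reads(self, seq):
        assert rs.structural_filter(seq) == brute_structural(seq)


# ------------------------------------------------------------- orientation

class TestToSense:
    def test_hand_reverse_complement(self):
        assert rs.to_sense("ACGTACGTACGTACG" + "A" * 20) == "CGTACGTACGTACGT"

    @given(st.text(alphabet="ACGT", min_size=15, max_size=35))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_involution(self, seq):
        once = rs.to_sense(seq)
        assert rs.to_sense(once + "A" * 20) == seq[:15]

    def test_n_in_15mer_rejected(self):
        assert rs.to_sense("ACGTNCGTACGTACG" + "A" * 20) is None


# --------------------------------------------------------- constant filter

def brute_constant(tenmer: str, constants, max_mm: int = 1) -> bool:
    for seq in constants:
        for s in (seq, revcomp_str(seq)):
            for i in range(len(s) - 9):
                if sum(a != b for a, b in zip(s[i : i + 10], tenmer)) <= max_mm:
                    return False  # discard
    return True


class TestConstantFilter:
    CONSTANTS = ["ACGTACGTACGTACGTACGT", "TTTTGGGGCCCCAAAATTTT"]

    def test_exact_window_discarded(self):
        assert rs.constant_seq_filter("ACGTACGTAC" + "AAAAA", self.CONSTANTS) is False

    def test_one_mismatch_discarded(self):
        assert rs.constant_seq_filter("ACGTACGTAG" + "AAAAA", self.CONSTANTS) is False

    def test_distance_two_kept(self):
        tenmer = "TTTTTTTTTT"
        assert brute_constant(tenmer, self.CONSTANTS) is True
        assert rs.constant_seq_filter(tenmer + "AAAAA", self.CONSTANTS) is True

    def test_random_10mers_match_brute_force(self):
        rng = np.random.default_rng(0)
        lut = build_constant_lut(self.CONSTANTS, max_mismatch=1)
        for _ in range(500):
            code = int(rng.integers(0, 4**10))
            tenmer = unpack_str(code, 10)
            assert (not lut[code]) == brute_constant(tenmer, self.CONSTANTS)

    def test_empty_constants_error(self):
        with pytest.raises(ValueError):
            rs.constant_seq_filter("A" * 15, [])


# ------------------------------------------------------- contaminant filter

class TestContaminantFilter:
    def test_exact_substring_discarded(self):
        rng = np.random.default_rng(1)
        contaminant = "".join(rng.choice(list("ACGT"), size=5000))
        idx = ContaminantIndex([contaminant], k=21)
        assert rs.contaminant_filter(contaminant[100:135], idx) is False

    def test_random_read_kept(self):
        rng = np.random.default_rng(2)
        contaminant = "".join(rng.choice(list("ACGT"), size=5000))
        idx = ContaminantIndex([contaminant], k=21)
        read = "".join(rng.choice(list("ACGT"), size=35))
        assert rs.contaminant_filter(read, idx) is True

    def test_disabled_is_identity(self):
        assert rs.contaminant_filter("ACGT" * 9, None) is True

    def test_empty_index_with_filtering_is_error(self):
        idx = ContaminantIndex([], k=21)
        with pytest.raises(ValueError):
            rs.contaminant_filter("ACGT" * 9, idx)

    def test_small_k_rejected(self):
        with pytest.raises(ValueError):
            ContaminantIndex(["ACGTACGTACGT"], k=8)


# ------------------------------------------------------------------- dedup

class TestDedup:
    def test_identical_key_collapses(self):
        pairs = [("A" * 35, "ACGTA"), ("A" * 35, "ACGTA")]
        assert len(rs.dedup(pairs)) == 1

    def test_distinct_umis_survive(self):
        pairs = [("A" * 35, "ACGTA"), ("A" * 35, "ACGTT")]
        assert len(rs.dedup(pairs)) == 2

    def test_all_distinct_is_identity(self):
        pairs = [(b * 35, "AAAAA") for b in "ACGT"]
        assert rs.dedup(pairs) == pairs


# ------------------------------------------------------------- process_run

class TestProcessRun:
    def _error_free_run(self, dup_rate=0.3, depth=20_000, seed=13):
        cfg = rs.ScreenConfig(error_rate=0.0, dup_rate=dup_rate)
        model = rs.build_activity_model("t7_like", 5.0, seed=7)
        reads, truth, _ = rs.simulate_screen(cfg, model, depth=depth, seed=seed)
        return cfg, reads, truth

    def test_error_free_recovery_matches_ground_truth(self):
        cfg, reads, truth = self._error_free_run()
        filtered, stats = rs.process_run(reads, None, cfg)
        assert stats.telescopes()

        # expected: one record per unique (15mer, UMI) molecule whose
        # +2..+11 10mer clears the constant filter; extra_c = min(events, 2)
        lut = build_constant_lut(cfg.constant_seqs, cfg.constant_max_mismatch)
        extras = np.minimum(
            truth.n_extra_g.astype(int) + truth.rt_c.astype(int), 2
        )
        mol_codes = truth.transcript_codes[reads.transcript_index]
        keys = mol_codes << 10 | reads.umi
        _, first = np.unique(keys, return_index=True)
        sel = np.sort(first)
        keep = ~lut[mol_codes[sel] >> 10]
        expected = collections.Counter(
            zip(mol_codes[sel][keep].tolist(),
                extras[reads.transcript_index[sel][keep]].tolist())
        )
        observed = collections.Counter(
            zip(filtered.motif_codes.tolist(), filtered.extra_c.tolist())
        )
        assert observed == expected

    def test_stats_telescope_and_count_duplicates(self):
        cfg, reads, truth = self._error_free_run(dup_rate=0.5)
        _, stats = rs.process_run(reads, None, cfg)
        assert stats.telescopes()
        assert stats.input == len(reads)
        # duplicates are exact copies, so dedup removes at least all of them
        assert stats.dedup_removed >= int(reads.is_duplicate.sum()) * 0.99

    def test_reprocessing_survivors_changes_nothing(self):
        cfg, reads, _ = self._error_free_run()
        filtered, _ = rs.process_run(reads, None, cfg)
        # rebuild a read set from the survivors and run the cascade again
        from racescreen.synthetic_screen import ReadSet
        from racescreen.sequence import revcomp_matrix, unpack
        r1 = np.full((len(filtered), cfg.read1_len), 0, dtype=np.uint8)
        r1[:, :15] = revcomp_matrix(unpack(filtered.motif_codes, 15))
        r1[:, 15] = 1  # C
        for k in (1, 2):
            r1[filtered.extra_c >= k, 15 + k] = 1
        again = ReadSet(
            read1=r1, umi=filtered.umi_codes,
            transcript_index=np.arange(len(filtered)),
            is_duplicate=np.zeros(len(filtered), dtype=bool),
            bg_codes=np.empty(0, dtype=np.int64), config=cfg,
        )
        refiltered, stats = rs.process_run(again, None, cfg)
        assert stats.dedup_removed == 0
        assert np.array_equal(
            np.sort(refiltered.motif_codes), np.sort(filtered.motif_codes)
        )
        assert len(refiltered) == len(filtered)

    def test_fastq_round_trip_equals_in_memory(self, tmp_path):
        cfg, reads, _ = self._error_free_run(depth=2_000)
        mem_filtered, mem_stats = rs.process_run(reads, None, cfg)
        paths = reads.write_fastq(tmp_path)
        f_filtered, f_stats = rs.process_run(paths["r1"], paths["r2"], cfg)
        assert f_stats == mem_stats
        assert np.array_equal(f_filtered.motif_codes, mem_filtered.motif_codes)
        assert np.array_equal(f_filtered.umi_codes, mem_filtered.umi_codes)

    def test_empty_input(self, cfg_t7, tmp_path):
        for name in ("e1.fastq", "e2.fastq"):
            (tmp_path / name).write_text("")
        filtered, stats = rs.process_run(
            tmp_path / "e1.fastq", tmp_path / "e2.fastq", cfg_t7
        )
        assert len(filtered) == 0 and stats.input == 0 and stats.telescopes()

    def test_malformed_record_names_index(self, cfg_t7, tmp_path):
        good = "@r0\n" + "A" * 35 + "\n+\n" + "I" * 35 + "\n"
        bad = "@r1\n" + "A" * 35 + "\nOOPS\n" + "I" * 35 + "\n"
        (tmp_path / "r1.fastq").write_text(good + bad)
        (tmp_path / "r2.fastq").write_text(good + good)
        with pytest.raises(ValueError, match="record 1"):
            rs.process_run(tmp_path / "r1.fastq", tmp_path / "r2.fastq", cfg_t7)

    def test_mismatched_pair_counts_rejected(self, cfg_t7, tmp_path):
        rec = "@r\n" + "A" * 35 + "\n+\n" + "I" * 35 + "\n"
        (tmp_path / "r1.fastq").write_text(rec * 2)
        (tmp_path / "r2.fastq").write_text(rec)
        with pytest.raises(ValueError, match="record counts differ"):
            rs.process_run(tmp_path / "r1.fastq", tmp_path / "r2.fastq", cfg_t7)

    def test_contaminated_reads_removed_first(self):
        cfg, reads, _ = self._error_free_run(depth=2_000)
        from racescreen.sequence import decode
        contaminant = decode(reads.read1[0])
        idx = ContaminantIndex([contaminant], k=21)
        _, stats = rs.process_run(reads, None, cfg, contaminant_index=idx)
        assert stats.contaminant_removed >= 1
        assert stats.telescopes()
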