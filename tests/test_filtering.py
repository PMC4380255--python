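"""Demultiplexing, the fixed criterion order, flowgram trimming, reports."""

import random

import pytest

import ampliflow as af
from ampliflow.filtering import (
    FilterConfig,
    FilterOutcome,
    FilterReport,
    SampleSpec,
    apply_filters,
    iupac_mismatches,
    match_mid_primer,
    read_sample_sheet,
    reverse_complement,
    run_filter,
    trim_flowgram,
)
from ampliflow.seqcall import CallPolicy, call_units
from ampliflow.sffio import FlowOrder, ReadRecord
from ampliflow.synthgen import SimConfig, ideal_flowgram, write_run

S = SampleSpec("S1", "TCAC", "ACGRT")


class TestMidPrimerMatch:
    def test_exact_prefix_matches_with_zero_allowance(self):
        read = "TCAC" + "ACGAT" + "TTTT"
        hit = match_mid_primer(read, [S], 0, 0)
        assert hit is not None
        sample, offset = hit
        assert sample.sample_id == "S1"
        assert offset == len("TCACACGAT")

    def test_mid_mismatch_needs_allowance(self):
        read = "TGAC" + "ACGAT" + "TTTT"  # one substitution in the mid
        assert match_mid_primer(read, [S], 0, 2) is None
        assert match_mid_primer(read, [S], 1, 2) is not None

    def test_iupac_degeneracy_costs_nothing(self):
        # primer position R matches A (and G) for free
        for base in "AG":
            read = "TCAC" + f"ACG{base}T" + "TT"
            assert match_mid_primer(read, [S], 0, 0) is not None
        read = "TCAC" + "ACGCT" + "TT"  # C is not in R
        assert match_mid_primer(read, [S], 0, 0) is None

    def test_first_matching_sample_wins(self):
        s2 = SampleSpec("S2", "TCAC", "ACGRA")
        read = "TCACACGAT"
        sample, _ = match_mid_primer(read, [S, s2], 1, 2)
        assert sample.sample_id == "S1"

    def test_iupac_mismatch_counting(self):
        assert iupac_mismatches("NRA", "GAC") == 1  # N free, R~A free, A vs C costs

    def test_reverse_complement_handles_degeneracies(self):
        assert reverse_complement("ACGR") == "YCGT"


class TestCriterionOrder:
    CFG = FilterConfig(
        min_seq_length=200, max_seq_length=600, max_ambiguous=0,
        remove_rev_primer=False, window_len=50, window_min_qual=25.0,
    )

    def test_clean_read_passes_untouched(self):
        bases = "ACGT" * 63  # 252 bases
        out = apply_filters(bases, [30] * len(bases), S, self.CFG)
        assert out.passed and out.kept_len == len(bases) and not out.truncated_by

    def test_short_read_eliminated_first(self):
        out = apply_filters("ACGT" * 10, [30] * 40, S, self.CFG)
        assert not out.passed and out.eliminated_by == "min_seq_length"

    def test_long_read_eliminated(self):
        bases = "A" * 601
        out = apply_filters(bases, [30] * 601, S, self.CFG)
        assert not out.passed and out.eliminated_by == "max_seq_length"

    def test_ambiguous_truncation_then_minlength_elimination(self):
        """A 300-base read with an N at base 120 (maxN=0) truncates to 119
        bases, which re-fails the 200 minimum; the elimination is attributed
        to the truncating criterion."""
        bases = "A" * 119 + "N" + "C" * 180
        out = apply_filters(bases, [30] * 300, S, self.CFG)
        assert not out.passed
        assert out.truncated_by == ["max_ambiguous"]
        assert out.eliminated_by == "max_ambiguous"

    def test_ambiguous_allowance_shifts_cut_point(self):
        cfg = FilterConfig(max_ambiguous=1)
        bases = "AANAA" + "N" + "CCC"
        out = apply_filters(bases, [30] * len(bases), S, cfg)
        assert out.passed and out.kept_len == 5  # cut before the 2nd N

    def test_reverse_primer_truncates_before_site(self):
        sample = SampleSpec("S1", "TCAC", "ACGRT", rev_primer="AAGGT")
        cfg = FilterConfig(primer_mismatches=0, remove_rev_primer=True)
        site = reverse_complement("AAGGT")  # ACCTT
        bases = "G" * 40 + site + "T" * 10
        out = apply_filters(bases, [30] * len(bases), sample, cfg)
        assert out.passed and out.kept_len == 40
        assert out.truncated_by == ["reverse_primer"]

    def test_window_truncates_at_quality_drop(self):
        """400 bases, quality 30 until base 300 then 10: the first failing
        50-window and hence the cut point match a brute-force scan."""
        quals = [30] * 300 + [10] * 100
        bases = "A" * 400
        cfg = FilterConfig(window_len=50, window_min_qual=25.0)
        out = apply_filters(bases, quals, S, cfg)
        cut = _window_oracle(quals, 50, 25.0)
        assert out.truncated_by == ["window_quality"]
        assert out.kept_len == cut

    def test_window_oracle_on_random_qualities(self):
        rng = random.Random(42)
        cfg = FilterConfig(window_len=10, window_min_qual=20.0)
        for _ in range(50):
            n = rng.randint(5, 120)
            quals = [rng.randint(0, 40) for _ in range(n)]
            out = apply_filters("A" * n, quals, S, cfg)
            cut = _window_oracle(quals, 10, 20.0)
            expected = n if cut is None else cut
            assert out.kept_len == expected

    def test_truncations_compose_in_order(self):
        # N truncation first shortens the read; window applies to the remainder
        cfg = FilterConfig(max_ambiguous=0, window_len=10, window_min_qual=20.0)
        bases = "A" * 50 + "N" + "A" * 50
        quals = [30] * 30 + [5] * 71
        out = apply_filters(bases, quals, S, cfg)
        assert out.truncated_by == ["max_ambiguous", "window_quality"]
        assert out.kept_len == _window_oracle(quals[:50], 10, 20.0)


def _window_oracle(quals, w, minq):
    """Exhaustive all-windows scan; cut before the first failing window."""
    for s in range(0, len(quals) - w + 1):
        if sum(quals[s:s + w]) / w < minq:
            return s
    return None


def _record_from_sequence(seq, flow_chars="TACG"):
    flows = [float(v) for v in ideal_flowgram(seq, flow_chars)]
    policy = CallPolicy(FlowOrder(flow_chars, len(flows) + 4))
    units = list(call_units(flows, policy))
    return ReadRecord(
        id="r",
        flow_values=flows,
        flow_index=[f for _, f in units],
        bases="".join(b for b, _ in units),
        quals=[30] * len(units),
    )


class TestTrimFlowgram:
    SEQ = "TCACACGATTTACCGGA"

    def test_keep_all_spans_first_to_last_base_flow(self):
        rec = _record_from_sequence(self.SEQ)
        flows, start = trim_flowgram(rec, (0, len(rec.bases)))
        assert start == rec.flow_index[0]
        assert flows == rec.flow_values[rec.flow_index[0]: rec.flow_index[-1] + 1]

    def test_trim_starts_at_first_kept_bases_flow(self):
        rec = _record_from_sequence(self.SEQ)
        start_base = 9  # past mid+primer in this constructed read
        flows, start = trim_flowgram(rec, (start_base, len(rec.bases)))
        assert start == rec.flow_index[start_base]
        assert flows[0] == rec.flow_values[start]
        # interior zero flows are preserved verbatim
        assert flows == rec.flow_values[start: rec.flow_index[-1] + 1]

    def test_right_truncation_drops_trailing_flows(self):
        rec = _record_from_sequence(self.SEQ)
        full, _ = trim_flowgram(rec, (0, len(rec.bases)))
        cut, _ = trim_flowgram(rec, (0, len(rec.bases) - 3))
        dropped = rec.flow_index[-1] - rec.flow_index[len(rec.bases) - 4]
        assert len(full) - len(cut) == dropped

    def test_empty_interval_is_an_error(self):
        rec = _record_from_sequence(self.SEQ)
        with pytest.raises(ValueError):
            trim_flowgram(rec, (5, 5))


class TestRunFilter:
    def _noise_free_cfg(self, **kw):
        cfg = SimConfig(seed=5, ref_length=240, **kw)
        cfg.sd_table = {k: 1e-6 for k in cfg.sd_table}
        return cfg

    def test_noise_free_run_all_pass_single_bin(self, tmp_path):
        # two samples sharing one primer; references share a first base so
        # every read starts its retained flowgram in the same cycle phase
        rng = random.Random(0)
        refs = ["A" + "".join(rng.choice("ACGT") for _ in range(239)) for _ in range(2)]
        cfg = self._noise_free_cfg(references=refs, reads_per_ref=50)
        run = write_run(cfg, tmp_path)
        fr = run_filter(run.sff_path, af.read_sample_sheet(run.sample_sheet_path),
                        FilterConfig.standard(), tmp_path / "out")
        assert fr.report.total_matched == 100
        assert fr.report.total_passed == 100
        assert len(fr.bin_paths) == 1

    def test_uniformly_short_reads_all_eliminated(self, tmp_path):
        cfg = self._noise_free_cfg(n_references=2, reads_per_ref=50)
        cfg.ref_length = 150
        cfg.references = None
        run = write_run(cfg, tmp_path)
        fr = run_filter(run.sff_path, af.read_sample_sheet(run.sample_sheet_path),
                        FilterConfig.standard(), tmp_path / "out")
        assert fr.report.total_matched == 100
        assert fr.report.total_passed == 0
        assert fr.report.eliminated == {"min_seq_length": 100}

    def test_conservation_per_sample_and_total(self, tmp_path):
        run = write_run(SimConfig(seed=9, n_references=3, ref_length=230,
                                  reads_per_ref=15), tmp_path)
        fr = run_filter(run.sff_path, af.read_sample_sheet(run.sample_sheet_path),
                        FilterConfig.standard(), tmp_path / "out")
        rep = fr.report
        assert rep.total_matched == rep.total_passed + rep.total_eliminated
        # every passed read appears in exactly one bin
        n_binned = 0
        for path in fr.bin_paths.values():
            _, entries = af.read_flowgrams(path)
            n_binned += len(entries)
        assert n_binned == rep.total_passed
        assert len(af.read_fasta(fr.fasta_path)) == rep.total_passed

    def test_empty_sample_sheet_fatal(self, tmp_path):
        run = write_run(SimConfig(seed=5, n_references=1, ref_length=100,
                                  reads_per_ref=1), tmp_path)
        with pytest.raises(ValueError):
            run_filter(run.sff_path, [], FilterConfig(), tmp_path / "out")

    def test_passed_reads_respect_min_length(self, benchmark):
        cfg_min = 200
        for rid, seq in benchmark.pre.items():
            assert len(seq) >= cfg_min


class TestSampleSheet:
    def test_roundtrip(self, tmp_path):
        p = tmp_path / "samples.tsv"
        p.write_text("# header\nS1\tTCAC\tACGRT\t\nS2\tTGAC\tACGRT\tAAGGT\n")
        sheet = read_sample_sheet(p)
        assert [s.sample_id for s in sheet] == ["S1", "S2"]
        assert sheet[0].rev_primer is None
        assert sheet[1].rev_primer == "AAGGT"

    def test_duplicate_mid_primer_rejected(self, tmp_path):
        p = tmp_path / "samples.tsv"
        p.write_text("S1\tTCAC\tACGRT\nS2\tTCAC\tACGRT\n")
        with pytest.raises(ValueError):
            read_sample_sheet(p)
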