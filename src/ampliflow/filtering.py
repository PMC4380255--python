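"""Demultiplexing and read filtering in a fixed order of operations.

Every read must first match one sample's mid tag and forward primer at the
5' end (Hamming comparison anchored at position 0; IUPAC degeneracies are
honoured on the primer side only).  A matched read then runs a gauntlet of
user-selected criteria in a strict order:

1. eliminate if the trimmed sequence is shorter than ``min_seq_length``;
2. eliminate if longer than ``max_seq_length``;
3. truncate immediately before the (``max_ambiguous``+1)-th ambiguous base;
4. truncate immediately before a reverse-primer site (the reverse
   complement of the sample's reverse primer, leftmost hit);
5. truncate immediately before the first ``window_len``-base sliding window
   (step 1) whose mean quality falls below ``window_min_qual``;
6. re-check ``min_seq_length`` after all truncations; an elimination here is
   attributed to the criterion that truncated last.

An eliminated read is attributed to exactly one criterion (the first that
fired); truncation counters increment independently, so one read may appear
under several truncation criteria.  Finally the read's flowgram is trimmed
to the flows of its retained bases so that denoising sees flow values for
exactly the kept sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from Bio.Seq import Seq

from .sffio import (
    FlowOrder,
    ReadRecord,
    read_sfftxt,
    write_fasta,
    write_flowgrams,
)

log = logging.getLogger(__name__)

# IUPAC nucleotide codes -> the plain bases they stand for.  A read 'N'
# matches only a primer 'N'.
IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T", "N"},
}

CRITERIA = (
    "min_seq_length",
    "max_seq_length",
    "max_ambiguous",
    "reverse_primer",
    "window_quality",
)


def iupac_mismatches(pattern: str, text: str) -> int:
    """Hamming mismatch count of an IUPAC pattern against a plain sequence."""
    if len(pattern) != len(text):
        raise ValueError("pattern and text lengths differ")
    return sum(t not in IUPAC[p] for p, t in zip(pattern.upper(), text.upper()))


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class SampleSpec:
    """One demultiplexing bin: mid tag + forward primer (+ optional reverse)."""

    sample_id: str
    mid_tag: str
    fwd_primer: str
    rev_primer: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.mid_tag or not set(self.mid_tag) <= set("ACGT"):
            raise ValueError(f"{self.sample_id}: mid tag must be nonempty over ACGT")
        for name, primer in (("fwd", self.fwd_primer), ("rev", self.rev_primer)):
            if name == "rev" and primer is None:
                continue
            if not primer or not set(primer.upper()) <= set(IUPAC):
                raise ValueError(f"{self.sample_id}: {name} primer must be IUPAC")


def read_sample_sheet(path: str | Path) -> list[SampleSpec]:
    """Tab-separated sample sheet: sample_id, mid, fwd_primer[, rev_primer]."""
    samples: list[SampleSpec] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"sample sheet line needs >= 3 columns: {line!r}")
            samples.append(
                SampleSpec(
                    sample_id=parts[0],
                    mid_tag=parts[1].upper(),
                    fwd_primer=parts[2].upper(),
                    rev_primer=parts[3].upper() if len(parts) > 3 and parts[3] else None,
                )
            )
    if not samples:
        raise ValueError(f"{path}: no sample sheet entries")
    seen = set()
    for s in samples:
        key = (s.mid_tag, s.fwd_primer)
        if key in seen:
            raise ValueError(f"duplicate (mid, primer) pair for sample {s.sample_id}")
        seen.add(key)
    return samples


@dataclass
class FilterConfig:
    """User-selected filtering criteria; ``None`` switches a criterion off."""

    mid_mismatches: int = 1
    primer_mismatches: int = 2
    min_seq_length: Optional[int] = None
    max_seq_length: Optional[int] = None
    max_ambiguous: Optional[int] = None
    remove_rev_primer: bool = False
    window_len: Optional[int] = None
    window_min_qual: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mid_mismatches < 0 or self.primer_mismatches < 0:
            raise ValueError("mismatch allowances must be >= 0")
        if self.window_len is not None and self.window_len <= 0:
            raise ValueError("window_len must be > 0")
        if (
            self.min_seq_length is not None
            and self.max_seq_length is not None
            and self.min_seq_length > self.max_seq_length
        ):
            raise ValueError("min_seq_length > max_seq_length")

    @classmethod
    def standard(cls) -> "FilterConfig":
        """A common 454 amplicon recipe: length 200..600, no ambiguous bases,
        reverse primer removal, 50-base quality window at mean 25."""
        return cls(
            mid_mismatches=1,
            primer_mismatches=2,
            min_seq_length=200,
            max_seq_length=600,
            max_ambiguous=0,
            remove_rev_primer=True,
            window_len=50,
            window_min_qual=25.0,
        )


def match_mid_primer(
    bases: str,
    samples: Sequence[SampleSpec],
    mid_mm: int,
    primer_mm: int,
    start: int = 0,
) -> Optional[tuple[SampleSpec, int]]:
    """First sample whose mid tag + forward primer match the read prefix.

    Returns ``(sample, trim_offset)`` where ``trim_offset`` is the absolute
    base index just past the primer, or ``None`` when no sample matches.
    """
    for sample in samples:
        mid, primer = sample.mid_tag, sample.fwd_primer
        end = start + len(mid) + len(primer)
        if end > len(bases):
            continue
        mid_part = bases[start : start + len(mid)]
        if sum(a != b for a, b in zip(mid, mid_part)) > mid_mm:
            continue
        if iupac_mismatches(primer, bases[start + len(mid) : end]) > primer_mm:
            continue
        return sample, end
    return None


@dataclass
class FilterOutcome:
    passed: bool
    kept_len: int
    truncated_by: list[str] = field(default_factory=list)
    eliminated_by: Optional[str] = None


def apply_filters(
    bases: str,
    quals: Sequence[int],
    sample: SampleSpec,
    cfg: FilterConfig,
) -> FilterOutcome:
    """Run the fixed criterion order on an already-demultiplexed read.

    ``bases``/``quals`` must be the portion *after* the mid tag and primer.
    """
    n0 = len(bases)
    if cfg.min_seq_length is not None and n0 < cfg.min_seq_length:
        return FilterOutcome(False, 0, eliminated_by="min_seq_length")
    if cfg.max_seq_length is not None and n0 > cfg.max_seq_length:
        return FilterOutcome(False, 0, eliminated_by="max_seq_length")

    kept = n0
    truncated_by: list[str] = []

    if cfg.max_ambiguous is not None:
        seen = 0
        for i in range(kept):
            if bases[i] == "N":
                seen += 1
                if seen > cfg.max_ambiguous:
                    kept = i
                    truncated_by.append("max_ambiguous")
                    break

    if cfg.remove_rev_primer and sample.rev_primer:
        site = reverse_complement(sample.rev_primer)
        m = len(site)
        for pos in range(0, kept - m + 1):
            if iupac_mismatches(site, bases[pos : pos + m]) <= cfg.primer_mismatches:
                kept = pos
                truncated_by.append("reverse_primer")
                break

    if cfg.window_len is not None and cfg.window_min_qual is not None:
        w = cfg.window_len
        q = quals[:kept]
        if len(q) >= w:
            running = sum(q[:w])
            threshold = cfg.window_min_qual * w
            for s in range(len(q) - w + 1):
                if s:
                    running += q[s + w - 1] - q[s - 1]
                if running < threshold:
                    kept = s
                    truncated_by.append("window_quality")
                    break

    too_short = cfg.min_seq_length is not None and kept < cfg.min_seq_length
    if truncated_by and (too_short or kept == 0):
        return FilterOutcome(False, 0, truncated_by, eliminated_by=truncated_by[-1])
    return FilterOutcome(True, kept, truncated_by)


def trim_flowgram(
    read: ReadRecord, kept_bases: tuple[int, int]
) -> tuple[list[float], int]:
    """Flow values spanning a half-open base interval of the read.

    Returns ``(values, start_flow)`` where values run from the flow of the
    first kept base through the flow of the last kept base inclusive
    (interior zero flows preserved), and ``start_flow`` is the absolute flow
    position of the first value.  If the first kept base shares its flow
    with the preceding primer base (a homopolymer spanning the junction),
    that shared flow is included, with the primer's contribution inherent in
    its value.
    """
    start, end = kept_bases
    if end <= start:
        raise ValueError("kept base interval is empty")
    if start < 0 or end > len(read.bases):
        raise ValueError("kept base interval outside the read")
    fstart = read.flow_index[start]
    fend = read.flow_index[end - 1]
    return read.flow_values[fstart : fend + 1], fstart


@dataclass
class FilterReport:
    """Accounting of the filtering step.

    ``matched == passed + eliminated`` per sample and in total; each
    eliminated read is attributed to exactly one criterion, while a read may
    be counted under several truncation criteria.
    """

    eliminated: dict[str, int] = field(default_factory=dict)
    truncated: dict[str, int] = field(default_factory=dict)
    per_sample: dict[str, dict[str, int]] = field(default_factory=dict)
    unmatched: int = 0
    skipped_parse: int = 0

    def _sample(self, sample_id: str) -> dict[str, int]:
        return self.per_sample.setdefault(sample_id, {"matched": 0, "passed": 0})

    def count_match(self, sample_id: str) -> None:
        self._sample(sample_id)["matched"] += 1

    def count_pass(self, sample_id: str) -> None:
        self._sample(sample_id)["passed"] += 1

    def count_outcome(self, outcome: FilterOutcome) -> None:
        for crit in outcome.truncated_by:
            self.truncated[crit] = self.truncated.get(crit, 0) + 1
        if outcome.eliminated_by:
            self.eliminated[outcome.eliminated_by] = (
                self.eliminated.get(outcome.eliminated_by, 0) + 1
            )

    @property
    def total_matched(self) -> int:
        return sum(s["matched"] for s in self.per_sample.values())

    @property
    def total_passed(self) -> int:
        return sum(s["passed"] for s in self.per_sample.values())

    @property
    def total_eliminated(self) -> int:
        return sum(self.eliminated.values())

    def to_tsv(self) -> str:
        lines = ["section\tname\teliminated\ttruncated"]
        for crit in CRITERIA:
            lines.append(
                f"criterion\t{crit}\t{self.eliminated.get(crit, 0)}"
                f"\t{self.truncated.get(crit, 0)}"
            )
        lines.append("section\tname\tmatched\tpassed")
        for sid in sorted(self.per_sample):
            s = self.per_sample[sid]
            lines.append(f"sample\t{sid}\t{s['matched']}\t{s['passed']}")
        lines.append(f"total\tmatched\t{self.total_matched}\t")
        lines.append(f"total\tpassed\t{self.total_passed}\t")
        lines.append(f"total\teliminated\t{self.total_eliminated}\t")
        lines.append(f"total\tunmatched\t{self.unmatched}\t")
        lines.append(f"total\tskipped_parse\t{self.skipped_parse}\t")
        return "\n".join(lines) + "\n"

    def to_text(self) -> str:
        width = max(len(c) for c in CRITERIA) + 2
        out = ["Filtering report", "", "criterion".ljust(width) + "eliminated  truncated"]
        for crit in CRITERIA:
            out.append(
                crit.ljust(width)
                + f"{self.eliminated.get(crit, 0):>10}  {self.truncated.get(crit, 0):>9}"
            )
        out.append("")
        out.append("sample".ljust(width) + "   matched     passed")
        for sid in sorted(self.per_sample):
            s = self.per_sample[sid]
            out.append(sid.ljust(width) + f"{s['matched']:>10}  {s['passed']:>9}")
        out.append("")
        out.append(
            f"total: matched {self.total_matched}, passed {self.total_passed}, "
            f"eliminated {self.total_eliminated}, unmatched {self.unmatched}, "
            f"unparseable {self.skipped_parse}"
        )
        return "\n".join(out) + "\n"


@dataclass
class FilterRun:
    """Everything the filtering step produced."""

    report: FilterReport
    flow_order: FlowOrder
    bin_paths: dict[str, Path]
    fasta_path: Path
    meta_path: Path
    report_txt: Path
    report_tsv: Path


def run_filter(
    sff_path: str | Path,
    samples: Sequence[SampleSpec],
    cfg: FilterConfig,
    outdir: str | Path,
    use_clips: bool = False,
) -> FilterRun:
    """Filter an sff.txt run end to end.

    Reads are binned for denoising by (forward primer, flow-cycle phase of
    the first retained flow): flowgrams are only positionally comparable
    when they are in phase.  With conventionally designed mid tags all
    samples of a primer land in one bin.  ``use_clips`` applies the dump's
    left clip point before mid-tag detection.
    """
    if not samples:
        raise ValueError("no sample sheet entries")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    flow_order, reader = read_sfftxt(sff_path)
    report = FilterReport()
    # bin key -> (label, [(read_id, flows)], phase)
    bins: dict[tuple[str, int], tuple[str, list[tuple[str, list[float]]], int]] = {}
    fasta_records: list[tuple[str, str, dict[str, object]]] = []
    meta_rows: list[tuple[str, str, str, int, int]] = []
    primer_labels: dict[str, int] = {}

    for read in reader:
        start = read.clip_left if use_clips else 0
        hit = match_mid_primer(
            read.bases, samples, cfg.mid_mismatches, cfg.primer_mismatches, start
        )
        if hit is None:
            report.unmatched += 1
            continue
        sample, offset = hit
        report.count_match(sample.sample_id)
        outcome = apply_filters(
            read.bases[offset:], read.quals[offset:], sample, cfg
        )
        report.count_outcome(outcome)
        if not outcome.passed:
            continue
        report.count_pass(sample.sample_id)
        kept = (offset, offset + outcome.kept_len)
        flows, start_flow = trim_flowgram(read, kept)
        phase = start_flow % flow_order.cycle_len
        key = (sample.fwd_primer, phase)
        if key not in bins:
            pnum = primer_labels.setdefault(sample.fwd_primer, len(primer_labels) + 1)
            label = f"bin_p{pnum}_f{phase}"
            bins[key] = (label, [], phase)
        label, entries, _ = bins[key]
        entries.append((read.id, flows))
        fasta_records.append(
            (read.id, read.bases[kept[0] : kept[1]], {"sample": sample.sample_id})
        )
        meta_rows.append((read.id, sample.sample_id, label, len(flows), outcome.kept_len))

    report.skipped_parse = reader.skipped

    bin_paths: dict[str, Path] = {}
    for (primer, phase), (label, entries, _) in sorted(bins.items()):
        path = outdir / f"{label}.flows.tsv"
        write_flowgrams(label, entries, path, flow_chars=flow_order.chars, phase=phase)
        bin_paths[label] = path

    fasta_path = outdir / "filtered.fasta"
    write_fasta(fasta_records, fasta_path)

    meta_path = outdir / "reads_meta.tsv"
    with open(meta_path, "w") as fh:
        fh.write("read_id\tsample_id\tbin\tflow_length\tkept_bases\n")
        for row in meta_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")

    report_txt = outdir / "filter_report.txt"
    report_txt.write_text(report.to_text())
    report_tsv = outdir / "filter_report.tsv"
    report_tsv.write_text(report.to_tsv())

    log.info(
        "filtering: %d matched, %d passed, %d eliminated, %d unmatched",
        report.total_matched, report.total_passed,
        report.total_eliminated, report.unmatched,
    )
    return FilterRun(
        report=report,
        flow_order=flow_order,
        bin_paths=bin_paths,
        fasta_path=fasta_path,
        meta_path=meta_path,
        report_txt=report_txt,
        report_tsv=report_tsv,
    )
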