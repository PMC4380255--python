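"""Readers and writers for flowgram-space sequencing data.

The entry format is the plain-text dump of an SFF file (the output of
``sffinfo``): a key/value header that declares the flow order and flow
count, followed by one block per read carrying the flowgram, the per-base
flow indexes, the called bases, quality scores and clip points.  Everything
downstream of parsing uses 0-based, half-open coordinates; the 1-based
inclusive clip convention of the dump is converted exactly once, here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")


class SffParseError(ValueError):
    """Raised when the header of an sff.txt dump is unusable."""


@dataclass(frozen=True)
class FlowOrder:
    """Cyclic nucleotide wash order plus the run's total flow count.

    ``chars`` holds one character per cycle position (e.g. ``"TACG"``); the
    cycle repeats implicitly out to ``num_flows``.
    """

    chars: str
    num_flows: int

    def __post_init__(self) -> None:
        if not self.chars or not set(self.chars) <= set("ACGT"):
            raise ValueError(f"flow order must be nonempty over ACGT, got {self.chars!r}")
        if self.num_flows < 1:
            raise ValueError("num_flows must be >= 1")

    def char_at(self, flow: int) -> str:
        return self.chars[flow % len(self.chars)]

    @property
    def cycle_len(self) -> int:
        return len(self.chars)


@dataclass
class ReadRecord:
    """One sequencing read as parsed from an sff.txt dump.

    ``flow_index`` is 0-based per called base (bases of one homopolymer share
    a flow).  ``clip_left``/``clip_right`` are a 0-based half-open interval of
    high-quality bases; ``clip_right == len(bases)`` means no right clip.
    """

    id: str
    flow_values: list[float]
    flow_index: list[int]
    bases: str
    quals: list[int]
    clip_left: int = 0
    clip_right: int = -1

    def __post_init__(self) -> None:
        if self.clip_right < 0:
            self.clip_right = len(self.bases)

    def validate(self, num_flows: int | None = None) -> None:
        n = len(self.bases)
        if not (len(self.flow_index) == n == len(self.quals)):
            raise ValueError(
                f"{self.id}: per-base field lengths disagree "
                f"(index={len(self.flow_index)}, bases={n}, quals={len(self.quals)})"
            )
        if not set(self.bases) <= VALID_BASES:
            raise ValueError(f"{self.id}: bases outside ACGTN")
        if any(q < 0 or q > 40 for q in self.quals):
            raise ValueError(f"{self.id}: quality score outside 0..40")
        if any(b > a for a, b in zip(self.flow_index[1:], self.flow_index)):
            raise ValueError(f"{self.id}: flow indexes not non-decreasing")
        if self.flow_index and self.flow_index[-1] >= len(self.flow_values):
            raise ValueError(f"{self.id}: flow index beyond flowgram")
        if num_flows is not None and len(self.flow_values) > num_flows:
            raise ValueError(f"{self.id}: more flow values than declared flows")
        if any(v < 0 for v in self.flow_values):
            raise ValueError(f"{self.id}: negative flow value")
        if not 0 <= self.clip_left <= len(self.bases):
            raise ValueError(f"{self.id}: bad left clip")
        if not self.clip_left <= self.clip_right <= len(self.bases):
            raise ValueError(f"{self.id}: bad right clip")


def minimal_period(s: str) -> str:
    """Shortest prefix whose repetition generates ``s`` (s itself if aperiodic)."""
    for p in range(1, len(s)):
        if all(s[i] == s[i % p] for i in range(len(s))):
            return s[:p]
    return s


# per-read keys recognised inside a block; anything else is ignored
_READ_KEYS = {
    "Flowgram",
    "Flow Indexes",
    "Bases",
    "Quality Scores",
    "Clip Qual Left",
    "Clip Qual Right",
}


class SffTextReader:
    """Streaming reader for sff.txt dumps.

    Iterating yields validated :class:`ReadRecord` objects.  Malformed read
    blocks are logged (with read id and line number), skipped, and counted in
    :attr:`skipped`.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.skipped = 0
        self._lines = self.path.read_text().splitlines()
        self._pos = 0
        self.flow_order = self._parse_header()

    def _parse_header(self) -> FlowOrder:
        header: dict[str, str] = {}
        while self._pos < len(self._lines):
            line = self._lines[self._pos]
            if line.startswith(">"):
                break
            if ":" in line:
                key, _, value = line.partition(":")
                header[key.strip()] = value.strip()
            self._pos += 1
        if "Flow Chars" not in header or "# of Flows" not in header:
            raise SffParseError(
                f"{self.path}: header must declare 'Flow Chars' and '# of Flows'"
            )
        chars = "".join(header["Flow Chars"].split()).upper()
        num_flows = int(header["# of Flows"])
        return FlowOrder(chars=minimal_period(chars), num_flows=num_flows)

    def __iter__(self) -> Iterator[ReadRecord]:
        lines, n = self._lines, len(self._lines)
        i = self._pos
        while i < n:
            if not lines[i].startswith(">"):
                i += 1
                continue
            start_line = i
            read_id = lines[i][1:].split()[0] if lines[i][1:].split() else ""
            i += 1
            fields: dict[str, str] = {}
            while i < n and not lines[i].startswith(">"):
                line = lines[i]
                if ":" in line:
                    key, _, value = line.partition(":")
                    key = key.strip()
                    if key in _READ_KEYS:
                        fields[key] = value.strip()
                i += 1
            try:
                rec = self._build_record(read_id, fields)
                rec.validate(self.flow_order.num_flows)
            except (ValueError, KeyError) as exc:
                self.skipped += 1
                log.warning(
                    "skipping malformed read %r at line %d: %s",
                    read_id, start_line + 1, exc,
                )
                continue
            yield rec

    def _build_record(self, read_id: str, fields: Mapping[str, str]) -> ReadRecord:
        flows = [round(float(x), 2) for x in fields["Flowgram"].split()]
        idx = [int(x) for x in fields["Flow Indexes"].split()]
        # some dumps store flow indexes as deltas from the previous base
        if any(b < a for a, b in zip(idx, idx[1:])):
            acc, cum = 0, []
            for d in idx:
                acc += d
                cum.append(acc)
            idx = cum
        idx = [x - 1 for x in idx]  # 1-based on disk
        bases = fields["Bases"].replace(" ", "").upper()
        quals = [int(x) for x in fields["Quality Scores"].split()]
        clip_left = int(fields.get("Clip Qual Left", "1"))
        clip_right = int(fields.get("Clip Qual Right", "0"))
        return ReadRecord(
            id=read_id,
            flow_values=flows,
            flow_index=idx,
            bases=bases,
            quals=quals,
            clip_left=max(clip_left - 1, 0),
            clip_right=len(bases) if clip_right == 0 else clip_right,
        )


def read_sfftxt(path: str | Path) -> tuple[FlowOrder, SffTextReader]:
    """Open an sff.txt dump; returns its flow order and a record stream."""
    reader = SffTextReader(path)
    return reader.flow_order, reader


# ---------------------------------------------------------------------------
# writers

def write_fasta(
    records: Iterable[tuple[str, str, Mapping[str, object]]],
    path: str | Path,
) -> int:
    """Write FASTA records with optional header annotations.

    Each record is ``(id, sequence, annotations)``.  A ``size`` annotation is
    appended directly to the id as ``;size=<n>`` (the dereplication dialect
    expected by UCHIME); any other annotations become space-separated
    ``key=value`` tokens.  Empty sequences are skipped with a warning.
    Returns the number of records written.
    """
    written = 0
    with open(path, "w") as fh:
        for rid, seq, ann in records:
            if not seq:
                log.warning("skipping empty sequence for %r", rid)
                continue
            ann = dict(ann)
            header = rid
            if "size" in ann:
                header += f";size={ann.pop('size')}"
            for key, value in ann.items():
                header += f" {key}={value}"
            fh.write(f">{header}\n{seq}\n")
            written += 1
    return written


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping.

    The id is the first whitespace-separated token of the header line,
    including any ``;size=`` suffix.
    """
    from Bio.SeqIO.FastaIO import SimpleFastaParser

    out: dict[str, str] = {}
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            out[header.split()[0]] = seq.upper()
    return out


def write_flowgrams(
    bin_label: str,
    entries: Iterable[tuple[str, Sequence[float]]],
    path: str | Path,
    flow_chars: str = "",
    phase: int = 0,
) -> int:
    """Write a tab-separated flowgram file: one ``id  length  values...`` line
    per entry, flow values at two decimals.

    The header line records the bin label plus the flow order and cycle phase
    needed to reinterpret the values as bases later.
    """
    written = 0
    with open(path, "w") as fh:
        fh.write(f"# bin={bin_label}\tflow_order={flow_chars or '.'}\tphase={phase}\n")
        for rid, values in entries:
            vals = "\t".join(f"{v:.2f}" for v in values)
            fh.write(f"{rid}\t{len(values)}" + ("\t" + vals if vals else "") + "\n")
            written += 1
    return written


def read_flowgrams(path: str | Path) -> tuple[dict[str, str], list[tuple[str, list[float]]]]:
    """Read a flowgram file written by :func:`write_flowgrams`.

    Returns ``(meta, entries)`` where meta holds the header fields
    (``bin``, ``flow_order``, ``phase``).
    """
    meta: dict[str, str] = {}
    entries: list[tuple[str, list[float]]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split("\t"):
                    token = token.strip()
                    if "=" in token:
                        key, _, value = token.partition("=")
                        meta[key] = value
                continue
            parts = line.split("\t")
            rid, nval = parts[0], int(parts[1])
            values = [round(float(x), 2) for x in parts[2 : 2 + nval]]
            if len(values) != nval:
                raise ValueError(f"{path}: entry {rid} declares {nval} flows, has {len(values)}")
            entries.append((rid, values))
    return meta, entries


def write_abundance_tsv(pairs: Iterable[tuple[str, int]], path: str | Path) -> None:
    """Tab-separated (id, abundance) mapping, e.g. the Perseus frequency file."""
    with open(path, "w") as fh:
        for name, count in pairs:
            fh.write(f"{name}\t{count}\n")
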