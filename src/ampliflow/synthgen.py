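"""Synthetic flowgram runs with known ground truth.

The generator emulates the physical error process of flow-based sequencing:
each template is walked along the cyclic flow order to produce its ideal
integer flowgram (one value per nucleotide wash, equal to the homopolymer
length incorporated); Gaussian noise whose standard deviation grows with
the homopolymer length is added, clamped at zero and quantised to
hundredths; and the read's base calls, flow indexes and quality scores are
derived *from the noisy values* with the same half-down caller used for
reconstitution, so the simulated reads carry realistic homopolymer in/del
errors relative to their source references.  Output is a parseable sff.txt
dump plus a truth table, a sample sheet and a reference FASTA.

The default standard-deviation table is synthetic — chosen to be gently
increasing from 0.08 at zero signal — and is a replaceable parameter, not a
measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .filtering import SampleSpec
from .seqcall import CallPolicy, call_units
from .sffio import FlowOrder, write_fasta

DEFAULT_FLOW_CHARS = "TACG"

#: synthetic per-homopolymer-length flow-value standard deviations
DEFAULT_SD_TABLE: dict[int, float] = {
    0: 0.08, 1: 0.10, 2: 0.12, 3: 0.14, 4: 0.16, 5: 0.18, 6: 0.20, 7: 0.22,
}


def _default_samples() -> list[SampleSpec]:
    # mid tags start with the first flow-order nucleotide, mirroring the
    # key-anchored start of real runs; primer is a standard 16S V3 forward
    return [
        SampleSpec("S1", "TCACGTAC", "CCTACGGGAGGCAGCAG"),
        SampleSpec("S2", "TGTACGCA", "CCTACGGGAGGCAGCAG"),
    ]


@dataclass
class SimConfig:
    """Study conditions for one simulated run."""

    seed: int
    references: Optional[list[str]] = None
    n_references: int = 5
    ref_length: int = 250
    reads_per_ref: int | list[int] = 40
    flow_chars: str = DEFAULT_FLOW_CHARS
    sd_table: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_SD_TABLE))
    samples: list[SampleSpec] = field(default_factory=_default_samples)
    qual_mean: float = 37.0
    qual_decay: float = 0.02
    qual_jitter: float = 2.0

    def __post_init__(self) -> None:
        if any(not sd > 0 for sd in self.sd_table.values()):
            raise ValueError("sd table values must be > 0")
        if not self.samples:
            raise ValueError("need at least one sample")


def ideal_flowgram(sequence: str, flow_chars: str | FlowOrder) -> list[int]:
    """Noise-free integer flowgram of a sequence over a cyclic flow order.

    Walks the cycle; each flow's value is the homopolymer length of that
    flow's nucleotide at the current template position (0 if absent), until
    the whole sequence is consumed.
    """
    chars = flow_chars.chars if isinstance(flow_chars, FlowOrder) else flow_chars
    if not set(sequence) <= set(chars):
        raise ValueError("sequence contains bases absent from the flow order")
    flows: list[int] = []
    i, f = 0, 0
    n = len(sequence)
    while i < n:
        c = chars[f % len(chars)]
        if sequence[i] == c:
            k = 1
            while i + k < n and sequence[i + k] == c:
                k += 1
            flows.append(k)
            i += k
        else:
            flows.append(0)
        f += 1
    return flows


def noisy_flowgram(
    ideal: Sequence[int], sd_table: dict[int, float], rng: np.random.Generator
) -> list[float]:
    """Gaussian noise per flow, sd indexed by the true homopolymer length
    (last table entry beyond its range), clamped at 0, hundredths precision."""
    last = max(sd_table)
    out = []
    for n in ideal:
        sd = sd_table[min(n, last)]
        out.append(round(max(0.0, float(rng.normal(n, sd))), 2))
    return out


def random_references(
    rng: np.random.Generator,
    n: int,
    length: int,
    forbid_first: str = "",
) -> list[str]:
    """Random ACGT references; the first base avoids ``forbid_first`` so a
    primer-terminal homopolymer never spans the trim junction."""
    bases = np.array(list("ACGT"))
    refs = []
    first_choices = [b for b in "ACGT" if b not in forbid_first]
    for _ in range(n):
        seq = bases[rng.integers(0, 4, size=length)]
        seq[0] = first_choices[int(rng.integers(0, len(first_choices)))]
        refs.append("".join(seq))
    return refs


@dataclass
class SimRun:
    sff_path: Path
    truth_path: Path
    sample_sheet_path: Path
    refs_path: Path
    references: dict[str, str]
    flow_order: FlowOrder
    n_reads: int


def write_run(cfg: SimConfig, outdir: str | Path) -> SimRun:
    """Simulate a run and write sff.txt + truth table + sample sheet + refs.

    Reads cycle through the samples; read blocks carry flow values at two
    decimals, absolute 1-based flow indexes consistent with the noisy base
    calls, and clip points covering the whole read.  Output is byte-stable
    for a given config and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    primer_last = {s.fwd_primer[-1].upper() for s in cfg.samples}
    refs = cfg.references or random_references(
        rng, cfg.n_references, cfg.ref_length, forbid_first="".join(primer_last)
    )
    ref_names = [f"ref{i + 1}" for i in range(len(refs))]
    per_ref = (
        list(cfg.reads_per_ref)
        if isinstance(cfg.reads_per_ref, (list, tuple))
        else [cfg.reads_per_ref] * len(refs)
    )
    if len(per_ref) != len(refs):
        raise ValueError("abundance vector length != number of references")

    chars = cfg.flow_chars
    reads = []
    counter = 0
    for ref_name, ref, n_reads in zip(ref_names, refs, per_ref):
        for _ in range(n_reads):
            sample = cfg.samples[counter % len(cfg.samples)]
            template = sample.mid_tag + sample.fwd_primer + ref
            ideal = ideal_flowgram(template, chars)
            noisy = noisy_flowgram(ideal, cfg.sd_table, rng)
            rid = f"r{counter:06d}"
            reads.append((rid, sample.sample_id, ref_name, noisy))
            counter += 1

    max_flows = max(len(r[3]) for r in reads)
    cycle = len(chars)
    num_flows = ((max_flows + cycle - 1) // cycle) * cycle
    flow_order = FlowOrder(chars=chars, num_flows=num_flows)
    policy = CallPolicy(flow_order=flow_order)

    sff_path = outdir / "run.sff.txt"
    truth_path = outdir / "truth.tsv"
    with open(sff_path, "w") as sff, open(truth_path, "w") as truth:
        full_chars = (chars * (num_flows // cycle + 1))[:num_flows]
        sff.write("Common Header:\n")
        sff.write("  Magic Number:  0x2E736666\n")
        sff.write("  Version:       0001\n")
        sff.write(f"  # of Reads:    {len(reads)}\n")
        sff.write(f"  # of Flows:    {num_flows}\n")
        sff.write("  Flowgram Code: 1\n")
        sff.write(f"  Flow Chars:    {full_chars}\n\n")
        truth.write("read_id\tsample_id\tref_id\n")
        for rid, sample_id, ref_name, noisy in reads:
            units = list(call_units(noisy, policy))
            bases = "".join(b for b, _ in units)
            flow_idx = [f + 1 for _, f in units]  # 1-based on disk
            quals = np.clip(
                np.rint(
                    cfg.qual_mean
                    - cfg.qual_decay * np.arange(len(bases))
                    + rng.normal(0.0, cfg.qual_jitter, size=len(bases))
                ),
                0, 40,
            ).astype(int)
            sff.write(f">{rid}\n")
            sff.write(f"  # of Bases:    {len(bases)}\n")
            sff.write("  Clip Qual Left:   1\n")
            sff.write("  Clip Qual Right:  0\n\n")
            sff.write("Flowgram:\t" + "\t".join(f"{v:.2f}" for v in noisy) + "\n")
            sff.write("Flow Indexes:\t" + "\t".join(str(x) for x in flow_idx) + "\n")
            sff.write("Bases:\t" + bases + "\n")
            sff.write("Quality Scores:\t" + "\t".join(str(q) for q in quals) + "\n\n")
            truth.write(f"{rid}\t{sample_id}\t{ref_name}\n")

    sheet_path = outdir / "samples.tsv"
    with open(sheet_path, "w") as fh:
        fh.write("# sample_id\tmid\tfwd_primer\trev_primer\n")
        for s in cfg.samples:
            rev = s.rev_primer or ""
            fh.write(f"{s.sample_id}\t{s.mid_tag}\t{s.fwd_primer}\t{rev}\n")

    refs_path = outdir / "refs.fasta"
    write_fasta([(name, seq, {}) for name, seq in zip(ref_names, refs)], refs_path)

    return SimRun(
        sff_path=sff_path,
        truth_path=truth_path,
        sample_sheet_path=sheet_path,
        refs_path=refs_path,
        references=dict(zip(ref_names, refs)),
        flow_order=flow_order,
        n_reads=len(reads),
    )


def read_truth(path: str | Path) -> dict[str, tuple[str, str]]:
    """Truth table as {read_id: (sample_id, ref_id)}."""
    out: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            rid, sample_id, ref_id = line.rstrip("\n").split("\t")
            out[rid] = (sample_id, ref_id)
    return out
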