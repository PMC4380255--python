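"""Quantifying what denoising did to the reads.

Without ground truth, the soundest check on a denoising run is the spectrum
of changes it made: pyrosequencing errors are overwhelmingly homopolymer
in/dels, so a denoiser that mostly substitutes bases is doing something
other than removing sequencing error.  This module aligns each read's
pre-denoising sequence against its post-denoising sequence (global
Needleman-Wunsch, match +1 / mismatch -1 / gap -1) and classifies every
difference as an insertion, deletion or substitution; conversions of an N
are tallied separately.

Against known reference sequences (mock-community style), an in/del error
rate per aligned base is computed with free end gaps on the reference side,
so 3' truncations made during filtering are not charged as deletions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .sffio import read_fasta

MATCH, MISMATCH, GAP = 1, -1, -1


def _seq_codes(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def _nw_matrix(
    a: str, b: str, match: int, mismatch: int, gap: int, free_a: bool
) -> np.ndarray:
    """Score matrix H[(len(a)+1) x (len(b)+1)], row-vectorised.

    ``free_a`` makes leading/trailing gaps against ``a`` free (semi-global:
    ``a`` is the reference, ``b`` must align end to end).
    """
    n, m = len(a), len(b)
    aa, bb = _seq_codes(a), _seq_codes(b)
    H = np.empty((n + 1, m + 1), dtype=np.float64)
    H[0] = gap * np.arange(m + 1)
    col0 = np.zeros(n + 1) if free_a else gap * np.arange(n + 1)
    jj = np.arange(1, m + 1)
    for i in range(1, n + 1):
        s = np.where(bb == aa[i - 1], match, mismatch)
        c = np.maximum(H[i - 1, :m] + s, H[i - 1, 1:] + gap)
        # resolve the in-row (left-gap) dependency with a prefix max:
        # H[i,j] = max(c[j], H[i,j-1] + gap)  =>  T[j] = H[i,j] - gap*j
        t = np.maximum.accumulate(np.concatenate(([col0[i]], c - gap * jj)))
        H[i, 0] = col0[i]
        H[i, 1:] = t[1:] + gap * jj
    return H


def global_align(
    a: str,
    b: str,
    match: int = MATCH,
    mismatch: int = MISMATCH,
    gap: int = GAP,
    free_end_gaps_a: bool = False,
) -> tuple[str, str, float]:
    """Optimal global alignment of two sequences over {A,C,G,T,N}.

    Returns ``(aligned_a, aligned_b, score)``.  Traceback ties break
    deterministically: diagonal, then up (gap in b), then left (gap in a).
    Empty inputs give an all-gap alignment.
    """
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return "-" * m if n == 0 else a, "-" * n if m == 0 else b, float(gap * (n + m))
    H = _nw_matrix(a, b, match, mismatch, gap, free_end_gaps_a)
    if free_end_gaps_a:
        i = int(np.argmax(H[:, m]))
        score = float(H[i, m])
        tail = n - i  # free trailing reference overhang
    else:
        i, score, tail = n, float(H[n, m]), 0
    j = m
    al_a: list[str] = []
    al_b: list[str] = []
    if tail:
        al_a.append(a[i:][::-1])
        al_b.append("-" * tail)
    eps = 1e-6
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = match if a[i - 1] == b[j - 1] else mismatch
            if abs(H[i, j] - (H[i - 1, j - 1] + s)) < eps:
                al_a.append(a[i - 1])
                al_b.append(b[j - 1])
                i -= 1
                j -= 1
                continue
        up_cost = 0 if (free_end_gaps_a and j == 0) else gap
        if i > 0 and abs(H[i, j] - (H[i - 1, j] + up_cost)) < eps:
            al_a.append(a[i - 1])
            al_b.append("-")
            i -= 1
            continue
        al_a.append("-")
        al_b.append(b[j - 1])
        j -= 1
    return "".join(al_a)[::-1], "".join(al_b)[::-1], score


@dataclass
class ChangeSpectrum:
    """Classified differences between paired pre/post sequences."""

    insertions: int = 0
    deletions: int = 0
    substitutions: int = 0
    n_conversions: int = 0
    per_read: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.insertions + self.deletions + self.substitutions

    def to_tsv(self) -> str:
        return (
            "insertions\tdeletions\tsubstitutions\ttotal\tn_conversions\n"
            f"{self.insertions}\t{self.deletions}\t{self.substitutions}"
            f"\t{self.total}\t{self.n_conversions}\n"
        )


def _classify(al_pre: str, al_post: str) -> tuple[int, int, int, int]:
    ins = dels = subs = nconv = 0
    for x, y in zip(al_pre, al_post):
        if x == "-":
            ins += 1
        elif y == "-":
            dels += 1
        elif x != y:
            subs += 1
            if (x == "N") != (y == "N"):
                nconv += 1
    return ins, dels, subs, nconv


def spectrum(
    pre_fasta: str | Path | Mapping[str, str],
    post_fasta: str | Path | Mapping[str, str],
    keep_per_read: bool = False,
) -> ChangeSpectrum:
    """Per-read change spectrum between two FASTA files with matching ids.

    A gap in the post sequence is a deletion (denoising removed a base), a
    gap in the pre sequence an insertion, a mismatched pair a substitution.
    """
    pre = _load(pre_fasta)
    post = _load(post_fasta)
    if set(pre) != set(post):
        offending = next(iter(set(pre) ^ set(post)))
        raise ValueError(f"read id {offending!r} present in only one input")
    out = ChangeSpectrum()
    for rid, pre_seq in pre.items():
        al_pre, al_post, _ = global_align(pre_seq, post[rid])
        ins, dels, subs, nconv = _classify(al_pre, al_post)
        out.insertions += ins
        out.deletions += dels
        out.substitutions += subs
        out.n_conversions += nconv
        if keep_per_read:
            out.per_read[rid] = (ins, dels, subs)
    return out


def _load(x: str | Path | Mapping[str, str]) -> dict[str, str]:
    if isinstance(x, Mapping):
        return {rid.split()[0].split(";")[0]: seq.upper() for rid, seq in x.items()}
    return {rid.split(";")[0]: seq for rid, seq in read_fasta(x).items()}


@dataclass
class ErrorRateResult:
    insertions: int
    deletions: int
    aligned_length: int

    @property
    def rate(self) -> float:
        return (self.insertions + self.deletions) / self.aligned_length if self.aligned_length else 0.0


def error_rate_vs_refs(
    reads_fasta: str | Path | Mapping[str, str],
    refs_fasta: str | Path | Mapping[str, str],
) -> ErrorRateResult:
    """Combined in/del error rate of reads against their best references.

    Each read is aligned to every reference with free end gaps on the
    reference side; the best-scoring reference wins (ties by file order).
    Only internal insertions and deletions are counted — substitutions are
    ignored (in/dels dominate flow-based sequencing error) and reference
    overhangs past the read's ends are free.  The denominator is the total
    read length aligned.
    """
    reads = _load(reads_fasta)
    refs = _load(refs_fasta)
    if not refs:
        raise ValueError("need at least one reference sequence")
    ref_items = list(refs.items())
    ins_total = del_total = length_total = 0
    for rid, seq in reads.items():
        best = None
        for _, ref_seq in ref_items:
            al_ref, al_read, score = global_align(ref_seq, seq, free_end_gaps_a=True)
            if best is None or score > best[0]:
                best = (score, al_ref, al_read)
        _, al_ref, al_read = best
        al_ref, al_read = _strip_ref_overhangs(al_ref, al_read)
        ins, dels, _, _ = _classify(al_ref, al_read)
        ins_total += ins
        del_total += dels
        length_total += len(seq)
    return ErrorRateResult(ins_total, del_total, length_total)


def _strip_ref_overhangs(al_ref: str, al_read: str) -> tuple[str, str]:
    """Drop leading/trailing columns where the read has a gap (free ends)."""
    start, end = 0, len(al_read)
    while start < end and al_read[start] == "-":
        start += 1
    while end > start and al_read[end - 1] == "-":
        end -= 1
    return al_ref[start:end], al_read[start:end]
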