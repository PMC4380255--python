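"""Reconstituting base sequences from (denoised) flowgrams.

A flow value v at a flow washing nucleotide X contributes ``h`` copies of X,
where h is v rounded to the nearest integer with .50 resolved *downward*
(the behaviour of the 454 software most of the time).  Whenever
``n_dropout_flows`` consecutive flows call zero bases, signal has dropped
out for a whole cycle minus one and a base was most likely missed, so a
single ``N`` is emitted per completed run (a run of 6 zero flows with the
default of 3 yields two Ns).

When a read is reconstituted from its cluster's (or trie path's) flowgram,
only the read's *own* filtered flow count is interpreted, so a short read
never inherits the 3' tail of a longer cluster-mate (no "accordion
effect").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

from .rounding import round_half_down
from .sffio import FlowOrder

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CallPolicy:
    """How flow values are interpreted as bases."""

    flow_order: FlowOrder
    n_dropout_flows: int = 3
    half_rounds_down: bool = True

    def __post_init__(self) -> None:
        if self.n_dropout_flows < 1:
            raise ValueError("n_dropout_flows must be >= 1")

    def homopolymer(self, v: float) -> int:
        if self.half_rounds_down:
            return round_half_down(v)
        # plain nearest-integer with ties up (the raw 454 description)
        h = int(round(v * 100))
        if h <= 0:
            return 0
        q, r = divmod(h, 100)
        return q + 1 if r >= 50 else q


def call_units(
    flows: Sequence[float],
    policy: CallPolicy,
    length_limit_flows: int | None = None,
    start_flow: int = 0,
) -> Iterator[tuple[str, int]]:
    """Yield ``(base, flow_position)`` pairs for the first ``length_limit_flows``
    flows, applying the rounding and dropout-N rules.

    ``start_flow`` is the absolute flow position of ``flows[0]``; only its
    value modulo the cycle length matters (it selects the nucleotides).
    An emitted N carries the position of the last flow of its zero-run.
    """
    limit = len(flows) if length_limit_flows is None else length_limit_flows
    if limit > len(flows):
        raise ValueError(f"length limit {limit} exceeds flowgram length {len(flows)}")
    order = policy.flow_order
    zero_run = 0
    for p in range(limit):
        v = flows[p]
        if v < 0:
            log.warning("negative flow value %.2f at flow %d treated as 0.00", v, p)
            v = 0.0
        h = policy.homopolymer(v)
        if h == 0:
            zero_run += 1
            if zero_run == policy.n_dropout_flows:
                yield "N", start_flow + p
                zero_run = 0
        else:
            zero_run = 0
            base = order.char_at(start_flow + p)
            for _ in range(h):
                yield base, start_flow + p


def call_bases(
    flows: Sequence[float],
    policy: CallPolicy,
    length_limit_flows: int | None = None,
    start_flow: int = 0,
) -> str:
    """Sequence over {A,C,G,T,N} called from a flowgram (see module docs)."""
    return "".join(base for base, _ in call_units(flows, policy, length_limit_flows, start_flow))


def reconstitute_all(
    assignments: Mapping[str, object],
    denoised_flowgrams: Mapping[object, Sequence[float]],
    per_read_flow_lengths: Mapping[str, int],
    policy: CallPolicy,
    start_flow: int = 0,
) -> Iterator[tuple[str, str, dict[str, object]]]:
    """Reconstitute every read from its assigned denoised flowgram.

    Yields ``(read_id, sequence, {"cluster": key})`` records ready for
    :func:`ampliflow.sffio.write_fasta`.  Each read is truncated to its own
    filtered flow count; a missing length is a bookkeeping bug and fatal.
    """
    for rid, key in assignments.items():
        if rid not in per_read_flow_lengths:
            raise KeyError(f"no filtered flowgram length recorded for read {rid!r}")
        flows = denoised_flowgrams[key]
        seq = call_bases(flows, policy, per_read_flow_lengths[rid], start_flow)
        yield rid, seq, {"cluster": key}
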