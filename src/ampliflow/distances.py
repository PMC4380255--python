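"""Denoising distance models.

A distance model answers one question: are two flow values *significantly
different*, i.e. more different than pyrosequencing noise alone would
explain?  Three models are supported:

* ``constant`` -- a single threshold ``j`` (e.g. 0.50) at every flow value;
* ``scaled_table`` -- ``k`` times a per-homopolymer-length standard
  deviation read from a table, so the allowance grows with signal strength;
* ``custom_table`` -- per-length distances used directly.

The comparison is boundary-inclusive: a difference exactly equal to the
threshold is *not* significant, so with j = 0.50 the not-distinct interval
around a center value of 1.09 is the closed interval [0.59, 1.59].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .rounding import round_half_down

log = logging.getLogger(__name__)

# guard against binary-float representation error at the hundredths boundary;
# far below the 0.01 resolution of flow values, so it never changes a decision
_EPS = 1e-9

_MODES = ("constant", "scaled_table", "custom_table")


@dataclass(frozen=True)
class DistanceModel:
    mode: str
    j: float = 0.0
    k: float = 0.0
    table: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "constant" and not self.j > 0:
            raise ValueError("constant distance j must be > 0")
        if self.mode == "scaled_table":
            if not self.k > 0:
                raise ValueError("multiplier k must be > 0")
            self._check_table(require_monotone=True)
        if self.mode == "custom_table":
            self._check_table(require_monotone=False)

    def _check_table(self, require_monotone: bool) -> None:
        if not self.table:
            raise ValueError("table modes need a distance table")
        lengths = sorted(self.table)
        if lengths != list(range(lengths[0], lengths[-1] + 1)) or lengths[0] != 0:
            raise ValueError("table must cover homopolymer lengths 0..max without gaps")
        if any(not self.table[n] > 0 for n in lengths):
            raise ValueError("table entries must be > 0")
        if require_monotone:
            values = [self.table[n] for n in lengths]
            if any(b < a for a, b in zip(values, values[1:])):
                raise ValueError("sd table must be non-decreasing in homopolymer length")

    # -- constructors -------------------------------------------------------

    @classmethod
    def constant(cls, j: float) -> "DistanceModel":
        return cls(mode="constant", j=j)

    @classmethod
    def scaled(cls, k: float, table: dict[int, float]) -> "DistanceModel":
        return cls(mode="scaled_table", k=k, table=dict(table))

    @classmethod
    def custom(cls, table: dict[int, float]) -> "DistanceModel":
        return cls(mode="custom_table", table=dict(table))


_warned_overflow: set[int] = set()


def threshold_at(model: DistanceModel, center_value: float) -> float:
    """Maximum non-significant difference for a given center flow value.

    Table modes index by the center's value rounded to the nearest
    homopolymer length (.50 resolving downward, matching the base caller);
    lookups beyond the table's last entry use the last entry.
    """
    if center_value < 0:
        raise ValueError("center value must be >= 0")
    if model.mode == "constant":
        return model.j
    n = round_half_down(center_value)
    last = max(model.table)
    if n > last:
        if id(model) not in _warned_overflow:
            _warned_overflow.add(id(model))
            log.warning(
                "distance table ends at length %d; using its last entry for %d+", last, n
            )
        n = last
    sd = model.table[n]
    return model.k * sd if model.mode == "scaled_table" else sd


def distinct(model: DistanceModel, center_value: float, read_value: float) -> bool:
    """True iff the two flow values are significantly different.

    Boundary-inclusive: ``|center - read| == threshold`` is not distinct.
    """
    return abs(center_value - read_value) > threshold_at(model, center_value) + _EPS


def load_distance_table(path: str | Path) -> dict[int, float]:
    """Read a two-column TSV (homopolymer length, distance/sd)."""
    table: dict[int, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            length, value = line.split("\t")[:2]
            table[int(length)] = float(value)
    return table


def write_distance_table(table: dict[int, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# homopolymer_length\tsd\n")
        for n in sorted(table):
            fh.write(f"{n}\t{table[n]}\n")
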