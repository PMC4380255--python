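"""Flow-value rounding at the native hundredths precision.

Flow values are printed (and compared) at two decimals.  To keep the
".50 rounds down" rule free of binary-float traps, values are converted to
integer hundredths before any boundary decision.
"""

from __future__ import annotations


def hundredths(v: float) -> int:
    """Flow value as an integer count of hundredths."""
    return int(round(v * 100))


def round_half_down(v: float) -> int:
    """Nearest integer, with a fractional part of exactly .50 rounded down.

    This is the homopolymer caller used when interpreting flow values as
    bases: 1.50 -> 1, 1.51 -> 2, 0.50 -> 0.  Negative inputs clamp to 0.
    """
    h = hundredths(v)
    if h <= 0:
        return 0
    q, r = divmod(h, 100)
    return q + 1 if r > 50 else q
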