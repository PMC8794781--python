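"""Tiny helper: block-like intervals for resolution tests.

``phased_fraction`` only consumes ``contig``/``start``/``end``, so tests
that exercise pure interval arithmetic use this lightweight stand-in
instead of building two het sites per block.
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class IntervalBlock:
    contig: str
    start: int
    end: int


def interval_block(start: int, end: int, contig: str = "chr1") -> IntervalBlock:
    return IntervalBlock(contig, start, end)
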