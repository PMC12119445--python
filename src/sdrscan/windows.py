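"""Sliding-window construction shared by the scan and repeat modules."""
from __future__ import annotations

from typing import NamedTuple

from .errors import ParameterError


class Window(NamedTuple):
    """Half-open genomic window [start, end) on ``contig``."""

    contig: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def make_windows(contig_length: int, width: int = 50_000, step: int = 25_000,
                 contig: str = "") -> list[Window]:
    """Tile ``[0, contig_length)`` with windows of ``width`` every ``step`` bp.

    The final window is truncated at the contig end and never extends past
    it; once a window reaches the end no further (fully redundant) windows
    are emitted.  With ``width=50_000, step=25_000`` a 100 kbp contig yields
    [0,50000), [25000,75000), [50000,100000).
    """
    if step <= 0:
        raise ParameterError("step must be > 0")
    if width < step:
        raise ParameterError("window width must be >= step")
    if contig_length <= 0:
        raise ParameterError("contig_length must be > 0")
    out: list[Window] = []
    start = 0
    while True:
        end = min(start + width, contig_length)
        out.append(Window(contig, start, end))
        if end >= contig_length:
            break
        start += step
    return out
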