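"""Genomic interval primitives and region-string parsing.

All internal coordinates are 0-based half-open, the BED convention. Region
strings such as ``"scaffold51_21:137857-138267"`` follow the samtools
convention (1-based, inclusive on both ends) and are converted on parse.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

_REGION_RE = re.compile(r"^(?P<scaffold>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a scaffold.

    strand is ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    scaffold: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.scaffold}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one base."""
        return (
            self.scaffold == other.scaffold
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start <= other.start
            and other.end <= self.end
        )

    def to_region_string(self) -> str:
        """Render as a 1-based inclusive region string."""
        return f"{self.scaffold}:{self.start + 1}-{self.end}"


def parse_region(region: str, strand: str = ".") -> GenomicInterval:
    """Parse a 1-based inclusive region string into a half-open interval.

    >>> parse_region("scaffold51_21:137857-138267")
    GenomicInterval(scaffold='scaffold51_21', start=137856, end=138267, strand='.')
    """
    m = _REGION_RE.match(region.strip())
    if m is None:
        raise ValueError(f"cannot parse region string {region!r}")
    start1 = int(m.group("start"))
    end1 = int(m.group("end"))
    if start1 < 1 or end1 < start1:
        raise ValueError(f"region {region!r}: require 1 <= start <= end")
    return GenomicInterval(m.group("scaffold"), start1 - 1, end1, strand)
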