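"""Genomic intervals and coordinate-dialect conversion.

Internal convention everywhere in this package: 1-based, fully-closed
intervals, identical to SAM/GTF coordinates. BED is 0-based half-open;
the two converters below are mutual inverses and round-trip losslessly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

STRANDS = {"+", "-", ".", "unknown"}

_REGION_RE = re.compile(r"^([^:]+):([\d,]+)(?:-([\d,]+))?$")


class CoordinateError(ValueError):
    """Invalid genomic coordinates (negative, inverted, or malformed)."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise CoordinateError(
                f"coordinates must be positive, got [{self.start}, {self.end}]"
            )
        if self.start > self.end:
            raise CoordinateError(f"start {self.start} > end {self.end}")
        if self.strand not in STRANDS:
            raise CoordinateError(f"strand must be one of {sorted(STRANDS)}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def to_bed(self) -> tuple[str, int, int]:
        """(chrom, start, end) in BED 0-based half-open coordinates."""
        return (self.chrom, self.start - 1, self.end)

    @classmethod
    def from_bed(
        cls, chrom: str, start: int, end: int, strand: str = "."
    ) -> "GenomicInterval":
        if start < 0:
            raise CoordinateError(f"negative BED start {start}")
        if end <= start:
            raise CoordinateError(f"empty/inverted BED interval [{start}, {end})")
        return cls(chrom, start + 1, end, strand)

    def to_sam(self) -> tuple[str, int, int]:
        """(chrom, start, end), 1-based inclusive — identical to internal."""
        return (self.chrom, self.start, self.end)

    @classmethod
    def from_sam(
        cls, chrom: str, start: int, end: int, strand: str = "."
    ) -> "GenomicInterval":
        return cls(chrom, start, end, strand)


def convert_coordinates(
    interval: GenomicInterval, dialect: str
) -> tuple[str, int, int]:
    """Express ``interval`` in the named dialect.

    ``bed`` → 0-based half-open, ``sam``/``internal`` → 1-based inclusive.
    """
    if dialect == "bed":
        return interval.to_bed()
    if dialect in ("sam", "internal"):
        return interval.to_sam()
    raise ValueError(f"unknown coordinate dialect {dialect!r}")


def parse_point(text: str) -> tuple[str, int]:
    """Parse ``chrom:pos`` (commas in the position are ignored)."""
    m = _REGION_RE.match(text.strip())
    if not m or m.group(3) is not None:
        raise CoordinateError(f"expected chrom:pos, got {text!r}")
    return m.group(1), int(m.group(2).replace(",", ""))


def parse_region(text: str, strand: str = ".") -> GenomicInterval:
    """Parse ``chrom:start-end`` (1-based inclusive, commas ignored)."""
    m = _REGION_RE.match(text.strip())
    if not m or m.group(3) is None:
        raise CoordinateError(f"expected chrom:start-end, got {text!r}")
    return GenomicInterval(
        m.group(1),
        int(m.group(2).replace(",", "")),
        int(m.group(3).replace(",", "")),
        strand,
    )
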