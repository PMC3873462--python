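"""Amplicon region model: exon/intron segmentation and reading frame.

The amplicon studied here spans the end of one exon, a complete intron and
the start of the next exon.  Coordinates are 0-based half-open in amplicon
space; ``frame_offset`` gives the codon phase of the first exonic base
(0 means the first exonic base starts a codon).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

EXON = "exon"
INTRON = "intron"


@dataclass(frozen=True)
class Segment:
    label: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.label not in (EXON, INTRON):
            raise ValueError(f"segment label must be 'exon' or 'intron', got {self.label!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid segment bounds [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class RegionSpec:
    """Ordered, contiguous exon/intron segmentation of an amplicon."""

    segments: tuple[Segment, ...]
    frame_offset: int = 0

    def __post_init__(self) -> None:
        segs = tuple(
            s if isinstance(s, Segment) else Segment(*s) for s in self.segments
        )
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ValueError("RegionSpec needs at least one segment")
        if segs[0].start != 0:
            raise ValueError("segments must start at 0")
        for a, b in zip(segs, segs[1:]):
            if a.end != b.start:
                raise ValueError("segments must be contiguous and sorted")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError("frame_offset must be 0, 1 or 2")

    @property
    def length(self) -> int:
        return self.segments[-1].end

    def __len__(self) -> int:
        return self.length

    def columns(self, label: str) -> list[int]:
        """All amplicon columns belonging to segments with ``label``."""
        return [i for s in self.segments if s.label == label for i in range(s.start, s.end)]

    @property
    def exon_columns(self) -> list[int]:
        return self.columns(EXON)

    @property
    def intron_columns(self) -> list[int]:
        return self.columns(INTRON)

    def iter_segments(self) -> Iterator[Segment]:
        return iter(self.segments)


def default_region(length: int = 200) -> RegionSpec:
    """Exon / intron / exon split emulating a ~200 bp amplicon that covers
    the tail of one exon, a full intron and the head of the next exon."""
    if length < 9:
        raise ValueError("amplicon too short for a three-segment region")
    a = length // 4           # end of first exon
    b = length - length // 3  # start of second exon
    return RegionSpec(
        segments=(
            Segment(EXON, 0, a),
            Segment(INTRON, a, b),
            Segment(EXON, b, length),
        ),
        frame_offset=0,
    )
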