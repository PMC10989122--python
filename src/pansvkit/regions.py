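"""Genome layout and interval primitives.

All coordinates inside the package are 0-based, half-open. Conversions to
and from 1-based formats (VCF, GFF3) happen only in :mod:`pansvkit.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and their lengths in base pairs."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self):
        if len(self.names) != len(set(self.names)):
            raise ValueError("chromosome names must be unique")
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")
        if any(l < 1 for l in self.lengths):
            raise ValueError("chromosome lengths must be >= 1")

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "GenomeLayout":
        return cls(tuple(d.keys()), tuple(int(v) for v in d.values()))

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.names, self.lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[self.names.index(chrom)]
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    @classmethod
    def read_tsv(cls, path) -> "GenomeLayout":
        names, lengths = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, length = line.split("\t")[:2]
                names.append(name)
                lengths.append(int(length))
        return cls(tuple(names), tuple(lengths))

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in zip(self.names, self.lengths):
                fh.write(f"{name}\t{length}\n")


@dataclass(frozen=True)
class Interval:
    """0-based half-open genomic span."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return overlap_bp(self.start, self.end, other.start, other.end)

    def contains(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def overlap_bp(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Overlap in bp between two half-open ranges on the same sequence."""
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def merge_ranges(ranges) -> list[tuple[int, int]]:
    """Merge possibly overlapping (start, end) half-open ranges.

    Touching ranges (end == next start) are merged; returns sorted output.
    """
    rs = sorted((int(s), int(e)) for s, e in ranges)
    merged: list[list[int]] = []
    for s, e in rs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def merged_overlap(start: int, end: int, ranges) -> int:
    """Total bp of [start, end) covered by the union of the given ranges."""
    total = 0
    for s, e in merge_ranges(ranges):
        total += overlap_bp(start, end, s, e)
    return total


def tile_windows(length: int, window: int, step: int | None = None):
    """Full tiling windows over [0, length).

    With ``step == window`` this is a non-overlapping tiling where the last
    partial window is kept; with ``step < window`` a sliding scan over full
    windows only (matching the (L - w)/s + 1 convention), falling back to a
    single truncated window when the sequence is shorter than the window.
    """
    if window <= 0 or (step is not None and step <= 0):
        raise ValueError("window and step must be positive")
    if step is None:
        step = window
    out = []
    if step == window:
        start = 0
        while start < length:
            out.append((start, min(start + window, length)))
            start += window
        return out
    if length < window:
        return [(0, length)]
    start = 0
    while start + window <= length:
        out.append((start, start + window))
        start += step
    return out
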