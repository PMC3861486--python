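"""Per-chromosome interval sets for BED-style overlap queries.

Intervals are stored 1-based inclusive; BED rows (0-based half-open) are
converted on load.  Queries ask whether a reference span shares at least
one base with any interval.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field


@dataclass
class GenomeIntervals:
    """Merged, sorted intervals keyed by chromosome."""

    _by_chrom: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, intervals: list[tuple[str, int, int]]) -> "GenomeIntervals":
        """Build from (chrom, start, end) 1-based inclusive triples."""
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start > end:
                raise ValueError(f"reversed interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end))
        merged: dict[str, list[tuple[int, int]]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            out = [ivs[0]]
            for s, e in ivs[1:]:
                ps, pe = out[-1]
                if s <= pe + 1:
                    out[-1] = (ps, max(pe, e))
                else:
                    out.append((s, e))
            merged[chrom] = out
        return cls(merged)

    @classmethod
    def from_bed_rows(cls, rows: list[tuple[str, int, int]]) -> "GenomeIntervals":
        """Build from BED rows (0-based half-open)."""
        return cls.from_intervals([(c, s + 1, e) for c, s, e in rows if e > s])

    def overlaps(self, chrom: str, start: int, end: int | None = None) -> bool:
        """Does [start, end] (1-based inclusive) share a base with any interval?"""
        if end is None:
            end = start
        ivs = self._by_chrom.get(chrom)
        if not ivs:
            return False
        i = bisect_right(ivs, (end, float("inf")))
        # candidate intervals start at or before `end`; check the closest one
        return i > 0 and ivs[i - 1][1] >= start

    def overlaps_span(self, chrom: str, pos: int, ref: str) -> bool:
        """Overlap against a variant's reference footprint."""
        return self.overlaps(chrom, pos, pos + len(ref) - 1)

    def to_bed_rows(self) -> list[tuple[str, int, int]]:
        return [
            (chrom, s - 1, e)
            for chrom in sorted(self._by_chrom)
            for s, e in self._by_chrom[chrom]
        ]

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())
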