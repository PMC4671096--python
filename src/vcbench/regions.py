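"""Region algebra for the evaluation territory.

The benchmark is only meaningful where the gold standard asserts both variants
and homozygous-reference positions confidently, further restricted to the
capture territory of the exome kit.  This module holds that territory as a
set of merged, disjoint, sorted 0-based half-open intervals and restricts
callsets to it.

A variant is kept only if its whole reference span lies inside one interval;
a deletion hanging off a region edge is dropped rather than scored against
truth that may have been clipped at the same edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TypeVar

import numpy as np

from .variant_model import GenomicInterval, read_bed_intervals

_V = TypeVar("_V")  # anything with .chrom, .pos (1-based) and .ref


class RegionSet:
    """Merged, disjoint, sorted genomic intervals with O(log n) queries."""

    def __init__(self, intervals: Iterable[GenomicInterval] = (), label: str = "") -> None:
        self.label = label
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        # merge overlapping and adjacent intervals per contig
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, ivs in per_chrom.items():
            ivs.sort()
            merged: list[tuple[int, int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    if e > merged[-1][1]:
                        merged[-1] = (merged[-1][0], e)
                else:
                    merged.append((s, e))
            self._starts[chrom] = np.asarray([s for s, _ in merged], dtype=np.int64)
            self._ends[chrom] = np.asarray([e for _, e in merged], dtype=np.int64)

    # -- container protocol -------------------------------------------------

    @property
    def intervals(self) -> list[GenomicInterval]:
        out = []
        for chrom in sorted(self._starts):
            for s, e in zip(self._starts[chrom], self._ends[chrom]):
                out.append(GenomicInterval(chrom, int(s), int(e)))
        return out

    def __len__(self) -> int:
        return sum(len(s) for s in self._starts.values())

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"RegionSet({len(self)} intervals, {self.covered_length()} bp{', ' + self.label if self.label else ''})"

    # -- queries ------------------------------------------------------------

    def covered_length(self) -> int:
        """Total bases covered (the TN universe before truth subtraction)."""
        return int(sum((self._ends[c] - self._starts[c]).sum() for c in self._starts))

    def contains_span(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) is fully inside one interval (0-based, half-open)."""
        starts = self._starts.get(chrom)
        if starts is None or len(starts) == 0:
            return False
        i = int(np.searchsorted(starts, start, side="right")) - 1
        return i >= 0 and end <= int(self._ends[chrom][i])

    def contains_point(self, chrom: str, point: int) -> bool:
        return self.contains_span(chrom, point, point + 1)

    # -- algebra ------------------------------------------------------------

    def intersect(self, other: "RegionSet") -> "RegionSet":
        """Exact interval intersection; result merged and sorted."""
        out: list[GenomicInterval] = []
        for chrom in self._starts:
            if chrom not in other._starts:
                continue
            a = list(zip(self._starts[chrom], self._ends[chrom]))
            b = list(zip(other._starts[chrom], other._ends[chrom]))
            i = j = 0
            while i < len(a) and j < len(b):
                s = max(a[i][0], b[j][0])
                e = min(a[i][1], b[j][1])
                if s < e:
                    out.append(GenomicInterval(chrom, int(s), int(e)))
                if a[i][1] <= b[j][1]:
                    i += 1
                else:
                    j += 1
        label = " ∩ ".join(x for x in (self.label, other.label) if x)
        return RegionSet(out, label=label)


def intersect(a: RegionSet, b: RegionSet) -> RegionSet:
    return a.intersect(b)


def covered_length(a: RegionSet) -> int:
    return a.covered_length()


def read_bed(path: str | Path, label: str = "") -> RegionSet:
    """Read a 3+ column BED into a merged, sorted RegionSet."""
    return RegionSet(read_bed_intervals(path), label=label or str(path))


def write_bed(regions: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in regions.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def restrict_variants(
    variants: Iterable[_V], territory: RegionSet
) -> tuple[list[_V], int]:
    """Keep variants whose reference span [pos-1, pos-1+len(ref)) lies fully
    inside the territory; return (kept, n_dropped)."""
    kept: list[_V] = []
    dropped = 0
    for v in variants:
        start = v.pos - 1
        if territory.contains_span(v.chrom, start, start + len(v.ref)):
            kept.append(v)
        else:
            dropped += 1
    return kept, dropped
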