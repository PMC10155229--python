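"""Genomic interval types and region algebra.

All coordinates are 0-based half-open (BED convention). Any 1-based
external convention is converted exactly once at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "CandidateRegion",
    "RegionTree",
    "filter_blacklist",
    "merge_group_peaks",
    "merge_intervals",
    "derive_dip_regions",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."
    summit: int | None = None  # narrowPeak column 10 offset, when present

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Half-open overlap: book-ended intervals do not overlap."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def _sort_key(iv: GenomicInterval) -> tuple[str, int, int]:
    return (iv.chrom, iv.start, iv.end)


@dataclass
class PeakSet:
    """An ordered collection of intervals from one sample group and assay."""

    intervals: list[GenomicInterval]
    group: str = ""
    assay: str = ""
    source_path: str = ""

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=_sort_key)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)


@dataclass(frozen=True)
class CandidateRegion:
    """A region entering affinity scoring: a source peak or a dip between peaks."""

    interval: GenomicInterval
    origin: str  # "peak" or "dip"
    assay: str = ""
    pairing: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        if self.origin not in {"peak", "dip"}:
            raise ValueError(f"origin must be 'peak' or 'dip', got {self.origin!r}")


class RegionTree:
    """Per-chromosome balanced interval search structure.

    query(iv) returns exactly the stored intervals overlapping iv under
    half-open semantics, in O(log n + k).
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self.size = 0
        for iv in intervals:
            self.insert(iv)

    def insert(self, iv: GenomicInterval) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
        self.size += 1

    def query(self, q: GenomicInterval) -> list[GenomicInterval]:
        tree = self._trees.get(q.chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(q.start, q.end)]
        return sorted(hits, key=_sort_key)

    def any_overlap(self, q: GenomicInterval) -> bool:
        tree = self._trees.get(q.chrom)
        return bool(tree is not None and tree.overlaps(q.start, q.end))


def filter_blacklist(peaks: PeakSet, blacklist: PeakSet) -> PeakSet:
    """Drop every peak overlapping (>= 1 bp) any blacklist interval.

    Half-open semantics: a peak that merely touches a blacklist interval
    end-to-start is kept. Order of the survivors is preserved.
    """
    if not blacklist.intervals:
        return PeakSet(list(peaks.intervals), peaks.group, peaks.assay, peaks.source_path)
    tree = RegionTree(blacklist.intervals)
    kept = [iv for iv in peaks.intervals if not tree.any_overlap(iv)]
    return PeakSet(kept, peaks.group, peaks.assay, peaks.source_path)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Coalesce overlapping or book-ended intervals into a sorted, disjoint set."""
    ivs = sorted(intervals, key=_sort_key)
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def merge_group_peaks(peak_sets: Sequence[PeakSet]) -> PeakSet:
    """Union replicate peak files of one sample group into a canonical set.

    Overlapping or book-ended intervals coalesce; the result is sorted and
    non-overlapping. All inputs must share group and assay labels.
    """
    if not peak_sets:
        raise ValueError("no peak sets to merge")
    groups = {ps.group for ps in peak_sets}
    assays = {ps.assay for ps in peak_sets}
    if len(groups) > 1:
        raise ValueError(f"mixed group labels: {sorted(groups)}")
    if len(assays) > 1:
        raise ValueError(f"mixed assay labels: {sorted(assays)}")
    merged = merge_intervals(iv for ps in peak_sets for iv in ps.intervals)
    return PeakSet(merged, peak_sets[0].group, peak_sets[0].assay)


def derive_dip_regions(
    peaks: PeakSet,
    dip_max_gap: int = 500,
    dip_mode: str = "add",
    pairing: str = "",
) -> list[CandidateRegion]:
    """Derive scoring regions from merged peaks, including peak-dip-peak gaps.

    Histone-mark peaks often flank, rather than cover, the regulatory
    element: the accessible "dip" sits between two nearby peaks. For each
    adjacent same-chromosome peak pair whose gap is between 1 and
    ``dip_max_gap`` bp, the gap [end_i, start_{i+1}) is emitted as a dip
    region.

    dip_mode: "add" emits peaks and dips, "replace" emits dips only,
    "off" emits peaks only.
    """
    if dip_mode not in {"add", "replace", "off"}:
        raise ValueError(f"invalid dip_mode {dip_mode!r}")
    out: list[CandidateRegion] = []
    if dip_mode in {"add", "off"}:
        out.extend(
            CandidateRegion(iv, "peak", peaks.assay, pairing, peaks.group)
            for iv in peaks.intervals
        )
    if dip_mode == "off":
        return out
    ivs = peaks.intervals
    for prev, nxt in zip(ivs, ivs[1:]):
        if prev.chrom != nxt.chrom:
            continue
        gap = nxt.start - prev.end
        if 1 <= gap <= dip_max_gap:
            dip = GenomicInterval(prev.chrom, prev.end, nxt.start)
            out.append(CandidateRegion(dip, "dip", peaks.assay, pairing, peaks.group))
    out.sort(key=lambda c: _sort_key(c.interval))
    return out
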