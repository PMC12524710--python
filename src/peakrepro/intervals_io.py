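"""Genomic-interval data model, BED/narrowPeak I/O, and interval algebra.

Coordinates are 0-based half-open throughout (BED convention): an interval
``(chrom, start, end)`` covers bases ``start .. end-1``. Two intervals overlap
when they share at least one base; book-ended intervals (gap of exactly 0)
do *not* overlap but *do* merge under the default ``gap=0`` merge policy,
matching the behaviour of ``bedtools merge``.

Peaks are unstranded. ``pvalue`` is the peak caller's significance, stored as
a plain probability in (0, 1]; the narrowPeak dialect stores it as −log10(p)
in column 8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "read_narrowpeak",
    "write_bed",
    "merge_intervals",
    "overlaps",
    "intersects_any",
    "coverage",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval with optional score and p-value."""

    chrom: str
    start: int
    end: int
    pvalue: float | None = None
    score: float | None = None
    name: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.pvalue is not None and not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"pvalue outside (0, 1]: {self.pvalue}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class PeakSet:
    """One replicate's called peaks, kept sorted by (chrom, start, end)."""

    replicate_id: str
    peaks: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.key)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


def _parse_line(line: str, lineno: int, path: str) -> GenomicInterval:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
    try:
        chrom = fields[0]
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: malformed coordinates") from exc
    if end <= start or start < 0:
        raise ValueError(f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}")
    name = fields[3] if len(fields) > 3 and fields[3] else "."
    score = None
    if len(fields) > 4 and fields[4] not in (".", ""):
        score = float(fields[4])
    pvalue = None
    # narrowPeak: col 8 (index 7) is −log10 p-value; -1 means unavailable
    if len(fields) >= 8 and fields[7] not in (".", ""):
        neglog = float(fields[7])
        if neglog >= 0:
            pvalue = 10.0 ** (-neglog)
    return GenomicInterval(chrom, start, end, pvalue=pvalue, score=score, name=name)


def read_narrowpeak(path: str | Path, replicate_id: str | None = None) -> PeakSet:
    """Read a BED3/BED6/narrowPeak file into a :class:`PeakSet`.

    Column count is auto-detected per line. In the 10-column narrowPeak
    dialect, column 8 carries −log10(p) and is converted to a probability.
    Empty files yield an empty peak set.
    """
    path = Path(path)
    peaks: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            peaks.append(_parse_line(line, lineno, str(path)))
    return PeakSet(replicate_id=replicate_id or path.stem, peaks=peaks)


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED, choosing the richest dialect the data needs.

    If any interval carries a p-value the 10-column narrowPeak layout is
    used (−log10 p in column 8, -1 in the unused signal/q columns); otherwise
    BED6 when scores are present, else BED3. Output is coordinate-sorted so
    ``read_narrowpeak`` round-trips it exactly.
    """
    ivs = sorted(intervals, key=lambda p: p.key)
    has_p = any(iv.pvalue is not None for iv in ivs)
    has_score = any(iv.score is not None for iv in ivs)
    with open(path, "w") as fh:
        for iv in ivs:
            if has_p:
                # 7 decimals so p-values round-trip to <1e-6 relative error
                neglog = f"{-math.log10(iv.pvalue):.7f}" if iv.pvalue is not None else "-1"
                score = iv.score if iv.score is not None else 0
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score:g}\t.\t"
                    f"-1\t{neglog}\t-1\t-1\n"
                )
            elif has_score:
                score = iv.score if iv.score is not None else 0
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score:g}\t.\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals share at least one base."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose overlap or separation is at most ``gap`` bases.

    ``gap=0`` (default) merges overlapping and book-ended intervals, so the
    output is pairwise non-overlapping, non-adjacent, and covers exactly the
    same bases as the input. Input order is irrelevant.
    """
    if gap < 0:
        raise ValueError(f"negative gap: {gap}")
    ivs = sorted(intervals, key=lambda p: p.key)
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start - merged[-1].end <= gap:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


class _SortedTrack:
    """Merged, per-chromosome sorted view of a track for fast hit queries."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self._by_chrom: dict[str, tuple[list[int], list[int]]] = {}
        for iv in merge_intervals(intervals, gap=0):
            starts, ends = self._by_chrom.setdefault(iv.chrom, ([], []))
            starts.append(iv.start)
            ends.append(iv.end)

    def hits(self, iv: GenomicInterval) -> bool:
        import bisect

        entry = self._by_chrom.get(iv.chrom)
        if entry is None:
            return False
        starts, ends = entry
        # first track interval with end > iv.start
        i = bisect.bisect_right(ends, iv.start)
        return i < len(starts) and starts[i] < iv.end


def intersects_any(
    intervals: Sequence[GenomicInterval], track: Sequence[GenomicInterval]
) -> list[bool]:
    """For each query interval, whether it overlaps >=1 track interval."""
    st = _SortedTrack(track)
    return [st.hits(iv) for iv in intervals]


def coverage(intervals: Iterable[GenomicInterval]) -> set[tuple[str, int]]:
    """The set of (chrom, base) positions covered; intended for small inputs."""
    out: set[tuple[str, int]] = set()
    for iv in intervals:
        for pos in range(iv.start, iv.end):
            out.add((iv.chrom, pos))
    return out


def coverage_is_subset(
    inner: Iterable[GenomicInterval], outer: Iterable[GenomicInterval]
) -> bool:
    """Whether every base covered by ``inner`` is also covered by ``outer``.

    Interval-resolution check (no per-base expansion), safe for Mb genomes.
    """
    out_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merge_intervals(outer, gap=0):
        out_by_chrom.setdefault(iv.chrom, []).append(iv)
    for iv in merge_intervals(inner, gap=0):
        track = out_by_chrom.get(iv.chrom, [])
        # iv must lie inside a single merged outer interval
        if not any(o.start <= iv.start and iv.end <= o.end for o in track):
            return False
    return True
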