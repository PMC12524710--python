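"""Priority-based genomic annotation and external-track overlap summaries.

Each peak receives exactly one category, the highest-priority feature class
it overlaps by >=1 base, in the fixed order::

    Promoter > 5'UTR > 3'UTR > Exon > Intron > Downstream > Distal Intergenic

Promoters are TSS-centred windows (default −1 kb .. +1 kb); the TSS is the
transcript start on the + strand and the last transcribed base on the −
strand. Downstream extends a configurable distance past the transcription
end on the strand-appropriate side. Peaks overlapping no feature of any
transcript are Distal Intergenic.

The gene model is file-based (BED12: blocks = exons, thick = CDS), keeping
the annotation self-contained and strand-aware.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Iterable, Sequence

from .intervals_io import GenomicInterval, intersects_any

__all__ = [
    "Transcript",
    "GeneModel",
    "AnnotatedPeak",
    "CATEGORIES",
    "read_bed12",
    "annotate",
    "category_proportions",
    "overlap_fraction",
]

CATEGORIES = (
    "Promoter",
    "5'UTR",
    "3'UTR",
    "Exon",
    "Intron",
    "Downstream",
    "Distal Intergenic",
)


@dataclass(frozen=True)
class Transcript:
    chrom: str
    tx_start: int
    tx_end: int
    strand: str  # '+' or '-'
    cds_start: int
    cds_end: int
    exons: tuple[tuple[int, int], ...]  # sorted, non-overlapping, absolute coords

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError("CDS outside transcript bounds")
        prev_end = self.tx_start
        for s, e in self.exons:
            if s < prev_end or e <= s or e > self.tx_end:
                raise ValueError("exon blocks must be sorted, disjoint, in-bounds")
            prev_end = e

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def coding(self) -> bool:
        return self.cds_end > self.cds_start


@dataclass
class GeneModel:
    transcripts: list[Transcript]


@dataclass(frozen=True)
class AnnotatedPeak:
    interval: GenomicInterval
    category: str


def read_bed12(path: str | Path) -> GeneModel:
    """Parse a BED12 gene model (blocks = exons, thick region = CDS)."""
    txs: list[Transcript] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 needs 12 columns")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            strand = f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                (start + o, start + o + s) for o, s in zip(offsets, sizes)
            )
            txs.append(
                Transcript(chrom, start, end, strand, thick_start, thick_end, exons)
            )
    return GeneModel(transcripts=txs)


def _clip(start: int, end: int) -> tuple[int, int] | None:
    start = max(start, 0)
    return (start, end) if end > start else None


def _feature_intervals(
    genes: GeneModel, promoter_up: int, promoter_down: int, downstream_len: int
) -> dict[str, list[GenomicInterval]]:
    feats: dict[str, list[GenomicInterval]] = {c: [] for c in CATEGORIES[:-1]}

    def add(cat: str, chrom: str, start: int, end: int) -> None:
        span = _clip(start, end)
        if span:
            feats[cat].append(GenomicInterval(chrom, span[0], span[1]))

    for tx in genes.transcripts:
        if tx.strand == "+":
            add("Promoter", tx.chrom, tx.tx_start - promoter_up, tx.tx_start + promoter_down)
            add("Downstream", tx.chrom, tx.tx_end, tx.tx_end + downstream_len)
        else:
            add("Promoter", tx.chrom, tx.tx_end - promoter_down, tx.tx_end + promoter_up)
            add("Downstream", tx.chrom, tx.tx_start - downstream_len, tx.tx_start)
        for s, e in tx.exons:
            add("Exon", tx.chrom, s, e)
            if tx.coding:
                # exonic bases before/after the CDS are UTR, by strand
                left = _clip(s, min(e, tx.cds_start))
                right = _clip(max(s, tx.cds_end), e)
                five, three = (left, right) if tx.strand == "+" else (right, left)
                if five:
                    add("5'UTR", tx.chrom, *five)
                if three:
                    add("3'UTR", tx.chrom, *three)
        prev = None
        for s, e in tx.exons:
            if prev is not None and s > prev:
                add("Intron", tx.chrom, prev, s)
            prev = e
    return feats


def annotate(
    peaks: Sequence[GenomicInterval],
    genes: GeneModel,
    promoter_up: int = 1000,
    promoter_down: int = 1000,
    downstream_len: int = 3000,
) -> list[AnnotatedPeak]:
    """Assign each peak its highest-priority overlapping feature category."""
    if not genes.transcripts:
        warnings.warn("empty gene model: all peaks annotated Distal Intergenic")
        return [AnnotatedPeak(p, "Distal Intergenic") for p in peaks]
    feats = _feature_intervals(genes, promoter_up, promoter_down, downstream_len)
    hit_masks = {
        cat: intersects_any(peaks, ivs) for cat, ivs in feats.items() if ivs
    }
    out: list[AnnotatedPeak] = []
    for i, p in enumerate(peaks):
        category = "Distal Intergenic"
        for cat in CATEGORIES[:-1]:
            if cat in hit_masks and hit_masks[cat][i]:
                category = cat
                break
        out.append(AnnotatedPeak(p, category))
    return out


def category_proportions(
    annotated: Sequence[AnnotatedPeak],
    group_keys: Sequence[Hashable] | None = None,
) -> dict[Hashable, dict[str, float]]:
    """Per-group category fractions (each group's fractions sum to 1).

    ``group_keys`` aligns with ``annotated`` (e.g. each peak's replicate
    support); when omitted all peaks form a single group keyed ``"all"``.
    """
    if group_keys is None:
        group_keys = ["all"] * len(annotated)
    groups: dict[Hashable, list[str]] = {}
    for ap, g in zip(annotated, group_keys):
        groups.setdefault(g, []).append(ap.category)
    out: dict[Hashable, dict[str, float]] = {}
    for g, cats in groups.items():
        if not cats:
            warnings.warn(f"group {g!r} is empty; excluded")
            continue
        out[g] = {c: cats.count(c) / len(cats) for c in CATEGORIES if c in cats}
    return out


def overlap_fraction(
    peaks: Sequence[GenomicInterval], track: Iterable[GenomicInterval]
) -> float:
    """Fraction of peaks overlapping at least one track interval."""
    if not peaks:
        raise ValueError("overlap fraction of an empty peak set")
    hits = intersects_any(peaks, list(track))
    return sum(hits) / len(peaks)
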