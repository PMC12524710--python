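"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own interval algebra: everything is
computed per-base on small toy genomes, or by exhaustive enumeration.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from peakrepro.intervals_io import GenomicInterval, PeakSet


def per_base_consensus(
    replicates: list[PeakSet], chrom_lengths: dict[str, int]
) -> list[tuple[str, int, int, int]]:
    """Per-base sweep: mark each base with its covering replicates, take
    maximal runs of covered bases, count replicates touching each run.

    Returns (chrom, start, end, support) tuples, sorted.
    """
    out: list[tuple[str, int, int, int]] = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        cover = np.zeros((len(replicates), length), dtype=bool)
        for i, rep in enumerate(replicates):
            for p in rep.peaks:
                if p.chrom == chrom:
                    cover[i, p.start : p.end] = True
        covered = cover.any(axis=0)
        pos = 0
        while pos < length:
            if not covered[pos]:
                pos += 1
                continue
            end = pos
            while end < length and covered[end]:
                end += 1
            support = int(sum(cover[i, pos:end].any() for i in range(len(replicates))))
            out.append((chrom, pos, end, support))
            pos = end
    return out


def per_base_merge(
    intervals: list[GenomicInterval], chrom_lengths: dict[str, int]
) -> list[tuple[str, int, int]]:
    """Covered-base runs of a single interval collection (gap=0 merge oracle
    up to book-ended joins, which add no covered bases)."""
    fake = [PeakSet("x", intervals)]
    return [(c, s, e) for c, s, e, _ in per_base_consensus(fake, chrom_lengths)]


def fisher_closed_form_m2(p1: float, p2: float) -> float:
    """Fisher combination for exactly two p-values: chi-square df=4 upper
    tail has the closed form e^(−X²/2)·(1 + X²/2)."""
    x2 = -2.0 * (math.log(p1) + math.log(p2))
    return math.exp(-x2 / 2.0) * (1.0 + x2 / 2.0)


def rank_product_pvalue_enum(observed_rp: float, m: int, n: int) -> float:
    """P(RP <= observed) by exhaustive enumeration over all M^N rank tuples
    (each replicate's rank uniform on 1..M under the null)."""
    total = 0
    count = 0
    for combo in itertools.product(range(1, m + 1), repeat=n):
        total += 1
        if math.prod(combo) <= observed_rp + 1e-12:
            count += 1
    return count / total
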