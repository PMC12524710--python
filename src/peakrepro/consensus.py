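"""Consensus regions and replicate support.

Given N replicate peak sets P_1..P_N, the universal set U = ∪ P_i is merged
into a non-overlapping set of consensus regions C = {C_1..C_M}. Each region
carries a support count s_j — the number of replicates with at least one peak
intersecting C_j — and, per supporting replicate, the smallest peak p-value
falling in the region (feeds the Fisher-combination strategy downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .intervals_io import GenomicInterval, PeakSet, merge_intervals

__all__ = [
    "ConsensusRegion",
    "ConsensusSet",
    "build_consensus",
    "support_distribution",
    "shared_by_k",
]


@dataclass
class ConsensusRegion:
    interval: GenomicInterval
    supporting_replicates: frozenset[str]
    member_pvalues: dict[str, float | None] = field(default_factory=dict)

    @property
    def support(self) -> int:
        return len(self.supporting_replicates)


@dataclass
class ConsensusSet:
    regions: list[ConsensusRegion]
    replicate_ids: list[str]

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_ids)

    def __len__(self) -> int:
        return len(self.regions)


def build_consensus(replicates: list[PeakSet]) -> ConsensusSet:
    """Merge the union of all replicates' peaks and count replicate support.

    A replicate supports a region if any of its peaks shares >=1 base with
    it; several peaks of one replicate hitting the same region count once,
    keeping that replicate's minimum p-value for the region. Every input
    peak maps to exactly one region (regions are the merge of the union).
    """
    if not replicates:
        raise ValueError("need at least one replicate peak set")
    ids = [r.replicate_id for r in replicates]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate replicate ids: {ids}")

    union = [p for r in replicates for p in r.peaks]
    merged = merge_intervals(union, gap=0)

    regions = [ConsensusRegion(iv, frozenset(), {}) for iv in merged]
    # index merged regions per chromosome for a linear sweep per replicate
    by_chrom: dict[str, list[int]] = {}
    for idx, reg in enumerate(regions):
        by_chrom.setdefault(reg.interval.chrom, []).append(idx)

    for rep in replicates:
        j = 0
        cur_chrom: str | None = None
        idxs: list[int] = []
        for peak in rep.peaks:  # sorted within replicate
            if peak.chrom != cur_chrom:
                cur_chrom = peak.chrom
                idxs = by_chrom.get(cur_chrom, [])
                j = 0
            # advance to the region containing this peak (peak lies fully
            # inside one merged region since regions merge the union)
            while j < len(idxs) and regions[idxs[j]].interval.end <= peak.start:
                j += 1
            if j >= len(idxs):  # pragma: no cover - cannot happen for union members
                raise AssertionError("peak outside every consensus region")
            reg = regions[idxs[j]]
            assert reg.interval.start <= peak.start and peak.end <= reg.interval.end
            prev = reg.member_pvalues.get(rep.replicate_id)
            if rep.replicate_id not in reg.member_pvalues:
                reg.member_pvalues[rep.replicate_id] = peak.pvalue
            elif peak.pvalue is not None and (prev is None or peak.pvalue < prev):
                reg.member_pvalues[rep.replicate_id] = peak.pvalue

    for reg in regions:
        reg.supporting_replicates = frozenset(reg.member_pvalues)
        assert reg.support >= 1
    return ConsensusSet(regions=regions, replicate_ids=ids)


def support_distribution(consensus: ConsensusSet) -> dict[int, float]:
    """Proportion of consensus regions supported by exactly k replicates."""
    if not consensus.regions:
        raise ValueError("support distribution of an empty consensus set")
    counts: dict[int, int] = {}
    for reg in consensus.regions:
        counts[reg.support] = counts.get(reg.support, 0) + 1
    total = len(consensus.regions)
    return {k: c / total for k, c in sorted(counts.items())}


def shared_by_k(consensus: ConsensusSet, k: int) -> list[ConsensusRegion]:
    """Regions supported by at least k of the N replicates."""
    if not (1 <= k <= consensus.n_replicates):
        raise ValueError(f"k={k} outside 1..{consensus.n_replicates}")
    return [reg for reg in consensus.regions if reg.support >= k]
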