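"""Reproducibility-measurement strategies over multi-replicate peak sets.

Five strategies, spanning the sensitivity/specificity spectrum:

* ``occurring_at_least_once`` — every consensus region (maximal sensitivity).
* ``shared_by_all`` — regions supported by all N replicates (maximal
  specificity). These two bracket every other method.
* ``mspc_like`` — rank regions by Fisher's combined p-value over the member
  peaks' p-values, rescuing weak-but-consistent signals; regions whose every
  member p-value is worse than a weak threshold are dropped as noise.
* ``rank_product`` — per-replicate p-value ranks multiplied across
  replicates; regions absent from a replicate are penalized with the worst
  rank. Significance is the null probability of an equal-or-smaller rank
  product under independent uniform ranks.
* ``pairwise_union`` — reproducible peaks from every replicate pair (scored
  by a pluggable pairwise rank-consistency scorer), unioned and merged.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .consensus import ConsensusSet
from .intervals_io import GenomicInterval, PeakSet, merge_intervals, overlaps

__all__ = [
    "RankedEntry",
    "RankedResult",
    "StrategyConfig",
    "occurring_at_least_once",
    "shared_by_all",
    "fisher_combine_pvalues",
    "mspc_like",
    "rank_product",
    "pairwise_union",
    "rank_discordance_scorer",
    "threshold_sweep",
    "default_thresholds",
]


@dataclass(frozen=True)
class RankedEntry:
    interval: GenomicInterval
    score: float
    rank: float


@dataclass
class RankedResult:
    """A strategy's scored and ranked output peaks."""

    strategy_name: str
    entries: list[RankedEntry]
    smaller_is_better: bool = True

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def intervals(self) -> list[GenomicInterval]:
        return [e.interval for e in self.entries]


@dataclass(frozen=True)
class StrategyConfig:
    """Tunable knobs shared across strategies.

    ``weak_threshold`` mirrors a peak caller's loose call threshold (1e-4):
    a region is noise if no member peak beats it. ``stringency_threshold``
    is the confident-call level (1e-8). ``idr_thresholds`` is the default
    sweep grid for the pairwise strategy.
    """

    min_overlap_replicates: int = 1
    stringency_threshold: float = 1e-8
    weak_threshold: float = 1e-4
    idr_thresholds: tuple[float, ...] = (1, 0.75, 0.5, 0.25, 0.1, 0.05, 0.01)

    def __post_init__(self) -> None:
        if self.stringency_threshold > self.weak_threshold:
            raise ValueError("stringency threshold must be <= weak threshold")
        for t in self.idr_thresholds:
            if not (0 < t <= 1):
                raise ValueError(f"idr threshold outside (0,1]: {t}")


def _ranked(name: str, intervals, scores, smaller_is_better: bool) -> RankedResult:
    scores = np.asarray(scores, dtype=float)
    order_scores = scores if smaller_is_better else -scores
    ranks = stats.rankdata(order_scores, method="average")
    entries = [
        RankedEntry(iv, float(s), float(r))
        for iv, s, r in zip(intervals, scores, ranks)
    ]
    entries.sort(key=lambda e: e.rank)
    return RankedResult(name, entries, smaller_is_better)


def occurring_at_least_once(consensus: ConsensusSet) -> RankedResult:
    """All consensus regions, scored by support (larger is better)."""
    ivs = [r.interval for r in consensus.regions]
    scores = [float(r.support) for r in consensus.regions]
    return _ranked("occurring_at_least_once", ivs, scores, smaller_is_better=False)


def shared_by_all(consensus: ConsensusSet) -> RankedResult:
    """Only regions supported by every replicate."""
    keep = [r for r in consensus.regions if r.support == consensus.n_replicates]
    return _ranked(
        "shared_by_all",
        [r.interval for r in keep],
        [float(r.support) for r in keep],
        smaller_is_better=False,
    )


def fisher_combine_pvalues(pvalues: Sequence[float]) -> float:
    """Fisher's method: X² = −2·Σ ln pᵢ ~ χ²(2m) under the global null."""
    ps = list(pvalues)
    if not ps:
        raise ValueError("no p-values to combine")
    for p in ps:
        if p is None or not (0.0 < p <= 1.0):
            raise ValueError(f"p-value outside (0, 1]: {p}")
    if len(ps) == 1:
        return float(ps[0])
    x2 = -2.0 * sum(math.log(p) for p in ps)
    return float(stats.chi2.sf(x2, df=2 * len(ps)))


def mspc_like(
    consensus: ConsensusSet, config: StrategyConfig = StrategyConfig()
) -> RankedResult:
    """Fisher-combination strategy over consensus regions.

    Regions supported by at least ``min_overlap_replicates`` are scored by
    the Fisher-combined p-value of their member peaks (one minimum p-value
    per supporting replicate); regions whose every member p-value exceeds
    the weak threshold are excluded as the noise class. Weak-but-consistent
    peaks thus survive through combination.
    """
    ivs: list[GenomicInterval] = []
    scores: list[float] = []
    for reg in consensus.regions:
        if reg.support < config.min_overlap_replicates:
            continue
        missing = [r for r, p in reg.member_pvalues.items() if p is None]
        if missing:
            raise ValueError(
                f"region {reg.interval.chrom}:{reg.interval.start}-"
                f"{reg.interval.end} lacks p-values for replicates {missing}"
            )
        ps = list(reg.member_pvalues.values())
        if all(p > config.weak_threshold for p in ps):
            continue  # noise class
        ivs.append(reg.interval)
        scores.append(fisher_combine_pvalues(ps))
    return _ranked("mspc_like", ivs, scores, smaller_is_better=True)


def replicate_rank_matrix(consensus: ConsensusSet) -> np.ndarray:
    """(M regions × N replicates) matrix of within-replicate p-value ranks.

    Regions a replicate supports are ranked 1..m_i by its member p-value
    (ascending, average ties); regions it did not call get the worst
    possible rank, M.
    """
    m, n = len(consensus.regions), consensus.n_replicates
    rank_matrix = np.full((m, n), float(m))
    for i, rep_id in enumerate(consensus.replicate_ids):
        idxs, ps = [], []
        for j, reg in enumerate(consensus.regions):
            p = reg.member_pvalues.get(rep_id)
            if p is not None:
                idxs.append(j)
                ps.append(p)
        if idxs:
            rank_matrix[idxs, i] = stats.rankdata(ps, method="average")
    return rank_matrix


def _null_rank_products(
    m: int, n: int, rng: np.random.Generator, max_exact: int = 10**6, draws: int = 10**5
) -> np.ndarray:
    """Null distribution of the rank product of n independent uniform ranks."""
    if m**n <= max_exact:
        grids = np.meshgrid(*([np.arange(1, m + 1)] * n), indexing="ij")
        prod = np.ones_like(grids[0], dtype=float)
        for g in grids:
            prod = prod * g
        return prod.ravel()
    ranks = rng.integers(1, m + 1, size=(draws, n)).astype(float)
    return ranks.prod(axis=1)


def rank_product(
    consensus: ConsensusSet,
    seed: int = 0,
    mc_draws: int = 10**5,
) -> RankedResult:
    """Rank-product strategy over consensus regions.

    Within each replicate, regions are ranked by that replicate's member
    p-value (ascending, average-rank ties); regions the replicate did not
    call get the worst possible rank M. The per-region rank product is
    converted to a significance score P(RP <= observed) under the null of
    independent uniform ranks — exhaustively when M^N is small, otherwise
    by seeded Monte-Carlo sampling.
    """
    n = consensus.n_replicates
    if n < 2:
        raise ValueError("rank product needs at least 2 replicates")
    m = len(consensus.regions)
    if m == 0:
        return RankedResult("rank_product", [], smaller_is_better=True)

    rank_matrix = replicate_rank_matrix(consensus)
    rp = rank_matrix.prod(axis=1)
    rng = np.random.default_rng(seed)
    null = np.sort(_null_rank_products(m, n, rng, draws=mc_draws))
    pvals = np.searchsorted(null, rp, side="right") / null.size

    ivs = [reg.interval for reg in consensus.regions]
    return _ranked("rank_product", ivs, pvals, smaller_is_better=True)


def rank_discordance_scorer(
    peak_a: GenomicInterval,
    peak_b: GenomicInterval,
    rank_a: float,
    rank_b: float,
    n_a: int,
    n_b: int,
) -> float:
    """Normalized within-replicate rank discordance of an intersecting pair.

    |r_A − r_B| / max(M_A, M_B) lies in [0, 1); 0 means the two replicates
    rank the shared signal identically (most reproducible). A lightweight
    rank-consistency score playing the role an irreproducible-discovery
    rate plays in pairwise frameworks.
    """
    return abs(rank_a - rank_b) / max(n_a, n_b)


PairScorer = Callable[[GenomicInterval, GenomicInterval, float, float, int, int], float]


def _pvalue_ranks(rep: PeakSet) -> dict[tuple[str, int, int], float]:
    ps = [p.pvalue if p.pvalue is not None else 1.0 for p in rep.peaks]
    ranks = stats.rankdata(ps, method="average") if ps else np.array([])
    return {p.key: float(r) for p, r in zip(rep.peaks, ranks)}


def pairwise_union(
    replicates: list[PeakSet],
    scorer: PairScorer = rank_discordance_scorer,
    threshold: float = 1.0,
) -> RankedResult:
    """Union-of-reproducible-pairs strategy.

    Every unordered replicate pair is examined; intersecting peak pairs are
    scored by ``scorer`` (smaller = more reproducible) and kept when their
    score is <= ``threshold``. Surviving peaks from all pairs are unioned
    and merged; each merged interval is scored by the best (minimum) pair
    score among its contributing peaks. Scores are for ranking only.
    """
    if len(replicates) < 2:
        raise ValueError("pairwise strategy needs at least 2 replicates")
    rank_of = {r.replicate_id: _pvalue_ranks(r) for r in replicates}

    best: dict[tuple[str, int, int], float] = {}
    survivors: dict[tuple[str, int, int], GenomicInterval] = {}
    for ra, rb in itertools.combinations(replicates, 2):
        ja = 0
        for pb in rb.peaks:
            # advance past peaks of ra entirely left of pb
            while ja < len(ra.peaks) and (
                ra.peaks[ja].chrom < pb.chrom
                or (ra.peaks[ja].chrom == pb.chrom and ra.peaks[ja].end <= pb.start)
            ):
                ja += 1
            k = ja
            while k < len(ra.peaks) and ra.peaks[k].chrom == pb.chrom and (
                ra.peaks[k].start < pb.end
            ):
                pa = ra.peaks[k]
                if overlaps(pa, pb):
                    s = scorer(
                        pa,
                        pb,
                        rank_of[ra.replicate_id][pa.key],
                        rank_of[rb.replicate_id][pb.key],
                        len(ra.peaks),
                        len(rb.peaks),
                    )
                    if s <= threshold:
                        for pk in (pa, pb):
                            if pk.key not in best or s < best[pk.key]:
                                best[pk.key] = s
                                survivors[pk.key] = pk
                k += 1

    merged = merge_intervals(survivors.values(), gap=0)
    # score of a merged interval = best score among the peaks inside it
    scores = []
    for iv in merged:
        member_scores = [
            best[k]
            for k in best
            if k[0] == iv.chrom and k[1] >= iv.start and k[2] <= iv.end
        ]
        scores.append(min(member_scores))
    return _ranked("pairwise_union", merged, scores, smaller_is_better=True)


def threshold_sweep(
    result: RankedResult, thresholds: Sequence[float]
) -> list[list[GenomicInterval]]:
    """Peak sets at each threshold; stricter thresholds give nested subsets.

    For smaller-is-better scores a peak passes threshold t when score <= t;
    for larger-is-better when score >= t.
    """
    sets: list[list[GenomicInterval]] = []
    for t in thresholds:
        if result.smaller_is_better:
            sets.append([e.interval for e in result.entries if e.score <= t])
        else:
            sets.append([e.interval for e in result.entries if e.score >= t])
    return sets


def default_thresholds(result: RankedResult, n: int | None = None) -> list[float]:
    """A sweep grid over the observed scores: every distinct score by
    default (exact curve), or ``n`` rank-evenly spaced ones."""
    if not result.entries:
        return [1.0]
    uniq = sorted({e.score for e in result.entries})
    if n is not None and len(uniq) > n:
        idx = np.unique(np.linspace(0, len(uniq) - 1, n).astype(int))
        uniq = [uniq[i] for i in idx]
    return uniq if result.smaller_is_better else uniq[::-1]
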