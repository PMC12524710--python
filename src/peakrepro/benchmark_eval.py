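"""Tiered pseudo-gold standard and precision/recall evaluation.

With no ground truth for in-vivo G4 peaks, a two-tier pseudo-gold standard
is built from the data itself plus external G4 evidence ("M of N"):

* **HC** (high confidence): consensus regions supported by at least
  ceil(2N/3) of the N replicates AND overlapping both a predicted-G4 (pG4)
  and an observed-G4 (oG4) track interval.
* **AN** (artifact noise): regions supported by exactly 1 replicate, or by
  exactly 2 replicates while missing pG4 or oG4 overlap.

A strategy's output is then scored: TP = HC regions recovered, FP = output
peaks hitting only AN, FN = HC regions missed. Peaks touching neither tier
are uninformative and ignored.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .consensus import ConsensusSet
from .intervals_io import GenomicInterval, intersects_any
from .strategies import RankedResult, threshold_sweep

__all__ = [
    "PseudoGold",
    "EvalMetrics",
    "PRCurve",
    "build_pseudo_gold",
    "classify",
    "pr_curve",
    "optimal_f1_peaks",
]


@dataclass
class PseudoGold:
    hc: list[GenomicInterval]
    an: list[GenomicInterval]
    n_replicates: int


@dataclass(frozen=True)
class EvalMetrics:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p > 0 and r > 0) else 0.0


@dataclass
class PRCurve:
    # (threshold, precision, recall, f1) per sweep point
    points: list[tuple[float, float, float, float]]
    auc: float
    optimal_f1_threshold: float

    @property
    def optimal_f1(self) -> float:
        return max(p[3] for p in self.points)


def hc_support_threshold(n_replicates: int) -> int:
    """ceil(2N/3), so 'at least two thirds of replicates' holds literally."""
    return math.ceil(2 * n_replicates / 3)


def build_pseudo_gold(
    consensus: ConsensusSet,
    pg4: Sequence[GenomicInterval],
    og4: Sequence[GenomicInterval],
) -> PseudoGold:
    """Partition consensus regions into HC and AN tiers (disjoint by design)."""
    n = consensus.n_replicates
    if n < 2:
        raise ValueError("pseudo-gold standard needs at least 2 replicates")
    thr = hc_support_threshold(n)
    ivs = [r.interval for r in consensus.regions]
    hits_pg4 = intersects_any(ivs, pg4)
    hits_og4 = intersects_any(ivs, og4)

    hc: list[GenomicInterval] = []
    an: list[GenomicInterval] = []
    for reg, pg, og in zip(consensus.regions, hits_pg4, hits_og4):
        if reg.support >= thr and pg and og:
            hc.append(reg.interval)
        elif reg.support == 1 or (reg.support == 2 and not (pg and og)):
            an.append(reg.interval)
    hc_keys = {iv.key for iv in hc}
    assert not hc_keys & {iv.key for iv in an}, "HC and AN tiers must be disjoint"
    if not hc and not an:
        warnings.warn("both HC and AN tiers are empty: benchmark undefined")
    return PseudoGold(hc=hc, an=an, n_replicates=n)


def classify(
    result_peaks: Sequence[GenomicInterval], gold: PseudoGold
) -> EvalMetrics:
    """Confusion counts of a peak set against the pseudo-gold standard.

    TP counts recovered HC *regions* (so recall is bounded by 1 even when a
    single output peak spans several HC regions); FP counts output peaks
    overlapping AN but no HC region; FN = |HC| − TP. Output peaks touching
    neither tier contribute nothing.
    """
    hc_recovered = intersects_any(gold.hc, result_peaks)
    tp = int(sum(hc_recovered))
    hits_an = intersects_any(result_peaks, gold.an)
    hits_hc = intersects_any(result_peaks, gold.hc)
    fp = int(sum(a and not h for a, h in zip(hits_an, hits_hc)))
    fn = len(gold.hc) - tp
    return EvalMetrics(tp=tp, fp=fp, fn=fn)


def _auc_trapezoid(recalls: np.ndarray, precisions: np.ndarray) -> float:
    order = np.argsort(recalls, kind="stable")
    r, p = recalls[order], precisions[order]
    if np.unique(r).size == 1:
        # degenerate curve collapsed onto one recall value: score the single
        # operating point rather than a zero-width integral
        return float(r[0] * p.max())
    return float(np.trapezoid(p, r))


def _prefix_metrics(ranked: RankedResult, gold: PseudoGold) -> list[EvalMetrics]:
    """Confusion counts for every score-ordered prefix of the ranked list.

    Because a threshold sweep over a ranked list selects prefixes (ties
    included), the whole curve is computed in one incremental pass instead
    of re-classifying each threshold's peak set from scratch.
    """
    from .intervals_io import _SortedTrack

    an_track = _SortedTrack(gold.an)
    # map each HC region to an id so TP counts recovered regions, not peaks
    hc_sorted = sorted(gold.hc, key=lambda iv: iv.key)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in hc_sorted:
        by_chrom.setdefault(iv.chrom, []).append(iv)

    import bisect

    def hc_ids(iv: GenomicInterval) -> list[tuple[str, int, int]]:
        track = by_chrom.get(iv.chrom, [])
        ends = [t.end for t in track]
        i = bisect.bisect_right(ends, iv.start)
        out = []
        while i < len(track) and track[i].start < iv.end:
            out.append(track[i].key)
            i += 1
        return out

    seen_hc: set[tuple[str, int, int]] = set()
    tp = fp = 0
    out: list[EvalMetrics] = []
    for entry in ranked.entries:  # already rank-sorted (best first)
        ids = hc_ids(entry.interval)
        if ids:
            for key in ids:
                if key not in seen_hc:
                    seen_hc.add(key)
                    tp += 1
        elif an_track.hits(entry.interval):
            fp += 1
        out.append(EvalMetrics(tp=tp, fp=fp, fn=len(gold.hc) - tp))
    return out


def pr_curve(
    ranked: RankedResult,
    gold: PseudoGold,
    thresholds: Sequence[float],
) -> PRCurve:
    """Precision–recall curve over a threshold sweep, with trapezoidal AUC.

    The AUC integrates precision over the observed recall range without
    extrapolation; the optimal-F1 threshold is the strictest threshold
    attaining the maximum F1.
    """
    if len(thresholds) < 2:
        raise ValueError("need at least 2 thresholds for a PR curve")
    prefix = _prefix_metrics(ranked, gold)
    scores = [e.score for e in ranked.entries]

    def prefix_size(t: float) -> int:
        import bisect

        if ranked.smaller_is_better:
            return bisect.bisect_right(scores, t)
        return len(scores) - bisect.bisect_left(sorted(scores), t)

    empty = EvalMetrics(tp=0, fp=0, fn=len(gold.hc))
    metrics = []
    sizes = []
    for t in thresholds:
        n = prefix_size(t)
        sizes.append(n)
        metrics.append(prefix[n - 1] if n > 0 else empty)
    if all(m.tp == 0 and m.fp == 0 for m in metrics):
        raise ValueError(
            "degenerate PR curve: no output peak overlaps either gold tier "
            "at any threshold"
        )
    points = [
        (float(t), m.precision, m.recall, m.f1) for t, m in zip(thresholds, metrics)
    ]
    auc = _auc_trapezoid(
        np.array([p[2] for p in points]), np.array([p[1] for p in points])
    )
    best_f1 = max(p[3] for p in points)
    # tie-break: strictest threshold (smallest peak set)
    candidates = [
        (n, p[0]) for p, n in zip(points, sizes) if p[3] == best_f1
    ]
    optimal = min(candidates)[1]
    return PRCurve(points=points, auc=auc, optimal_f1_threshold=optimal)


def optimal_f1_peaks(
    ranked: RankedResult,
    gold: PseudoGold,
    thresholds: Sequence[float],
) -> list[GenomicInterval]:
    """The peak set at the threshold maximizing F1 (ties -> strictest)."""
    curve = pr_curve(ranked, gold, thresholds)
    (peaks,) = threshold_sweep(ranked, [curve.optimal_f1_threshold])
    return peaks
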