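"""Replicate-count and sequencing-depth design experiments.

Two questions an experimentalist asks before sequencing:

* **How many replicates?** Random k-replicate subsets (k = 2..N) are drawn,
  the reproducibility strategy re-run on each subset, and its optimal F1
  against the full-data pseudo-gold standard recorded over repeated
  iterations — mean F1 rises and its spread shrinks as k grows.
* **How deep?** Optimal F1 as a function of per-replicate depth d follows
  the saturating law F1(d) = F1_max·(1 − e^(−k·d)); fitting the rate k
  (with F1_max pinned at the full-depth optimum) gives the depth at which
  a chosen fraction of peak performance is reached, d = −ln(1−frac)/k.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

from .benchmark_eval import PseudoGold, build_pseudo_gold, pr_curve, threshold_sweep
from .consensus import build_consensus
from .intervals_io import GenomicInterval, PeakSet
from .strategies import (
    RankedResult,
    StrategyConfig,
    default_thresholds,
    mspc_like,
    occurring_at_least_once,
    pairwise_union,
    rank_product,
    shared_by_all,
)

__all__ = [
    "ReplicateDesignResult",
    "SaturationFit",
    "run_strategy",
    "strategy_thresholds",
    "evaluate_strategy",
    "replicate_design_experiment",
    "fit_depth_saturation",
    "required_depth",
    "depth_saturation_experiment",
]

STRATEGY_NAMES = ("atleastonce", "sharedbyall", "fisher", "rankprod", "pairwise")


def run_strategy(
    name: str,
    replicates: list[PeakSet],
    config: StrategyConfig = StrategyConfig(),
    seed: int = 0,
) -> RankedResult:
    """Dispatch a strategy by name on a replicate collection."""
    consensus = build_consensus(replicates)
    if name == "atleastonce":
        return occurring_at_least_once(consensus)
    if name == "sharedbyall":
        return shared_by_all(consensus)
    if name == "fisher":
        return mspc_like(consensus, config)
    if name == "rankprod":
        return rank_product(consensus, seed=seed)
    if name == "pairwise":
        return pairwise_union(replicates, threshold=max(config.idr_thresholds))
    raise ValueError(f"unknown strategy {name!r}; choose from {STRATEGY_NAMES}")


def strategy_thresholds(
    name: str, result: RankedResult, config: StrategyConfig = StrategyConfig()
) -> list[float]:
    """A sensible sweep grid per strategy: the printed grid for the pairwise
    strategy, support counts for the baselines, score quantiles otherwise."""
    if name == "pairwise":
        return sorted(config.idr_thresholds)
    if name in ("atleastonce", "sharedbyall"):
        supports = sorted({e.score for e in result.entries}, reverse=True)
        return supports if len(supports) >= 2 else supports + [1.0]
    return default_thresholds(result)


def evaluate_strategy(
    name: str,
    replicates: list[PeakSet],
    gold: PseudoGold,
    config: StrategyConfig = StrategyConfig(),
    seed: int = 0,
):
    """Run a strategy and score it: returns (RankedResult, PRCurve)."""
    result = run_strategy(name, replicates, config, seed=seed)
    thresholds = strategy_thresholds(name, result, config)
    return result, pr_curve(result, gold, thresholds)


@dataclass
class ReplicateDesignResult:
    k: int
    iterations: int
    f1_values: list[float]
    n_optimal_peaks: list[int]

    @property
    def f1_mean(self) -> float:
        return float(np.mean(self.f1_values))

    @property
    def f1_sd(self) -> float:
        vals = self.f1_values
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0


def replicate_design_experiment(
    replicates: list[PeakSet],
    pg4: Sequence[GenomicInterval],
    og4: Sequence[GenomicInterval],
    strategy: str = "fisher",
    k_range: Sequence[int] | None = None,
    iterations: int = 5,
    seed: int = 0,
    config: StrategyConfig = StrategyConfig(),
) -> list[ReplicateDesignResult]:
    """Subsample k of N replicates and score the strategy against the
    full-data pseudo-gold standard.

    The gold standard is built once from all N replicates and held fixed;
    each (k, iteration) draws a uniform k-subset without replacement within
    the draw (subsets may repeat across iterations when C(N,k) is small).
    """
    n = len(replicates)
    full_consensus = build_consensus(replicates)
    gold = build_pseudo_gold(full_consensus, pg4, og4)
    if k_range is None:
        k_range = range(2, n + 1)
    rng = np.random.default_rng(seed)

    out: list[ReplicateDesignResult] = []
    for k in k_range:
        if not (2 <= k <= n):
            raise ValueError(f"subset size k={k} outside 2..{n}")
        f1s: list[float] = []
        counts: list[int] = []
        for _ in range(iterations):
            idx = rng.choice(n, size=k, replace=False)
            subset = [replicates[i] for i in sorted(idx)]
            result, curve = evaluate_strategy(
                strategy, subset, gold, config, seed=int(rng.integers(2**31))
            )
            f1s.append(curve.optimal_f1)
            (opt_set,) = threshold_sweep(result, [curve.optimal_f1_threshold])
            counts.append(len(opt_set))
        out.append(ReplicateDesignResult(k=int(k), iterations=iterations,
                                         f1_values=f1s, n_optimal_peaks=counts))
    return out


@dataclass(frozen=True)
class SaturationFit:
    """Fitted depth-saturation curve F1(d) = f1_max·(1 − e^(−k_rate·d))."""

    f1_max: float
    k_rate: float

    @property
    def n90(self) -> float:
        """Depth (millions of reads) reaching 90% of the F1 ceiling."""
        return math.log(10.0) / self.k_rate

    def predict(self, depth: float) -> float:
        return self.f1_max * (1.0 - math.exp(-self.k_rate * depth))


def fit_depth_saturation(
    points: Sequence[tuple[float, float]], f1_max: float
) -> SaturationFit:
    """Least-squares fit of the saturation rate k with F1_max held fixed.

    F1_max is pinned at the full-depth optimum rather than co-fitted, so the
    single free parameter is found by bounded 1-D minimization (closed form
    when only one point is given).
    """
    if not points:
        raise ValueError("no points to fit")
    if f1_max <= 0:
        raise ValueError("f1_max must be positive")
    depths = np.array([d for d, _ in points], dtype=float)
    f1s = np.array([f for _, f in points], dtype=float)
    if np.any(depths <= 0):
        raise ValueError("depths must be positive")
    if np.any(f1s > f1_max * (1.0 + 1e-9)):
        warnings.warn("observed F1 above the stated F1_max ceiling")

    def k_from_point(d: float, f: float) -> float:
        frac = min(f / f1_max, 1.0 - 1e-12)
        return -math.log(1.0 - max(frac, 0.0)) / d if frac > 0 else 1e-9

    if len(points) == 1:
        return SaturationFit(f1_max=f1_max, k_rate=k_from_point(depths[0], f1s[0]))

    def residuals(k: np.ndarray) -> np.ndarray:
        return f1_max * (1.0 - np.exp(-k[0] * depths)) - f1s

    # per-point closed-form inversions give an excellent starting value;
    # the SSE surface is flat for large k, so a good init matters
    k0 = float(np.median([k_from_point(d, f) for d, f in zip(depths, f1s)]))
    res = optimize.least_squares(
        residuals, x0=[max(k0, 1e-9)], bounds=([1e-12], [np.inf]),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    return SaturationFit(f1_max=f1_max, k_rate=float(res.x[0]))


def required_depth(fit: SaturationFit, fraction: float = 0.9) -> float:
    """Depth (millions of reads) at which F1 reaches ``fraction``·F1_max."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie strictly between 0 and 1")
    return -math.log(1.0 - fraction) / fit.k_rate


def depth_saturation_experiment(
    bundle,
    depths: Sequence[float] = (5.0, 10.0, 15.0, 25.0),
    strategy: str = "fisher",
    seed: int = 0,
    config: StrategyConfig = StrategyConfig(),
) -> tuple[list[tuple[float, float]], SaturationFit]:
    """Resequence a synthetic experiment at several depths and fit the
    saturation curve.

    The pseudo-gold standard and F1_max come from the bundle's own
    (full-depth) replicates; each depth point redraws all replicates from
    the same truth at that uniform depth and records the strategy's optimal
    F1 against the fixed gold.
    """
    from .synthetic_data import resample_replicates

    full_consensus = build_consensus(bundle.replicates)
    gold = build_pseudo_gold(full_consensus, bundle.pg4_track, bundle.og4_track)
    _, full_curve = evaluate_strategy(
        strategy, bundle.replicates, gold, config, seed=seed
    )
    f1_max = full_curve.optimal_f1

    pts: list[tuple[float, float]] = []
    n = len(bundle.replicates)
    for i, d in enumerate(depths):
        reps = resample_replicates(bundle, [d] * n, seed=seed + 1000 + i)
        _, curve = evaluate_strategy(strategy, reps, gold, config, seed=seed + i)
        pts.append((float(d), curve.optimal_f1))
    fit = fit_depth_saturation(pts, f1_max=f1_max)
    return pts, fit
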