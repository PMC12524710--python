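"""Seeded generator of ground-truthed multi-replicate G4 peak datasets.

The generator emulates the statistical structure of BG4 ChIP-Seq replicate
experiments on a toy genome:

* a tiled gene model, with true G4 loci preferentially placed in promoter
  windows (G4s concentrate at promoters in real data);
* per-locus binding affinity a_i ~ log-normal, encoding cell-to-cell
  heterogeneity of the G4 landscape;
* per-replicate, depth-dependent detection — a locus with affinity a is
  called in a replicate of depth d (millions of mapped reads) with
  probability 1 − exp(−c·d·a), the same saturating form the depth-design
  analysis fits downstream;
* called-peak p-values that strengthen with d·a, never weaker than the
  caller threshold 1e-4;
* uniform background noise peaks with barely-significant p-values;
* pG4/oG4 evidence tracks enriched at true loci and sparse at noise; and
* an optional low-yield outlier replicate that keeps only a fraction of
  its peaks.

Ground-truth labels are kept on the bundle for testing only; the BED-style
outputs never expose them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotation import GeneModel, Transcript
from .intervals_io import GenomicInterval, PeakSet, merge_intervals, write_bed

__all__ = ["SimConfig", "TruthBundle", "generate", "resample_replicates",
           "default_scenarios", "write_bundle", "config_from_yaml"]

_P_FLOOR = 1e-300
_CALL_THRESHOLD = 1e-4  # loose caller threshold: every emitted peak beats it


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic multi-replicate experiment."""

    genome: tuple[tuple[str, int], ...] = (("chr1", 1_000_000), ("chr2", 1_000_000))
    n_true_loci: int = 300
    promoter_fraction: float = 0.7
    n_replicates: int = 6
    depth_per_replicate: tuple[float, ...] | None = None  # millions of reads
    locus_affinity_dispersion: float = 1.0  # log-normal sigma
    noise_rate: float = 50.0  # expected noise peaks / replicate / Mb
    pg4_coverage_true: float = 0.9
    og4_coverage_true: float = 0.75
    pg4_coverage_noise: float = 0.15
    og4_coverage_noise: float = 0.10
    outlier_replicate: tuple[int, float] | None = None  # (index, yield_factor)
    detection_rate: float = math.log(5.0) / 15.0  # median detection 0.8 @ 15 M
    pvalue_rate: float = 0.5  # −log10 p grows as rate·d·a
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("promoter_fraction", "pg4_coverage_true", "og4_coverage_true",
                     "pg4_coverage_noise", "og4_coverage_noise"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0,1]")
        if any(length <= 0 for _, length in self.genome):
            raise ValueError("chromosome lengths must be positive")
        if self.depths is not None and any(d <= 0 for d in self.depths):
            raise ValueError("depths must be positive")
        if self.outlier_replicate is not None:
            idx, yf = self.outlier_replicate
            if not (0 <= idx < self.n_replicates) or not (0.0 <= yf <= 1.0):
                raise ValueError(
                    f"bad outlier_replicate {self.outlier_replicate}"
                )

    @property
    def depths(self) -> tuple[float, ...] | None:
        return self.depth_per_replicate

    def resolved_depths(self) -> list[float]:
        if self.depth_per_replicate is None:
            return [15.0] * self.n_replicates
        if len(self.depth_per_replicate) != self.n_replicates:
            raise ValueError("depth_per_replicate length != n_replicates")
        return list(self.depth_per_replicate)


@dataclass
class TruthBundle:
    """A generated dataset plus the ground truth behind it."""

    config: SimConfig
    true_loci: list[GenomicInterval]
    affinities: np.ndarray  # parallel to true_loci
    gene_model: GeneModel
    pg4_track: list[GenomicInterval]
    og4_track: list[GenomicInterval]
    replicates: list[PeakSet]
    # per replicate: label per peak, "true" or "noise" (test accessors only)
    peak_labels: dict[str, list[str]] = field(default_factory=dict)


def _tile_gene_model(genome: Sequence[tuple[str, int]]) -> GeneModel:
    """Tile non-overlapping 3 kb 3-exon transcripts every 6 kb, strands alternating."""
    txs: list[Transcript] = []
    for chrom, length in genome:
        pos, i = 2000, 0
        while pos + 3000 + 2000 < length:
            strand = "+" if i % 2 == 0 else "-"
            exons = ((pos, pos + 500), (pos + 1250, pos + 1750), (pos + 2500, pos + 3000))
            txs.append(Transcript(chrom, pos, pos + 3000, strand,
                                  pos + 250, pos + 2750, exons))
            pos += 6000
            i += 1
    return GeneModel(transcripts=txs)


def _place_true_loci(
    cfg: SimConfig, genes: GeneModel, rng: np.random.Generator
) -> list[GenomicInterval]:
    chrom_lengths = dict(cfg.genome)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c, _ in cfg.genome}
    min_sep = 150  # jittered peaks of distinct loci must never merge

    def free(chrom: str, start: int, end: int) -> bool:
        return all(
            end + min_sep <= s or start >= e + min_sep
            for s, e in occupied[chrom]
        )

    promoters = []
    for tx in genes.transcripts:
        promoters.append((tx.chrom, max(tx.tss - 1000, 0), tx.tss + 1000))

    loci: list[GenomicInterval] = []
    attempts = 0
    while len(loci) < cfg.n_true_loci:
        attempts += 1
        if attempts > cfg.n_true_loci * 200:
            raise ValueError(
                f"cannot place {cfg.n_true_loci} loci on this genome "
                f"(placed {len(loci)}); genome too small or loci too many"
            )
        width = int(rng.integers(150, 601))
        if promoters and rng.random() < cfg.promoter_fraction:
            chrom, ps, pe = promoters[int(rng.integers(len(promoters)))]
            lo, hi = ps, max(ps + 1, pe - width)
            start = int(rng.integers(lo, hi))
        else:
            chrom, clen = cfg.genome[int(rng.integers(len(cfg.genome)))]
            start = int(rng.integers(0, max(1, clen - width)))
        end = min(start + width, chrom_lengths[chrom])
        if end - start < 150 or not free(chrom, start, end):
            continue
        occupied[chrom].append((start, end))
        loci.append(GenomicInterval(chrom, start, end, name=f"locus{len(loci)}"))
    loci.sort(key=lambda iv: iv.key)
    return loci


def _merge_within_replicate(
    peaks: list[GenomicInterval], labels: list[str]
) -> tuple[list[GenomicInterval], list[str]]:
    """Resolve overlapping/book-ended peaks within one replicate (min-p wins),
    as a real peak caller emits non-overlapping peaks per sample."""
    order = sorted(range(len(peaks)), key=lambda i: peaks[i].key)
    out_p: list[GenomicInterval] = []
    out_l: list[str] = []
    for i in order:
        p, lab = peaks[i], labels[i]
        if out_p and out_p[-1].chrom == p.chrom and p.start <= out_p[-1].end:
            last = out_p[-1]
            pv = min(x for x in (last.pvalue, p.pvalue) if x is not None)
            out_p[-1] = GenomicInterval(
                last.chrom, last.start, max(last.end, p.end), pvalue=pv
            )
            if lab == "true":
                out_l[-1] = "true"
        else:
            out_p.append(p)
            out_l.append(lab)
    return out_p, out_l


def _track_interval(
    locus: GenomicInterval, rng: np.random.Generator, chrom_len: int
) -> GenomicInterval:
    pad_l, pad_r = int(rng.integers(0, 51)), int(rng.integers(0, 51))
    start = max(0, locus.start - pad_l)
    end = min(chrom_len, locus.end + pad_r)
    return GenomicInterval(locus.chrom, start, end)


def generate(config: SimConfig) -> TruthBundle:
    """Generate one seeded, fully ground-truthed replicate experiment."""
    rng = np.random.default_rng(config.seed)
    chrom_lengths = dict(config.genome)
    genes = _tile_gene_model(config.genome)
    loci = _place_true_loci(config, genes, rng)
    affinities = rng.lognormal(mean=0.0, sigma=config.locus_affinity_dispersion,
                               size=len(loci))

    pg4: list[GenomicInterval] = []
    og4: list[GenomicInterval] = []
    for locus in loci:
        if rng.random() < config.pg4_coverage_true:
            pg4.append(_track_interval(locus, rng, chrom_lengths[locus.chrom]))
        if rng.random() < config.og4_coverage_true:
            og4.append(_track_interval(locus, rng, chrom_lengths[locus.chrom]))

    bundle = TruthBundle(
        config=config, true_loci=loci, affinities=affinities, gene_model=genes,
        pg4_track=pg4, og4_track=og4, replicates=[],
    )
    _draw_replicates(bundle, config.resolved_depths(), rng)
    bundle.pg4_track = merge_intervals(bundle.pg4_track)
    bundle.og4_track = merge_intervals(bundle.og4_track)
    return bundle


def _draw_replicates(
    bundle: TruthBundle, depths: Sequence[float], rng: np.random.Generator
) -> None:
    cfg = bundle.config
    chrom_lengths = dict(cfg.genome)
    genome_mb = sum(length for _, length in cfg.genome) / 1e6
    replicates: list[PeakSet] = []
    labels_by_rep: dict[str, list[str]] = {}

    for r, depth in enumerate(depths):
        rep_id = f"rep{r + 1}"
        peaks: list[GenomicInterval] = []
        labels: list[str] = []
        # true-locus detections
        for locus, a in zip(bundle.true_loci, bundle.affinities):
            p_detect = 1.0 - math.exp(-cfg.detection_rate * depth * a)
            if rng.random() >= p_detect:
                continue
            j1, j2 = rng.integers(-50, 51, size=2)
            start = max(0, locus.start + int(j1))
            end = min(chrom_lengths[locus.chrom], locus.end + int(j2))
            if end <= start:
                continue
            u = rng.uniform(0.5, 1.5)
            pv = 10.0 ** (-cfg.pvalue_rate * depth * a * u)
            pv = float(min(max(pv, _P_FLOOR), _CALL_THRESHOLD))
            peaks.append(GenomicInterval(locus.chrom, start, end, pvalue=pv))
            labels.append("true")
        # background noise
        n_noise = int(rng.poisson(cfg.noise_rate * genome_mb))
        for _ in range(n_noise):
            chrom, clen = cfg.genome[int(rng.integers(len(cfg.genome)))]
            width = int(rng.integers(150, 601))
            start = int(rng.integers(0, max(1, clen - width)))
            pv = float(rng.uniform(1e-6, _CALL_THRESHOLD))
            iv = GenomicInterval(chrom, start, min(start + width, clen), pvalue=pv)
            peaks.append(iv)
            labels.append("noise")
            if rng.random() < cfg.pg4_coverage_noise:
                bundle.pg4_track.append(_track_interval(iv, rng, clen))
            if rng.random() < cfg.og4_coverage_noise:
                bundle.og4_track.append(_track_interval(iv, rng, clen))
        # low-yield outlier thinning
        if cfg.outlier_replicate is not None and r == cfg.outlier_replicate[0]:
            keep_p = cfg.outlier_replicate[1]
            kept = [i for i in range(len(peaks)) if rng.random() < keep_p]
            peaks = [peaks[i] for i in kept]
            labels = [labels[i] for i in kept]
        peaks, labels = _merge_within_replicate(peaks, labels)
        replicates.append(PeakSet(replicate_id=rep_id, peaks=peaks))
        labels_by_rep[rep_id] = labels

    bundle.replicates = replicates
    bundle.peak_labels = labels_by_rep


def resample_replicates(
    bundle: TruthBundle, depths: Sequence[float], seed: int
) -> list[PeakSet]:
    """Redraw the replicate peak sets at new depths from the same truth.

    Emulates sequencing the same libraries shallower or deeper: true loci,
    affinities and evidence tracks stay fixed; detection and p-values are
    redrawn under the new per-replicate depths. Noise events are redrawn
    too, but their (already recorded) track contributions are not extended.
    """
    cfg = replace(bundle.config, seed=seed)
    tmp = TruthBundle(
        config=cfg, true_loci=bundle.true_loci, affinities=bundle.affinities,
        gene_model=bundle.gene_model,
        pg4_track=list(bundle.pg4_track), og4_track=list(bundle.og4_track),
        replicates=[],
    )
    rng = np.random.default_rng(seed)
    _draw_replicates(tmp, depths, rng)
    return tmp.replicates


def config_from_yaml(path: str | Path) -> SimConfig:
    """Load a :class:`SimConfig` from a YAML file mirroring its fields."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in SimConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    if "genome" in raw:
        raw["genome"] = tuple((str(c), int(n)) for c, n in raw["genome"])
    for key in ("depth_per_replicate", "outlier_replicate"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    return SimConfig(**raw)


def default_scenarios() -> dict[str, SimConfig]:
    """The three study designs: 5, 6 and 9 replicates, the last with a
    low-yield outlier replicate."""
    return {
        "rep5": SimConfig(n_replicates=5, seed=5),
        "rep6": SimConfig(n_replicates=6, seed=6),
        "rep9": SimConfig(n_replicates=9, outlier_replicate=(8, 0.03), seed=9),
    }


def write_bundle(bundle: TruthBundle, outdir: str | Path) -> None:
    """Write one narrowPeak per replicate plus tracks, gene model and truth."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for rep in bundle.replicates:
        write_bed(rep.peaks, outdir / f"{rep.replicate_id}.narrowPeak")
    write_bed(bundle.pg4_track, outdir / "pg4.bed")
    write_bed(bundle.og4_track, outdir / "og4.bed")
    with open(outdir / "genes.bed12", "w") as fh:
        for tx in bundle.gene_model.transcripts:
            sizes = ",".join(str(e - s) for s, e in tx.exons)
            offs = ",".join(str(s - tx.tx_start) for s, e in tx.exons)
            fh.write(
                f"{tx.chrom}\t{tx.tx_start}\t{tx.tx_end}\ttx\t0\t{tx.strand}\t"
                f"{tx.cds_start}\t{tx.cds_end}\t0\t{len(tx.exons)}\t{sizes}\t{offs}\n"
            )
    truth = {
        "seed": bundle.config.seed,
        "true_loci": [[iv.chrom, iv.start, iv.end] for iv in bundle.true_loci],
        "affinities": [float(a) for a in bundle.affinities],
        "peak_labels": bundle.peak_labels,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
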