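"""Genome-distribution binning, element enrichment and the enhancer-overlap
permutation test.

Enrichment uses a double normalization: a class score is the fraction of
junction loci falling in the class divided by the fraction of the genome the
class covers, so uniform placement gives an expected score of 1 for every
class.  The enhancer test compares, per sample, the normalized enhancer-overlap
score of unique multi-chromosomal joined regions against length-matched random
regions, with a one-tailed exact Wilcoxon signed-rank test across samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .caller import CircleCall
from .genome import AnnotationSet, DERIVED_CLASSES, GENIC_CLASSES, merge_intervals
from .stats import TestResult, ks_two_sample, wilcoxon_signed_rank

logger = logging.getLogger(__name__)

#: classes whose absence at a locus makes it distal intergenic
STRUCTURAL_CLASSES = (*GENIC_CLASSES, *DERIVED_CLASSES, "CpG_island")


class BinningError(ValueError):
    pass


@dataclass
class BinDistribution:
    bin_width: int
    table: pd.DataFrame  # chrom, bin_start, bin_end, count, fraction

    @property
    def fractions(self) -> np.ndarray:
        return self.table["fraction"].to_numpy()

    def same_tiling(self, other: "BinDistribution") -> bool:
        a, b = self.table, other.table
        return self.bin_width == other.bin_width and len(a) == len(b) and bool(
            (a[["chrom", "bin_start", "bin_end"]].values == b[["chrom", "bin_start", "bin_end"]].values).all()
        )


def bin_distribution(
    calls: list[CircleCall],
    chrom_lengths: dict[str, int],
    bin_width: int = 1_000_000,
) -> BinDistribution:
    """Tile each chromosome with non-overlapping bins (trailing partial bins
    kept) and count calls by their start breakpoint; fractions sum to 1."""
    if not calls:
        raise BinningError("cannot bin an empty call set")
    rows = []
    index: dict[tuple[str, int], int] = {}
    for chrom, L in chrom_lengths.items():
        for b0 in range(0, L, bin_width):
            index[(chrom, b0 // bin_width)] = len(rows)
            rows.append({"chrom": chrom, "bin_start": b0, "bin_end": min(b0 + bin_width, L), "count": 0})
    for c in calls:
        key = (c.chrom, c.start // bin_width)
        if key not in index:
            raise BinningError(f"call start {c.chrom}:{c.start} outside the genome tiling")
        rows[index[key]]["count"] += 1
    table = pd.DataFrame(rows)
    table["fraction"] = table["count"] / table["count"].sum()
    return BinDistribution(bin_width, table)


def compare_bin_distributions(a: BinDistribution, b: BinDistribution) -> TestResult:
    """Two-sample KS test on the genome distribution patterns.

    Each call set is represented as a sample of global bin indices
    (reconstructed from the per-bin counts) and the two samples are compared
    with the asymptotic two-sample KS test: identical distributions give D = 0,
    disjoint single-bin point masses give D = 1.
    """
    if not a.same_tiling(b):
        raise BinningError("bin distributions use different genome tilings")
    sa = np.repeat(np.arange(len(a.table)), a.table["count"].to_numpy())
    sb = np.repeat(np.arange(len(b.table)), b.table["count"].to_numpy())
    return ks_two_sample(sa, sb)


class AnnotationIndex:
    """Interval trees over an AnnotationSet for point-containment queries."""

    def __init__(self, ann: AnnotationSet):
        self.ann = ann
        self.trees: dict[str, dict[str, IntervalTree]] = {}
        for label, ivs in ann.tracks.items():
            per: dict[str, IntervalTree] = {}
            for chrom, s, e in ivs:
                if e > s:
                    per.setdefault(chrom, IntervalTree()).addi(s, e)
            self.trees[label] = per

    def labels_at(self, chrom: str, pos: int) -> set[str]:
        out = set()
        for label, per in self.trees.items():
            if label == "distal_intergenic":
                continue
            tree = per.get(chrom)
            if tree is not None and tree.overlaps_point(pos):
                out.add(label)
        if not out & set(STRUCTURAL_CLASSES):
            out.add("distal_intergenic")
        return out


def junction_loci(call: CircleCall, loci: str = "both") -> list[tuple[str, int]]:
    """Breakpoint loci of a call: the start base and (by default) the final
    circle base as a second locus."""
    pts = [(call.chrom, call.start)]
    if loci == "both":
        pts.append((call.chrom, call.end - 1))
    return pts


def classify_junction(
    call: CircleCall, index: AnnotationIndex, loci: str = "both"
) -> set[str]:
    """Multi-label annotation classes containing the call's junction loci."""
    out: set[str] = set()
    for chrom, pos in junction_loci(call, loci):
        if pos < 0 or pos >= index.ann.chrom_lengths[chrom]:
            raise ValueError(f"locus {chrom}:{pos} outside chromosome bounds")
        out |= index.labels_at(chrom, pos)
    return out


def element_enrichment(
    calls: list[CircleCall],
    ann: AnnotationSet,
    loci: str = "both",
) -> pd.DataFrame:
    """Per-class junction counts with double normalization.

    score = (junction loci in class / total loci) / (class bp / genome bp);
    expected 1 under uniform placement.  Classes with zero merged coverage are
    excluded with a warning.
    """
    index = AnnotationIndex(ann)
    genome_bp = sum(ann.chrom_lengths.values())
    loci_list = [pt for c in calls for pt in junction_loci(c, loci)]
    total = len(loci_list)
    counts: dict[str, int] = {label: 0 for label in ann.tracks}
    for chrom, pos in loci_list:
        for label in index.labels_at(chrom, pos):
            if label in counts:  # distal fallback only when the track exists
                counts[label] += 1
    rows = []
    for label in ann.tracks:
        cov = ann.coverage_bp(label)
        if cov == 0:
            logger.warning("class %s has zero coverage; excluded", label)
            continue
        score = (counts[label] / total) / (cov / genome_bp) if total else float("nan")
        rows.append(
            {
                "class": label,
                "junction_count": counts[label],
                "total_junctions": total,
                "class_coverage_bp": cov,
                "genome_bp": genome_bp,
                "normalized_score": score,
            }
        )
    return pd.DataFrame(rows)


def random_regions(
    template: list[tuple[str, int, int]],
    chrom_lengths: dict[str, int],
    rng: np.random.Generator | int,
) -> list[tuple[str, int, int]]:
    """One random region per template region, same length, chromosome drawn
    proportional to length (among chromosomes the region fits) and start
    uniform over the legal positions; fully seed-reproducible."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    names = list(chrom_lengths)
    lens = np.array([chrom_lengths[c] for c in names], dtype=float)
    out = []
    for _, s, e in template:
        size = e - s
        ok = lens >= size
        if not ok.any():
            raise ValueError(f"region of {size} bp fits on no chromosome")
        p = np.where(ok, lens, 0.0)
        p /= p.sum()
        ci = int(rng.choice(len(names), p=p))
        start = int(rng.integers(0, chrom_lengths[names[ci]] - size + 1))
        out.append((names[ci], start, start + size))
    return out


def _overlap_tree(intervals: list[tuple[str, int, int]]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, s, e in intervals:
        if e > s:
            trees.setdefault(chrom, IntervalTree()).addi(s, e)
    return trees


def normalized_overlap_score(
    regions: list[tuple[str, int, int]],
    elements: list[tuple[str, int, int]],
    chrom_lengths: dict[str, int],
) -> float:
    """(fraction of unique regions hitting >= 1 element) / (element coverage
    fraction of the genome).  Each region counts once however many elements it
    touches."""
    uniq = sorted(set(regions))
    if not uniq:
        raise ValueError("no regions to score")
    trees = _overlap_tree(elements)
    hits = sum(
        1
        for chrom, s, e in uniq
        if chrom in trees and trees[chrom].overlap(s, e)
    )
    cov = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in elements:
        by_chrom.setdefault(chrom, []).append((s, e))
    for ivs in by_chrom.values():
        cov += sum(e - s for s, e in merge_intervals(ivs))
    genome_bp = sum(chrom_lengths.values())
    if cov == 0:
        raise ValueError("elements have zero coverage")
    return (hits / len(uniq)) / (cov / genome_bp)


@dataclass
class EnhancerEnrichment:
    observed: dict[str, float]
    null: dict[str, list[float]]
    null_summary: dict[str, float]
    test: TestResult
    min_attainable_p: float


def enhancer_enrichment_test(
    joined_regions: dict[str, list[tuple[str, int, int]]],
    enhancers: list[tuple[str, int, int]],
    chrom_lengths: dict[str, int],
    n_draws: int = 20,
    seed: int = 0,
) -> EnhancerEnrichment:
    """Are multi-chromosomal joined regions enriched for enhancer overlap?

    Per sample: observed = normalized enhancer-overlap score of its unique
    joined regions; null = the same score on length-matched random regions
    (mean over n_draws seeded draws; n_draws=1 gives the single-draw variant).
    One-tailed exact Wilcoxon signed-rank test of observed > null across
    samples.
    """
    if not joined_regions:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    observed: dict[str, float] = {}
    null: dict[str, list[float]] = {}
    for sample in sorted(joined_regions):
        regions = sorted(set(joined_regions[sample]))
        observed[sample] = normalized_overlap_score(regions, enhancers, chrom_lengths)
        draws = []
        for _ in range(n_draws):
            rand = random_regions(regions, chrom_lengths, rng)
            draws.append(normalized_overlap_score(rand, enhancers, chrom_lengths))
        null[sample] = draws
    null_summary = {s: float(np.mean(v)) for s, v in null.items()}
    diffs = np.array([observed[s] - null_summary[s] for s in sorted(joined_regions)])
    test = wilcoxon_signed_rank(diffs, sided="greater")
    n = len(diffs)
    return EnhancerEnrichment(observed, null, null_summary, test, min_attainable_p=0.5 ** n)
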