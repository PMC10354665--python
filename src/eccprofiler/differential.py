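"""Gene-level eccDNA abundance, recurrence sets and biomarker intersection.

Gene abundance is counted from supportive split reads: a gene accrues the
split-read support of every call whose interval overlaps the gene body (a call
overlapping k genes contributes to all k), then counts are scaled to split
reads per million per sample.  The differential fit itself is delegated to an
external count-based tool; this module exports its exact inputs (integer count
matrix + design table) and the 150-bp breakpoint-flanking FASTA used for motif
scanning.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .caller import CircleCall
from .genome import Gene, ReferenceGenome

logger = logging.getLogger(__name__)


@dataclass
class GeneAbundanceMatrix:
    raw: pd.DataFrame  # genes x samples, integer supportive-split-read counts
    normalized: pd.DataFrame  # per-million-total-split-reads
    total_split_reads: dict[str, int]


def _gene_trees(genes: list, extend_bp: int = 0) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        name, chrom, s, e = (
            (g.name, g.chrom, g.start, g.end) if isinstance(g, Gene) else g
        )
        trees.setdefault(chrom, IntervalTree()).addi(max(0, s - extend_bp), e + extend_bp, name)
    return trees


def gene_abundance(
    calls_by_sample: dict[str, list[CircleCall]],
    genes: list,
    total_split_reads: dict[str, int],
    extend_bp: int = 0,
    use_duplicates: bool = False,
) -> GeneAbundanceMatrix:
    """Genes x samples supportive-split-read count matrix plus its per-million
    normalization.  Genes may be Gene objects or (name, chrom, start, end)
    tuples; extend_bp widens gene bodies symmetrically before overlap."""
    for s, t in total_split_reads.items():
        if t <= 0:
            raise ValueError(f"sample {s}: total_split_reads must be positive")
    names = sorted(
        {(g.name if isinstance(g, Gene) else g[0]) for g in genes}
    )
    samples = sorted(calls_by_sample)
    trees = _gene_trees(genes, extend_bp)
    raw = pd.DataFrame(0, index=names, columns=samples, dtype=np.int64)
    for sample in samples:
        for call in calls_by_sample[sample]:
            support = call.n_evidence_reads if use_duplicates else call.n_split_support
            tree = trees.get(call.chrom)
            if tree is None:
                continue
            for iv in tree.overlap(call.start, call.end):
                raw.loc[iv.data, sample] += support
    norm = raw / pd.Series(total_split_reads)[samples] * 1e6
    return GeneAbundanceMatrix(raw, norm, dict(total_split_reads))


@dataclass
class RecurrentEccdnaSet:
    group: str
    members: list[tuple[str, int, int]]
    per_member_samples: dict[tuple[str, int, int], list[str]]
    gene_set: set[str]


def recurrent_eccdna(
    calls_by_sample: dict[str, list[CircleCall]],
    groups: dict[str, str],
    min_samples: int = 2,
    tolerance_bp: int = 0,
    genes: list | None = None,
) -> dict[str, RecurrentEccdnaSet]:
    """Per group, the unique circles present in at least min_samples samples
    ("highly abundant" recurrence), with gene sets by gene-body overlap.

    tolerance_bp = 0 matches identities exactly; a positive tolerance merges
    junctions by single-linkage within the tolerance on both breakpoints
    (clusters wider than 2x the tolerance are flagged with a warning).
    """
    by_group: dict[str, list[str]] = defaultdict(list)
    for sample, grp in groups.items():
        by_group[grp].append(sample)
    gene_trees = _gene_trees(genes, 0) if genes else {}
    out: dict[str, RecurrentEccdnaSet] = {}
    for grp in sorted(by_group):
        samples = sorted(by_group[grp])
        items = [
            ((c.chrom, c.start, c.end), sample)
            for sample in samples
            for c in calls_by_sample.get(sample, [])
        ]
        clusters = _cluster_identities(items, tolerance_bp)
        members = []
        per_member: dict[tuple[str, int, int], list[str]] = {}
        for ident, sample_list in clusters:
            uniq = sorted(set(sample_list))
            if len(uniq) >= min_samples:
                members.append(ident)
                per_member[ident] = uniq
        members.sort()
        gene_set: set[str] = set()
        for chrom, s, e in members:
            tree = gene_trees.get(chrom)
            if tree is not None:
                gene_set |= {iv.data for iv in tree.overlap(s, e)}
        out[grp] = RecurrentEccdnaSet(grp, members, per_member, gene_set)
    return out


def _cluster_identities(items, tolerance_bp: int):
    """Group (identity, sample) pairs; exact hash-join at tolerance 0, else
    single-linkage over junction coordinates within the tolerance."""
    if tolerance_bp == 0:
        buckets: dict[tuple[str, int, int], list[str]] = defaultdict(list)
        for ident, sample in items:
            buckets[ident].append(sample)
        return sorted(buckets.items())
    by_chrom: dict[str, list[tuple[tuple[str, int, int], str]]] = defaultdict(list)
    for ident, sample in items:
        by_chrom[ident[0]].append((ident, sample))
    clusters = []
    for chrom in sorted(by_chrom):
        entries = sorted(by_chrom[chrom], key=lambda t: t[0])
        cur: list[tuple[tuple[str, int, int], str]] = []
        for ident, sample in entries:
            if cur and (
                ident[1] - cur[-1][0][1] > tolerance_bp
                or abs(ident[2] - cur[-1][0][2]) > tolerance_bp
            ):
                clusters.append(_finish_cluster(cur, tolerance_bp))
                cur = []
            cur.append((ident, sample))
        if cur:
            clusters.append(_finish_cluster(cur, tolerance_bp))
    return clusters


def _finish_cluster(entries, tolerance_bp):
    starts = [i[1] for i, _ in entries]
    ends = [i[2] for i, _ in entries]
    if max(starts) - min(starts) > 2 * tolerance_bp or max(ends) - min(ends) > 2 * tolerance_bp:
        logger.warning("junction cluster spans more than 2x tolerance (%d bp)", tolerance_bp)
    rep = min(i for i, _ in entries)
    return rep, [s for _, s in entries]


def intersect_biomarkers(
    plasma_recurrent_genes: dict[str, set[str]],
    placenta_differential_genes: dict[str, set[str]],
) -> dict[tuple[str, str], set[str]]:
    """Per (plasma group, placenta direction) intersection of gene sets; an
    empty intersection is a valid result, but zero shared identifiers across
    all inputs raises a namespace diagnostic."""
    all_plasma = set().union(*plasma_recurrent_genes.values()) if plasma_recurrent_genes else set()
    all_plac = set().union(*placenta_differential_genes.values()) if placenta_differential_genes else set()
    if all_plasma and all_plac and not all_plasma & all_plac:
        logger.warning(
            "no shared gene identifiers between the two inputs — check namespaces"
        )
    return {
        (grp, direction): plasma & plac
        for grp, plasma in sorted(plasma_recurrent_genes.items())
        for direction, plac in sorted(placenta_differential_genes.items())
    }


def export_differential_inputs(
    matrix: GeneAbundanceMatrix,
    design: dict[str, str],
    counts_path: str | Path,
    design_path: str | Path,
) -> None:
    """Integer raw-count table plus design file, ready for a count-based
    differential-abundance tool (which applies its own normalization)."""
    matrix.raw.to_csv(counts_path, sep="\t", index_label="gene", lineterminator="\n")
    rows = pd.DataFrame(
        {"sample": list(matrix.raw.columns), "group": [design[s] for s in matrix.raw.columns]}
    )
    rows.to_csv(design_path, sep="\t", index=False, lineterminator="\n")


def export_flank_fasta(
    calls: list[CircleCall],
    genome: ReferenceGenome,
    path: str | Path,
    inside_bp: int = 50,
    outside_bp: int = 100,
) -> tuple[int, int]:
    """150-bp breakpoint-flanking sequences: for each breakpoint, 50 bp inside
    the circle plus 100 bp outside it.  Records clipped by a chromosome edge
    are dropped and counted, never silently truncated.

    Returns (n_written, n_dropped).
    """
    written = dropped = 0
    with open(path, "w", newline="\n") as fh:
        for c in calls:
            L = len(genome.sequences[c.chrom])
            flanks = [
                ("start", c.start - outside_bp, c.start + inside_bp),
                ("end", c.end - inside_bp, c.end + outside_bp),
            ]
            for side, s, e in flanks:
                if s < 0 or e > L:
                    dropped += 1
                    continue
                fh.write(f">{c.chrom}:{c.start}-{c.end}|{side}\n{genome.fetch(c.chrom, s, e)}\n")
                written += 1
    if dropped:
        logger.info("%d flank records dropped at chromosome edges", dropped)
    return written, dropped
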