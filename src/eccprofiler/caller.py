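"""Split-read eccDNA calling.

The caller consumes standard paired-end alignments and implements the
split-read + anchored-mate evidence model: a candidate junction is one read
aligned in two pieces (primary + supplementary, linked through the SA field)
whose mate maps uniquely and contiguously.  Junction coordinates are then
corrected at base-pair resolution for flanking direct repeats — a k-bp repeat
makes k+1 split placements sequence-identical, and every one of them is
canonicalized to the leftmost offset — before evidence is grouped into
single-fragment circle calls.  Cross-chromosomal junctions feed the
multi-fragment path: confident regions (fully covered intervals whose both
ends are junction breakpoints joined to other chromosomes) are chained into
two- and three-fragment circles.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pysam

from .genome import ReferenceGenome

logger = logging.getLogger(__name__)

_CIG_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass(frozen=True)
class Placement:
    chrom: str
    start: int  # 0-based
    end: int  # exclusive
    strand: str


@dataclass(frozen=True)
class JunctionEvidence:
    """One split read (two placements, read order) plus its anchored mate.

    ``placement_a`` is the segment that comes first along the aligned read; for
    a circularizing junction it carries the circle *end* breakpoint
    (``placement_a.end``) while ``placement_b.start`` is the circle *start*.
    """

    read_id: str
    placement_a: Placement
    placement_b: Placement
    mate_anchor: tuple[str, int, int]
    is_duplicate: bool = False
    repeat_shift_window: int = 0

    @property
    def junction(self) -> tuple[str, int, str, int]:
        """(end_chrom, end_pos, start_chrom, start_pos) of the junction."""
        return (
            self.placement_a.chrom,
            self.placement_a.end,
            self.placement_b.chrom,
            self.placement_b.start,
        )

    @property
    def same_chrom(self) -> bool:
        return self.placement_a.chrom == self.placement_b.chrom


@dataclass(frozen=True)
class CircleCall:
    chrom: str
    start: int
    end: int
    n_split_support: int
    n_evidence_reads: int
    direct_repeat_len: int = 0
    sample_id: str = ""

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ConfidentRegion:
    chrom: str
    start: int
    end: int
    left_partner: tuple[str, int]
    right_partner: tuple[str, int]
    covered_fraction: float = 1.0


@dataclass
class MultiFragmentCircle:
    fragments: list[ConfidentRegion]
    junction_support: list[int]
    shares_region: bool = False

    @property
    def chroms(self) -> tuple[str, ...]:
        return tuple(f.chrom for f in self.fragments)


def _cigar_ops(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIG_RE.findall(cigar)]


def _is_contiguous(cigartuples, max_clip: int = 5) -> bool:
    """Single match block with total clipping below max_clip."""
    if cigartuples is None:
        return False
    clips = sum(n for op, n in cigartuples if op in (4, 5))
    matches = [n for op, n in cigartuples if op == 0]
    others = [op for op, n in cigartuples if op not in (0, 4, 5)]
    return len(matches) == 1 and not others and clips < max_clip


def _sa_placement(sa: str) -> tuple[Placement, int] | None:
    """Parse the first SA entry into a Placement plus its leading-clip length."""
    entry = sa.split(";")[0]
    if not entry:
        return None
    chrom, pos, strand, cigar, _mapq, _nm = entry.split(",")
    ops = _cigar_ops(cigar)
    ref_len = sum(n for n, op in ops if op in "MDN=X")
    lead = ops[0][1] in "SH" and ops[0][0] or 0
    start = int(pos) - 1
    return Placement(chrom, start, start + ref_len, strand), lead


def extract_junction_evidence(
    sam_path: str | Path,
    min_mapq: int = 20,
    keep_duplicates: bool = True,
) -> tuple[list[JunctionEvidence], dict]:
    """Collect split-read + anchored-mate junction evidence from a SAM/BAM file.

    A read pair contributes evidence when one read is a split read (primary
    alignment with an SA-linked supplementary placement on the same strand) and
    the other maps uniquely and contiguously (single match block, mapq >=
    min_mapq).  Secondary alignments are always discarded; duplicate-flagged
    pairs are retained by default so that every junction is discoverable.

    Returns the evidence list plus a counter dict of skipped categories
    (orphan supplementary records, unmapped mates, inverted junctions, ...).
    """
    skipped: dict[str, int] = Counter()
    primaries: dict[tuple[str, bool], dict] = {}
    supp_qnames: set[str] = set()

    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_unmapped:
                continue
            if rec.is_supplementary:
                supp_qnames.add(rec.query_name)
                continue
            ops = rec.cigartuples or []
            lead = ops[0][1] if ops and ops[0][0] in (4, 5) else 0
            primaries[(rec.query_name, rec.is_read1)] = {
                "chrom": rec.reference_name,
                "start": rec.reference_start,
                "end": rec.reference_end,
                "strand": "-" if rec.is_reverse else "+",
                "mapq": rec.mapping_quality,
                "lead_clip": lead,
                "contiguous": _is_contiguous(ops),
                "sa": rec.get_tag("SA") if rec.has_tag("SA") else None,
                "dup": rec.is_duplicate,
                "mate_unmapped": rec.mate_is_unmapped,
            }

    for q in supp_qnames:
        if (q, True) not in primaries and (q, False) not in primaries:
            skipped["orphan_supplementary"] += 1
    if skipped.get("orphan_supplementary"):
        logger.warning("%d supplementary records without a reachable primary", skipped["orphan_supplementary"])

    evidence: list[JunctionEvidence] = []
    seen_pairs = {q for q, _ in primaries}
    for qname in sorted(seen_pairs):
        r1 = primaries.get((qname, True))
        r2 = primaries.get((qname, False))
        if r1 is None or r2 is None:
            skipped["unpaired"] += 1
            continue
        if r1["mate_unmapped"] or r2["mate_unmapped"]:
            skipped["unmapped_mate"] += 1
            continue
        split, mate = None, None
        for a, b in ((r1, r2), (r2, r1)):
            if a["sa"] is not None and b["sa"] is None:
                split, mate = a, b
        if split is None:
            skipped["no_split_or_both_split"] += 1
            continue
        if not (mate["contiguous"] and mate["mapq"] >= min_mapq):
            skipped["mate_not_anchored"] += 1
            continue
        if split["dup"] or mate["dup"]:
            if not keep_duplicates:
                skipped["duplicate"] += 1
                continue
        parsed = _sa_placement(split["sa"])
        if parsed is None:
            skipped["bad_sa"] += 1
            continue
        supp_pl, supp_lead = parsed
        if supp_pl.strand != split["strand"]:
            skipped["inverted_junction"] += 1
            continue
        prim_pl = Placement(split["chrom"], split["start"], split["end"], split["strand"])
        if split["lead_clip"] <= supp_lead:
            pl_a, pl_b = prim_pl, supp_pl
        else:
            pl_a, pl_b = supp_pl, prim_pl
        evidence.append(
            JunctionEvidence(
                read_id=qname,
                placement_a=pl_a,
                placement_b=pl_b,
                mate_anchor=(mate["chrom"], mate["start"], mate["end"]),
                is_duplicate=split["dup"] or mate["dup"],
            )
        )
    return evidence, dict(skipped)


# ---------------------------------------------------------------------------
# direct-repeat junction correction


def shift_window(
    genome: ReferenceGenome,
    end_chrom: str,
    end_pos: int,
    start_chrom: str,
    start_pos: int,
    cap: int = 100,
) -> tuple[int, int]:
    """(left, right) extents of the sequence-identical junction-offset window.

    A junction joining reference position ``end_pos`` (exclusive, circle end)
    back to ``start_pos`` (circle start) can be shifted left while the bases
    entering the circle start match the bases leaving the circle end, and
    right symmetrically; the window is truncated at chromosome edges.
    """
    s_seq = genome.sequences[start_chrom]
    e_seq = genome.sequences[end_chrom]
    left = 0
    while (
        left < cap
        and start_pos - left - 1 >= 0
        and end_pos - left - 1 >= 0
        and s_seq[start_pos - left - 1] == e_seq[end_pos - left - 1]
    ):
        left += 1
    right = 0
    while (
        right < cap
        and start_pos + right < len(s_seq)
        and end_pos + right < len(e_seq)
        and s_seq[start_pos + right] == e_seq[end_pos + right]
    ):
        right += 1
    return left, right


def correct_junction_for_direct_repeat(
    ev: JunctionEvidence, genome: ReferenceGenome, cap: int = 100
) -> JunctionEvidence:
    """Canonicalize a junction to the leftmost sequence-identical offset.

    The correction is a pure function of the genome around the junction (not of
    how the particular read happened to be split), so every legal aligner
    offset of the same physical junction maps to identical coordinates.
    Idempotent; records the equivalence-window size in repeat_shift_window.
    """
    e_chrom, e_pos, s_chrom, s_pos = ev.junction
    left, right = shift_window(genome, e_chrom, e_pos, s_chrom, s_pos, cap)
    if left == 0 and right == 0:
        return replace(ev, repeat_shift_window=0)
    return replace(
        ev,
        placement_a=replace(ev.placement_a, end=e_pos - left),
        placement_b=replace(ev.placement_b, start=s_pos - left),
        repeat_shift_window=left + right,
    )


def correct_evidence(
    evidence: list[JunctionEvidence], genome: ReferenceGenome, cap: int = 100
) -> list[JunctionEvidence]:
    return [correct_junction_for_direct_repeat(ev, genome, cap) for ev in evidence]


# ---------------------------------------------------------------------------
# single-fragment calling


def partition_evidence(evidence: list[JunctionEvidence]):
    """Split canonicalized evidence into the single-fragment candidates and the
    cross-chromosomal stream that feeds the multi-fragment path."""
    single = [ev for ev in evidence if ev.same_chrom]
    cross = [ev for ev in evidence if not ev.same_chrom]
    return single, cross


def _support_counts(group: list[JunctionEvidence]) -> tuple[int, int]:
    support = len({ev.read_id for ev in group if not ev.is_duplicate})
    return support, len(group)


def call_single_fragment(
    evidence: list[JunctionEvidence],
    genome: ReferenceGenome | None = None,
    min_support: int = 1,
    sample_id: str = "",
    max_repeat_len: int = 20,
) -> list[CircleCall]:
    """Group corrected same-chromosome evidence into single-fragment calls.

    Only head-to-tail evidence is eligible: both placements on one chromosome
    and strand, the read running from the circle end back to its start
    (placement_b.start < placement_a.end), with the anchored mate overlapping
    the circle interval.  Support counts distinct non-duplicate read ids;
    n_evidence_reads additionally counts duplicates.
    """
    from .features import find_direct_repeat

    groups: dict[tuple[str, int, int], list[JunctionEvidence]] = defaultdict(list)
    for ev in evidence:
        if not ev.same_chrom:
            continue  # cross-chromosomal evidence belongs to the multi-fragment path
        if ev.placement_a.strand != ev.placement_b.strand:
            continue
        start, end = ev.placement_b.start, ev.placement_a.end
        if not start < end:
            continue  # deletion-like split, not a circularizing junction
        m_chrom, m_start, m_end = ev.mate_anchor
        if m_chrom != ev.placement_a.chrom or m_end <= start or m_start >= end:
            continue  # mate must overlap the circle body
        groups[(ev.placement_a.chrom, start, end)].append(ev)

    calls = []
    for (chrom, start, end), group in groups.items():
        support, n_evidence = _support_counts(group)
        if support < min_support:
            continue
        rep = (
            find_direct_repeat(genome, chrom, start, end, max_len=max_repeat_len)
            if genome is not None
            else max(ev.repeat_shift_window for ev in group)
        )
        calls.append(
            CircleCall(chrom, start, end, support, n_evidence, rep, sample_id)
        )
    return sorted(calls, key=lambda c: (c.chrom, c.start, c.end))


def format_call_label(call: CircleCall, genes) -> str:
    """Human-readable label, 1-based inclusive coordinates: GENE^circle s-e."""
    name = next(
        (g.name for g in genes if g.chrom == call.chrom and g.start < call.end and call.start < g.end),
        call.chrom,
    )
    return f"{name}^circle {call.start + 1:,}–{call.end:,}"


# ---------------------------------------------------------------------------
# multi-fragment path


def compute_coverage(sam_path: str | Path) -> dict[str, np.ndarray]:
    """Per-base read coverage over every chromosome, from all mapped records."""
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        lengths = dict(zip(fh.references, fh.lengths))
        diffs = {c: np.zeros(L + 1, dtype=np.int64) for c, L in lengths.items()}
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                continue
            diffs[rec.reference_name][rec.reference_start] += 1
            diffs[rec.reference_name][rec.reference_end] -= 1
    return {c: np.cumsum(d[:-1]) for c, d in diffs.items()}


def extract_confident_regions(
    cross_evidence: list[JunctionEvidence],
    coverage: dict[str, np.ndarray],
    max_region_len: int = 100_000,
) -> list[ConfidentRegion]:
    """Intervals with 100% read coverage whose both ends are cross-chromosomal
    junction breakpoints (evidence must already be repeat-corrected)."""
    starts: dict[str, dict[int, Counter]] = defaultdict(lambda: defaultdict(Counter))
    ends: dict[str, dict[int, Counter]] = defaultdict(lambda: defaultdict(Counter))
    # raw alignments may place a split boundary anywhere inside a junction
    # direct repeat; the canonicalized placements of the same reads cover the
    # repeat-adjacent bases, so they are overlaid for the 100%-coverage check
    fill: dict[str, np.ndarray] = {c: np.zeros(len(v) + 1, dtype=np.int64) for c, v in coverage.items()}
    for ev in cross_evidence:
        e_chrom, e_pos, s_chrom, s_pos = ev.junction
        ends[e_chrom][e_pos][(s_chrom, s_pos)] += 1
        starts[s_chrom][s_pos][(e_chrom, e_pos)] += 1
        for pl in (ev.placement_a, ev.placement_b):
            if pl.chrom in fill and 0 <= pl.start < pl.end <= len(coverage[pl.chrom]):
                fill[pl.chrom][pl.start] += 1
                fill[pl.chrom][pl.end] -= 1
    fill = {c: np.cumsum(d[:-1]) for c, d in fill.items()}

    regions: list[ConfidentRegion] = []
    for chrom in sorted(set(starts) | set(ends)):
        end_positions = sorted(ends[chrom])
        for s_pos in sorted(starts[chrom]):
            nxt = [e for e in end_positions if e > s_pos]
            if not nxt:
                continue
            e_pos = nxt[0]
            if e_pos - s_pos > max_region_len:
                logger.info("region %s:%d-%d rejected: exceeds max_region_len", chrom, s_pos, e_pos)
                continue
            if coverage.get(chrom) is None or len(coverage[chrom]) < e_pos:
                continue
            if (coverage[chrom][s_pos:e_pos] + fill[chrom][s_pos:e_pos]).min() < 1:
                logger.info("region %s:%d-%d rejected: coverage gap", chrom, s_pos, e_pos)
                continue
            left_partner = starts[chrom][s_pos].most_common(1)[0][0]
            right_partner = ends[chrom][e_pos].most_common(1)[0][0]
            regions.append(ConfidentRegion(chrom, s_pos, e_pos, left_partner, right_partner))
    return regions


def assemble_multifragment(
    regions: list[ConfidentRegion],
    cross_evidence: list[JunctionEvidence],
    max_cycle_len: int = 3,
) -> tuple[list[MultiFragmentCircle], list[list[ConfidentRegion]]]:
    """Chain confident regions through their cross-chromosomal junctions into
    circles of 2 or 3 fragments on pairwise distinct chromosomes.

    Returns (circles, longer_cycles); cycles above max_cycle_len are reported
    separately, never merged into the main call set.  Cycles sharing a region
    are all reported, flagged via shares_region.
    """
    support: dict[tuple, set[str]] = defaultdict(set)
    for ev in cross_evidence:
        e_chrom, e_pos, s_chrom, s_pos = ev.junction
        if not ev.is_duplicate:
            support[((e_chrom, e_pos), (s_chrom, s_pos))].add(ev.read_id)
    adj: dict[int, list[int]] = defaultdict(list)
    for i, u in enumerate(regions):
        for j, v in enumerate(regions):
            if i != j and ((u.chrom, u.end), (v.chrom, v.start)) in support:
                adj[i].append(j)

    cycles: list[tuple[int, ...]] = []
    seen: set[frozenset] = set()

    def dfs(path: list[int], limit: int) -> None:
        u = path[-1]
        for v in adj[u]:
            if v == path[0] and len(path) >= 2:
                key = frozenset(path)
                if key not in seen and len({regions[i].chrom for i in path}) == len(path):
                    seen.add(key)
                    cycles.append(tuple(path))
            elif v not in path and len(path) < limit:
                dfs(path + [v], limit)

    for i in range(len(regions)):
        dfs([i], limit=6)

    region_use: Counter = Counter()
    for cyc in cycles:
        for i in cyc:
            region_use[i] += 1

    def canonical(cyc: tuple[int, ...]) -> list[int]:
        keyed = [(regions[i].chrom, regions[i].start, regions[i].end) for i in cyc]
        k = keyed.index(min(keyed))
        return list(cyc[k:]) + list(cyc[:k])

    circles: list[MultiFragmentCircle] = []
    longer: list[list[ConfidentRegion]] = []
    for cyc in cycles:
        order = canonical(cyc)
        frags = [regions[i] for i in order]
        if len(order) > max_cycle_len:
            longer.append(frags)
            continue
        supp = [
            len(support[((frags[i].chrom, frags[i].end), (frags[(i + 1) % len(frags)].chrom, frags[(i + 1) % len(frags)].start))])
            for i in range(len(frags))
        ]
        circles.append(
            MultiFragmentCircle(frags, supp, shares_region=any(region_use[i] > 1 for i in order))
        )
    circles.sort(key=lambda c: [(f.chrom, f.start, f.end) for f in c.fragments])
    return circles, longer


def call_circles(
    sam_path: str | Path,
    genome: ReferenceGenome,
    min_mapq: int = 20,
    min_support: int = 1,
    keep_duplicates: bool = True,
    sample_id: str = "",
):
    """Full calling pipeline for one sample: evidence -> correction -> single-
    fragment calls + multi-fragment circles."""
    evidence, skipped = extract_junction_evidence(sam_path, min_mapq, keep_duplicates)
    evidence = correct_evidence(evidence, genome)
    single_ev, cross_ev = partition_evidence(evidence)
    calls = call_single_fragment(single_ev, genome, min_support, sample_id)
    coverage = compute_coverage(sam_path)
    regions = extract_confident_regions(cross_ev, coverage)
    multi, longer = assemble_multifragment(regions, cross_ev)
    return {
        "calls": calls,
        "multi": multi,
        "longer_cycles": longer,
        "regions": regions,
        "evidence": evidence,
        "skipped": skipped,
    }
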