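"""Circle-sequencing read simulator.

Generates ground-truth eccDNA (single-fragment circles with a bimodal
nucleosome-ladder size distribution, plus two- and three-fragment circles with
fragments on distinct chromosomes), plants flanking direct repeats at the
junctions, and emits already-aligned 150-bp paired-end reads as a
coordinate-sorted SAM file following bwa-mem conventions: a junction-spanning
read becomes a soft-clipped primary alignment plus a supplementary alignment of
the clipped part, cross-referenced through the SA auxiliary field.

Two library chemistries are emulated: ``rca`` (rolling-circle amplification —
the sequenced template is a tandem concatemer of the circle, geometric number
of copies) and ``tagmentation`` (fragments cut directly from the circle, at
most one pass).

When a junction carries a k-bp direct repeat, the reported split boundary is
drawn uniformly among the k+1 sequence-identical offsets, reproducing the
alignment ambiguity that downstream junction correction must undo.  Reads that
wrap a circle more than once (or span two junctions of a multi-fragment
circle) emit the primary plus one supplementary covering the first junction
only; later wraps are soft-clipped away.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import ReferenceGenome

logger = logging.getLogger(__name__)

_COMP = bytes.maketrans(b"ACGTN", b"TGCAN")


class PlacementError(RuntimeError):
    """Raised when a truth circle cannot be placed after bounded retries."""


@dataclass(frozen=True)
class TruthCircle:
    """One ground-truth eccDNA: an ordered cycle of genomic fragments."""

    circle_id: str
    fragments: tuple[tuple[str, int, int, str], ...]  # (chrom, start, end, strand)
    copy_number: int = 1
    planted_repeat_len: int = 0
    chemistry: str = "rca"

    @property
    def length(self) -> int:
        return sum(e - s for _, s, e, _ in self.fragments)

    @property
    def is_single(self) -> bool:
        return len(self.fragments) == 1


@dataclass
class SimParams:
    """Simulation settings; one seed fully determines all outputs."""

    seed: int = 0
    n_single: int = 50
    n_multi2: int = 0
    n_multi3: int = 0
    #: (mode_bp, sd_bp, weight) — nucleosome-ladder modes observed in circle-seq
    size_mixture: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(201.0, 15.0, 0.5), (348.0, 20.0, 0.5)]
    )
    read_len: int = 150
    frag_mean: float = 250.0
    frag_sd: float = 25.0
    depth: float = 30.0  # mean junction-spanning read pairs per circle
    error_rate: float = 0.0
    duplicate_fraction: float = 0.0
    chemistry: str = "rca"
    rca_mean_copies: float = 5.0
    # planted flanking direct repeats: 0 with prob repeat_zero_prob, else
    # uniform on 1..repeat_max (gives ~36% of circles a >=2 bp repeat with the
    # defaults, within the range reported for real circle-seq libraries)
    repeat_zero_prob: float = 0.6
    repeat_max: int = 10

    def __post_init__(self) -> None:
        w = sum(w for _, _, w in self.size_mixture)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("size_mixture weights must sum to 1")
        if self.read_len > self.frag_mean:
            raise ValueError("read_len must not exceed frag_mean")
        if not 0 <= self.repeat_max <= 20:
            raise ValueError("repeat_max must be in [0, 20]")
        if self.chemistry not in ("rca", "tagmentation"):
            raise ValueError(f"unknown chemistry {self.chemistry!r}")


def _sample_size(rng: np.random.Generator, mixture, floor: int = 50) -> int:
    weights = np.array([w for _, _, w in mixture])
    k = rng.choice(len(mixture), p=weights)
    mode, sd, _ = mixture[k]
    return max(floor, int(round(rng.normal(mode, sd))))


_PAD = 40  # bp kept free around each fragment for repeat planting / breakers


def _place_fragment(
    rng: np.random.Generator,
    genome: ReferenceGenome,
    occupied: dict[str, list[tuple[int, int]]],
    size: int,
    exclude_chroms: set[str],
    max_tries: int = 200,
) -> tuple[str, int, int]:
    names = [c for c in genome.chrom_names if c not in exclude_chroms]
    lens = np.array([len(genome.sequences[c]) for c in names], dtype=float)
    probs = lens / lens.sum()
    for _ in range(max_tries):
        chrom = names[rng.choice(len(names), p=probs)]
        L = len(genome.sequences[chrom])
        if L < size + 2 * _PAD:
            continue
        start = int(rng.integers(_PAD, L - size - _PAD + 1))
        end = start + size
        clash = any(start - _PAD < oe and os < end + _PAD for os, oe in occupied[chrom])
        if not clash:
            occupied[chrom].append((start, end))
            return chrom, start, end
    raise PlacementError(f"could not place a {size}-bp fragment after {max_tries} tries")


def _plant_junction(genome: ReferenceGenome, prev_frag, next_frag, k: int) -> None:
    """Edit the genome so the junction prev.end -> next.start carries an exact
    k-bp direct repeat and no accidental extension on either side."""
    pc, _, pe, _ = prev_frag
    nc, ns, _, _ = next_frag
    pseq, nseq = genome.sequences[pc], genome.sequences[nc]
    if k > 0:
        pseq[pe : pe + k] = nseq[ns : ns + k]
    # break leftward extension: base before circle start vs last base before junction
    if ns - 1 >= 0 and nseq[ns - 1] == pseq[pe - 1]:
        nseq[ns - 1] = _other_base(pseq[pe - 1])
    # break rightward extension beyond k
    if pe + k < len(pseq) and ns + k < len(nseq) and pseq[pe + k] == nseq[ns + k]:
        pseq[pe + k] = _other_base(nseq[ns + k])


def _other_base(b: int) -> int:
    return {65: 67, 67: 71, 71: 84, 84: 65}[b]  # A->C->G->T->A


def _sample_repeat_len(rng: np.random.Generator, params: SimParams) -> int:
    if params.repeat_max == 0 or rng.random() < params.repeat_zero_prob:
        return 0
    return int(rng.integers(1, params.repeat_max + 1))


def make_truth_circles(
    genome: ReferenceGenome,
    params: SimParams,
    occupied: dict[str, list[tuple[int, int]]] | None = None,
    id_offset: int = 0,
) -> list[TruthCircle]:
    """Place single- and multi-fragment truth circles on (and into) the genome.

    The genome is edited in place to plant each circle's junction direct
    repeats, so downstream sequence extraction sees exactly the homology the
    truth set declares.  An ``occupied`` interval registry may be passed (and is
    mutated) to place several truth sets on one genome without collisions.
    """
    rng = np.random.default_rng(params.seed)
    if occupied is None:
        occupied = {c: [] for c in genome.chrom_names}
    circles: list[TruthCircle] = []
    cid = id_offset

    def new_circle(n_frag: int) -> TruthCircle:
        nonlocal cid
        k = _sample_repeat_len(rng, params)
        frags: list[tuple[str, int, int, str]] = []
        used: set[str] = set()
        for _ in range(n_frag):
            size = _sample_size(rng, params.size_mixture)
            chrom, s, e = _place_fragment(
                rng, genome, occupied, size, used if n_frag > 1 else set()
            )
            if n_frag > 1:
                used.add(chrom)
            frags.append((chrom, s, e, "+"))
        circle = TruthCircle(
            circle_id=f"c{cid:05d}",
            fragments=tuple(frags),
            planted_repeat_len=k,
            chemistry=params.chemistry,
        )
        cid += 1
        return circle

    if params.n_multi2 and len(genome.chrom_names) < 2:
        raise PlacementError("two-fragment circles need >= 2 chromosomes")
    if params.n_multi3 and len(genome.chrom_names) < 3:
        raise PlacementError("three-fragment circles need >= 3 chromosomes")

    for _ in range(params.n_single):
        circles.append(new_circle(1))
    for _ in range(params.n_multi2):
        circles.append(new_circle(2))
    for _ in range(params.n_multi3):
        circles.append(new_circle(3))

    for c in circles:
        n = len(c.fragments)
        for i in range(n):
            _plant_junction(genome, c.fragments[i], c.fragments[(i + 1) % n], c.planted_repeat_len)
    return circles


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class SamRecord:
    qname: str
    flag: int
    chrom: str
    pos: int  # 0-based
    mapq: int
    cigar: str
    rnext: str
    pnext: int
    seq: str
    sa: str | None = None

    def to_line(self) -> str:
        fields = [
            self.qname,
            str(self.flag),
            self.chrom,
            str(self.pos + 1),
            str(self.mapq),
            self.cigar,
            self.rnext,
            str(self.pnext + 1),
            "0",
            self.seq,
            "I" * len(self.seq),
        ]
        if self.sa:
            fields.append(f"SA:Z:{self.sa}")
        return "\t".join(fields)


def _circle_layout(genome: ReferenceGenome, circle: TruthCircle):
    """Per-base reference coordinates and sequence of one circle copy."""
    chrom_idx = {c: i for i, c in enumerate(genome.chrom_names)}
    ci = np.concatenate([np.full(e - s, chrom_idx[c], dtype=np.int32) for c, s, e, _ in circle.fragments])
    pos = np.concatenate([np.arange(s, e, dtype=np.int64) for c, s, e, _ in circle.fragments])
    seq = b"".join(bytes(genome.sequences[c][s:e]) for c, s, e, _ in circle.fragments)
    return ci, pos, seq


def _read_segments(ci: np.ndarray, pos: np.ndarray, a: int, b: int):
    """Maximal colinear runs of the template interval [a, b) as
    (read_offset, read_end, chrom_idx, ref_start) tuples."""
    c, p = ci[a:b], pos[a:b]
    brk = np.flatnonzero((np.diff(p) != 1) | (np.diff(c) != 0)) + 1
    bounds = [0, *brk.tolist(), b - a]
    return [
        (bounds[i], bounds[i + 1], int(c[bounds[i]]), int(p[bounds[i]]))
        for i in range(len(bounds) - 1)
    ]


def _apply_repeat_offsets(segs, k: int, rng: np.random.Generator):
    """Shift each internal split boundary by a random offset in [0, k],
    emulating where an aligner may place the boundary inside a k-bp repeat."""
    if k == 0 or len(segs) == 1:
        return segs
    out = [list(s) for s in segs]
    for i in range(len(out) - 1):
        j = int(rng.integers(0, k + 1))
        j = min(j, out[i + 1][1] - out[i + 1][0] - 1)  # next segment keeps >= 1 base
        if j <= 0:
            continue
        out[i][1] += j
        out[i + 1][0] += j
        out[i + 1][3] += j
    return [tuple(s) for s in out]


def _cigar(q0: int, q1: int, read_len: int) -> str:
    parts = []
    if q0:
        parts.append(f"{q0}S")
    parts.append(f"{q1 - q0}M")
    if read_len - q1:
        parts.append(f"{read_len - q1}S")
    return "".join(parts)


def simulate_alignments(
    genome: ReferenceGenome,
    truth: list[TruthCircle],
    params: SimParams,
    sam_path: str | Path,
    bed_path: str | Path | None = None,
    fastq_prefix: str | Path | None = None,
) -> dict:
    """Simulate read pairs from the truth circles and write a coordinate-sorted
    SAM file (plus optional truth BED and FASTQ export).

    Returns bookkeeping counts (pairs emitted, junction pairs, duplicate pairs).
    """
    rng = np.random.default_rng(params.seed + 1)
    read_len = params.read_len
    frag_max = int(params.frag_mean + 4 * params.frag_sd)
    records: list[SamRecord] = []
    fastq_reads: list[tuple[str, bytes, bytes]] = []
    stats = {"pairs": 0, "junction_pairs": 0, "duplicate_pairs": 0}

    for circle in truth:
        ci_arr, pos_arr, seq = _circle_layout(genome, circle)
        L = len(seq)
        need = int(np.ceil((frag_max + 1) / L)) + 1
        if circle.chemistry == "rca":
            copies = max(int(rng.geometric(1.0 / params.rca_mean_copies)), need)
        else:
            copies = need
        ci = np.tile(ci_arr, copies)
        pos = np.tile(pos_arr, copies)
        template = seq * copies
        T = len(template)

        target = int(rng.poisson(params.depth))
        got, attempts = 0, 0
        pair_idx = 0
        while got < target and attempts < 60 * target + 200:
            attempts += 1
            flen = int(round(rng.normal(params.frag_mean, params.frag_sd)))
            flen = min(max(flen, read_len), frag_max)
            if circle.chemistry == "tagmentation":
                f0 = int(rng.integers(0, L))
            else:
                f0 = int(rng.integers(0, T - flen + 1))
            reads = [(f0, f0 + read_len, False), (f0 + flen - read_len, f0 + flen, True)]
            is_dup = rng.random() < params.duplicate_fraction
            qname = f"{circle.circle_id}p{pair_idx:05d}"
            pair_idx += 1
            pair_records: list[list[SamRecord]] = []
            crossed = False
            for a, b, is_read2 in reads:
                segs = _read_segments(ci, pos, a, b)
                if len(segs) > 1:
                    crossed = True
                    segs = _apply_repeat_offsets(segs, circle.planted_repeat_len, rng)
                    segs = segs[:2]  # first junction only; later wraps are clipped
                seq_bytes = bytearray(template[a:b])
                if params.error_rate > 0:
                    hits = np.flatnonzero(rng.random(read_len) < params.error_rate)
                    for h in hits:
                        seq_bytes[h] = _other_base(seq_bytes[h])
                pair_records.append(
                    _make_records(genome, segs, bytes(seq_bytes), qname, is_read2, read_len)
                )
                if fastq_prefix is not None:
                    raw = bytes(seq_bytes)
                    if is_read2:
                        raw = raw.translate(_COMP)[::-1]
                    fastq_reads.append((qname, raw, b"2" if is_read2 else b"1"))
            _link_mates(pair_records[0], pair_records[1])
            if is_dup:
                for rec in pair_records[0] + pair_records[1]:
                    rec.flag |= 0x400
                stats["duplicate_pairs"] += 1
            records.extend(pair_records[0] + pair_records[1])
            stats["pairs"] += 1
            if crossed:
                got += 1
                stats["junction_pairs"] += 1

    order = {c: i for i, c in enumerate(genome.chrom_names)}
    records.sort(key=lambda r: (order[r.chrom], r.pos, r.qname, r.flag))
    with open(sam_path, "w", newline="\n") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for c in genome.chrom_names:
            fh.write(f"@SQ\tSN:{c}\tLN:{len(genome.sequences[c])}\n")
        for rec in records:
            fh.write(rec.to_line() + "\n")

    if bed_path is not None:
        write_truth_bed(truth, bed_path)
    if fastq_prefix is not None:
        _write_fastq(fastq_reads, fastq_prefix)
    return stats


def _make_records(genome, segs, seq_bytes, qname, is_read2, read_len) -> list[SamRecord]:
    base_flag = 0x1 | 0x2 | (0x80 if is_read2 else 0x40)
    strand_flag = 0x10 if is_read2 else 0x0
    mate_strand_flag = 0x0 if is_read2 else 0x20
    strand = "-" if is_read2 else "+"
    # primary = longest segment (ties -> first), matching bwa's scoring choice
    primary_i = max(range(len(segs)), key=lambda i: (segs[i][1] - segs[i][0], -i))
    recs = []
    seq = seq_bytes.decode()
    for i, (q0, q1, cidx, rstart) in enumerate(segs):
        flag = base_flag | strand_flag | mate_strand_flag
        if i != primary_i:
            flag |= 0x800
        recs.append(
            SamRecord(
                qname=qname,
                flag=flag,
                chrom=genome.chrom_names[cidx],
                pos=rstart,
                mapq=60,
                cigar=_cigar(q0, q1, read_len),
                rnext="=",
                pnext=0,
                seq=seq,
            )
        )
    if len(recs) == 2:
        for i, other in ((0, 1), (1, 0)):
            o = recs[other]
            recs[i].sa = f"{o.chrom},{o.pos + 1},{strand},{o.cigar},60,0;"
    return recs


def _link_mates(recs1: list[SamRecord], recs2: list[SamRecord]) -> None:
    p1 = next(r for r in recs1 if not r.flag & 0x800)
    p2 = next(r for r in recs2 if not r.flag & 0x800)
    for r in recs1:
        r.rnext, r.pnext = p2.chrom, p2.pos
    for r in recs2:
        r.rnext, r.pnext = p1.chrom, p1.pos


def write_truth_bed(truth: list[TruthCircle], path: str | Path) -> None:
    rows = []
    for c in truth:
        for i, (chrom, s, e, strand) in enumerate(c.fragments):
            rows.append((chrom, s, e, f"{c.circle_id}_f{i}", c.planted_repeat_len, strand, len(c.fragments)))
    rows.sort()
    with open(path, "w", newline="\n") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


def _write_fastq(reads, prefix) -> None:
    prefix = str(prefix)
    with open(prefix + "_1.fastq", "w", newline="\n") as f1, open(
        prefix + "_2.fastq", "w", newline="\n"
    ) as f2:
        for qname, raw, mate in reads:
            fh = f1 if mate == b"1" else f2
            fh.write(f"@{qname}/{mate.decode()}\n{raw.decode()}\n+\n{'I' * len(raw)}\n")
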