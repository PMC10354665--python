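"""Independent brute-force oracles used to validate the pipeline.

These deliberately avoid the package's own calling/correction code paths:
junctions are canonicalized by exhaustive shift search, sequence identity is
checked by direct reference re-extraction, and overlap/abundance counting is
done by quadratic scans.
"""

from __future__ import annotations

import re
from collections import defaultdict

import pysam

_CIG = re.compile(r"(\d+)([MIDNSHP=X])")


def cigar_ops(cigar):
    return [(int(n), op) for n, op in _CIG.findall(cigar)]


def longest_common_prefix_repeat(seq: bytes, start: int, end: int, max_len: int = 20) -> int:
    """Reference oracle for the flanking-direct-repeat length."""
    k = 0
    while k < max_len and end + k < len(seq) and seq[start + k] == seq[end + k]:
        k += 1
    return k


def exhaustive_leftmost_junction(genome, end_chrom, end_pos, start_chrom, start_pos, span=60):
    """Leftmost sequence-identical junction placement by trying every shift."""
    s_seq = genome.sequences[start_chrom]
    e_seq = genome.sequences[end_chrom]

    def valid(delta):
        # shifting by delta is legal iff every intermediate base matches
        lo, hi = min(0, delta), max(0, delta)
        for i in range(lo, hi):
            if not (0 <= start_pos + i < len(s_seq) and 0 <= end_pos + i < len(e_seq)):
                return False
            if s_seq[start_pos + i] != e_seq[end_pos + i]:
                return False
        return True

    best = 0
    for delta in range(-span, 0):
        if valid(delta):
            best = delta
            break
    return end_pos + best, start_pos + best


def brute_force_single_fragment_calls(sam_path, genome, min_mapq=20, min_support=1):
    """Enumerate every (split read, mate) pair straight from the SAM text,
    verify both criteria on reconstructed sequences, canonicalize junctions by
    exhaustive shift search, and group into calls.

    Returns a dict {(chrom, start, end): support} with support = distinct
    non-duplicate read names.
    """
    reads: dict[tuple[str, bool], list[dict]] = defaultdict(list)
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_unmapped:
                continue
            reads[(rec.query_name, rec.is_read1)].append(
                dict(
                    chrom=rec.reference_name,
                    pos=rec.reference_start,
                    end=rec.reference_end,
                    cigar=rec.cigarstring,
                    mapq=rec.mapping_quality,
                    strand="-" if rec.is_reverse else "+",
                    supp=rec.is_supplementary,
                    dup=rec.is_duplicate,
                    seq=rec.query_sequence,
                )
            )

    support: dict[tuple[str, int, int], set[str]] = defaultdict(set)
    counts: dict[tuple[str, int, int], int] = defaultdict(int)
    qnames = sorted({q for q, _ in reads})
    for q in qnames:
        r1, r2 = reads.get((q, True), []), reads.get((q, False), [])
        if not r1 or not r2:
            continue
        for split_side, mate_side in ((r1, r2), (r2, r1)):
            if len(split_side) != 2 or len(mate_side) != 1:
                continue
            mate = mate_side[0]
            ops = cigar_ops(mate["cigar"])
            clips = sum(n for n, op in ops if op in "SH")
            n_match = sum(1 for _, op in ops if op == "M")
            n_other = sum(1 for _, op in ops if op not in "MSH")
            if not (n_match == 1 and n_other == 0 and clips < 5):
                continue
            if mate["mapq"] < min_mapq:
                continue
            segs = []
            for rec in split_side:
                ops = cigar_ops(rec["cigar"])
                lead = ops[0][0] if ops[0][1] in "SH" else 0
                mlen = sum(n for n, op in ops if op in "M=X")
                segs.append((lead, rec["chrom"], rec["pos"], rec["pos"] + mlen, rec["strand"]))
            segs.sort()
            (q0a, ca, sa, ea, sta), (q0b, cb, sb, eb, stb) = segs
            if sta != stb or ca != cb:
                continue
            # circularizing orientation: read runs from circle end back to start
            if not sb < ea:
                continue
            # criterion check on reconstructed sequence: the split read's bases
            # must equal ref[first segment] + ref[second segment]
            seq = split_side[0]["seq"]
            recon = genome.fetch(ca, sa, ea) + genome.fetch(cb, sb, eb)
            if seq is not None and len(recon) == len(seq) and recon != seq:
                continue
            # mate anchored inside the circle (any overlap)
            if mate["chrom"] != ca or mate["end"] <= sb or mate["pos"] >= ea:
                continue
            e_can, s_can = exhaustive_leftmost_junction(genome, ca, ea, cb, sb)
            key = (ca, s_can, e_can)
            counts[key] += 1
            if not (split_side[0]["dup"] or mate["dup"]):
                support[key].add(q)
    return {
        k: len(v) for k, v in support.items() if len(v) >= min_support
    }


def brute_point_labels(ann, chrom, pos, structural):
    """Point-in-interval scan over raw interval lists."""
    labels = set()
    for label, ivs in ann.tracks.items():
        if label == "distal_intergenic":
            continue
        for c, s, e in ivs:
            if c == chrom and s <= pos < e:
                labels.add(label)
                break
    if not labels & set(structural):
        labels.add("distal_intergenic")
    return labels


def brute_gene_counts(calls, genes, support_attr="n_split_support"):
    """Quadratic overlap-and-sum oracle for gene abundance."""
    out = defaultdict(int)
    for g in genes:
        name, chrom, s, e = g
        for c in calls:
            if c.chrom == chrom and c.start < e and s < c.end:
                out[name] += getattr(c, support_attr)
    return dict(out)
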