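import numpy as np
import pytest

from eccprofiler.caller import (
    CircleCall,
    ConfidentRegion,
    JunctionEvidence,
    Placement,
    assemble_multifragment,
    call_single_fragment,
    compute_coverage,
    correct_evidence,
    correct_junction_for_direct_repeat,
    extract_confident_regions,
    extract_junction_evidence,
    format_call_label,
    partition_evidence,
)
from eccprofiler.genome import Gene, ReferenceGenome, make_genome

import oracles
from conftest import simulate_case, write_sam


def _toy_genome(seed=0, length=2000):
    rng = np.random.default_rng(seed)
    seq = bytearray(rng.choice(list(b"ACGT"), size=length).astype(np.uint8).tobytes())
    return ReferenceGenome(["chr1"], {"chr1": seq})


def _split_pair_lines(seq_split, seq_mate):
    """One split read (75M75S primary at 225 + 75S75M supplementary at 100)
    plus a contiguously mapped mate, for a 200-bp circle chr1:[100,300)."""
    return [
        f"q1\t99\tchr1\t226\t60\t75M75S\t=\t151\t0\t{seq_split}\t*\tSA:Z:chr1,101,+,75S75M,60,0;",
        f"q1\t2147\tchr1\t101\t60\t75S75M\t=\t151\t0\t{seq_split}\t*\tSA:Z:chr1,226,+,75M75S,60,0;",
        f"q1\t147\tchr1\t151\t60\t150M\t=\t226\t0\t{seq_mate}\t*",
    ]


@pytest.fixture
def toy_case(tmp_path):
    genome = _toy_genome()
    seq = genome.sequences["chr1"]
    # break accidental junction homology so the call is exactly [100, 300)
    if seq[99] == seq[299]:
        seq[99] = ord("A") if seq[299] != ord("A") else ord("C")
    if seq[100] == seq[300]:
        seq[300] = ord("A") if seq[100] != ord("A") else ord("C")
    seq_split = genome.fetch("chr1", 225, 300) + genome.fetch("chr1", 100, 175)
    seq_mate = genome.fetch("chr1", 150, 300)
    sam = write_sam(tmp_path / "toy.sam", {"chr1": 2000}, _split_pair_lines(seq_split, seq_mate))
    return genome, sam


def test_empty_input_gives_no_evidence(tmp_path):
    sam = write_sam(tmp_path / "e.sam", {"chr1": 1000}, [])
    evidence, skipped = extract_junction_evidence(sam)
    assert evidence == [] and skipped == {}


def test_hand_built_split_pair_yields_one_evidence(toy_case):
    genome, sam = toy_case
    evidence, _ = extract_junction_evidence(sam)
    assert len(evidence) == 1
    ev = evidence[0]
    assert ev.placement_a.end == 300 and ev.placement_b.start == 100
    assert ev.mate_anchor == ("chr1", 150, 300)
    calls = call_single_fragment(correct_evidence(evidence, genome), genome)
    assert [(c.chrom, c.start, c.end) for c in calls] == [("chr1", 100, 300)]


def test_duplicate_flag_handling(toy_case, tmp_path):
    genome, sam = toy_case
    lines = sam.read_text().splitlines()
    body = [ln for ln in lines if not ln.startswith("@")]
    dup_body = []
    for ln in body:
        f = ln.split("\t")
        f[0] = "q2"
        f[1] = str(int(f[1]) | 0x400)
        dup_body.append("\t".join(f))
    sam2 = write_sam(tmp_path / "dup.sam", {"chr1": 2000}, body + dup_body)
    kept, _ = extract_junction_evidence(sam2, keep_duplicates=True)
    dropped, _ = extract_junction_evidence(sam2, keep_duplicates=False)
    assert len(kept) == 2 and len(dropped) == 1
    calls = call_single_fragment(correct_evidence(kept, genome), genome)
    assert calls[0].n_evidence_reads == 2
    assert calls[0].n_split_support == 1  # duplicate-flagged pair excluded


def test_secondary_alignments_always_discarded(toy_case, tmp_path):
    genome, sam = toy_case
    body = [ln for ln in sam.read_text().splitlines() if not ln.startswith("@")]
    f = body[0].split("\t")
    f[0], f[1] = "q_sec", str(int(f[1]) | 0x100)
    sam2 = write_sam(tmp_path / "sec.sam", {"chr1": 2000}, body + ["\t".join(f)])
    evidence, _ = extract_junction_evidence(sam2)
    assert len(evidence) == 1


def test_orphan_supplementary_is_skipped_and_counted(tmp_path):
    genome = _toy_genome()
    seq = genome.fetch("chr1", 100, 250)
    sam = write_sam(
        tmp_path / "o.sam",
        {"chr1": 2000},
        [f"orphan\t2147\tchr1\t101\t60\t75S75M\t=\t151\t0\t{seq}\t*"],
    )
    evidence, skipped = extract_junction_evidence(sam)
    assert evidence == []
    assert skipped["orphan_supplementary"] == 1


def _evidence(chrom, end_pos, start_pos, mate=None):
    return JunctionEvidence(
        read_id="r",
        placement_a=Placement(chrom, end_pos - 75, end_pos, "+"),
        placement_b=Placement(chrom, start_pos, start_pos + 75, "+"),
        mate_anchor=mate or (chrom, start_pos, start_pos + 100),
    )


class TestDirectRepeatCorrection:
    def test_no_homology_is_unchanged(self):
        genome = ReferenceGenome(["chr1"], {"chr1": bytearray(b"ACGT" * 100)})
        # junction end=300, start=100: bases around differ by construction? use
        # an engineered genome where they differ
        seq = bytearray(b"A" * 400)
        seq[99] = ord("C")
        seq[100] = ord("G")
        seq[299] = ord("T")
        seq[300] = ord("T")
        genome = ReferenceGenome(["chr1"], {"chr1": seq})
        ev = _evidence("chr1", 300, 100)
        out = correct_junction_for_direct_repeat(ev, genome, cap=20)
        assert out.junction == ev.junction
        assert out.repeat_shift_window == 0

    def test_all_legal_offsets_canonicalize_identically(self):
        rng = np.random.default_rng(42)
        seq = bytearray(rng.choice(list(b"ACGT"), size=1000).astype(np.uint8).tobytes())
        s, e, k = 200, 500, 4
        seq[e : e + k] = seq[s : s + k]
        seq[s - 1] = {65: 67}.get(seq[e - 1], 65)  # break left extension
        seq[e + k] = {65: 67}.get(seq[s + k], 65)  # break right extension
        genome = ReferenceGenome(["chr1"], {"chr1": seq})
        results = set()
        for offset in range(k + 1):
            ev = _evidence("chr1", e + offset, s + offset)
            out = correct_junction_for_direct_repeat(ev, genome)
            results.add(out.junction)
            assert out.repeat_shift_window == k
        assert len(results) == 1
        assert next(iter(results)) == ("chr1", e, "chr1", s)

    def test_idempotent(self):
        genome, _ = make_genome(2, 1, [60_000])
        ev = _evidence("chr1", 3000, 1000)
        once = correct_junction_for_direct_repeat(ev, genome)
        twice = correct_junction_for_direct_repeat(once, genome)
        assert once == twice

    def test_window_truncates_at_chromosome_edge(self):
        genome = ReferenceGenome(["chr1"], {"chr1": bytearray(b"A" * 200)})
        ev = _evidence("chr1", 150, 2)
        out = correct_junction_for_direct_repeat(ev, genome, cap=100)
        assert out.placement_b.start == 0  # shifted to the edge, never past it


def test_no_evidence_gives_no_calls():
    assert call_single_fragment([], None) == []


def test_cross_chromosomal_evidence_not_called_single():
    ev = JunctionEvidence(
        "r",
        Placement("chr2", 500, 575, "+"),
        Placement("chr1", 100, 175, "+"),
        ("chr1", 100, 250),
    )
    assert call_single_fragment([ev], None) == []
    single, cross = partition_evidence([ev])
    assert single == [] and cross == [ev]


def test_simulated_circle_called_exactly(tmp_path):
    genome, _ = make_genome(17, 1, [60_000])
    from eccprofiler.simulate import SimParams, make_truth_circles, simulate_alignments

    params = SimParams(seed=17, n_single=1, size_mixture=[(500, 1, 1.0)], depth=30)
    truth = make_truth_circles(genome, params)
    sam = tmp_path / "one.sam"
    simulate_alignments(genome, truth, params, sam)
    evidence, _ = extract_junction_evidence(sam)
    calls = call_single_fragment(correct_evidence(evidence, genome), genome)
    chrom, s, e, _ = truth[0].fragments[0]
    assert [(c.chrom, c.start, c.end) for c in calls] == [(chrom, s, e)]
    assert calls[0].direct_repeat_len == truth[0].planted_repeat_len


def test_call_report_label_follows_gene_circle_convention():
    call = CircleCall("chr22", 50_447_496, 50_447_834, 12, 12)
    genes = [Gene("SBF1", "chr22", 50_400_000, 50_500_000, "+")]
    assert format_call_label(call, genes) == "SBF1^circle 50,447,497–50,447,834"


def test_calls_invariant_under_input_order(tmp_path):
    genome, _, _, sam, _ = simulate_case(tmp_path, seed=23, n_single=10, depth=15)
    lines = sam.read_text().splitlines()
    header = [ln for ln in lines if ln.startswith("@")]
    body = [ln for ln in lines if not ln.startswith("@")]
    rng = np.random.default_rng(0)
    shuffled = list(body)
    rng.shuffle(shuffled)
    sam2 = tmp_path / "shuf.sam"
    sam2.write_text("\n".join(header + shuffled) + "\n")
    ev1, _ = extract_junction_evidence(sam)
    ev2, _ = extract_junction_evidence(sam2)
    c1 = call_single_fragment(correct_evidence(ev1, genome), genome)
    c2 = call_single_fragment(correct_evidence(ev2, genome), genome)
    assert c1 == c2


def test_support_never_exceeds_evidence_reads(standard_sample):
    for c in standard_sample["calls"]:
        assert c.n_split_support <= c.n_evidence_reads


def test_oracle_equivalence_on_standard_sample(standard_sample):
    oracle = oracles.brute_force_single_fragment_calls(
        standard_sample["sam"], standard_sample["genome"]
    )
    mine = {
        (c.chrom, c.start, c.end): c.n_split_support for c in standard_sample["calls"]
    }
    assert mine == oracle


class TestMultiFragment:
    def test_no_cross_chromosomal_reads_gives_no_regions(self):
        assert extract_confident_regions([], {"chr1": np.ones(100)}) == []

    def test_planted_two_fragment_circle_recovers_reciprocal_regions(self, tmp_path):
        genome, _, truth, sam, _ = simulate_case(
            tmp_path, seed=31, n_single=0, n_multi2=1, n_multi3=0, depth=30
        )
        evidence, _ = extract_junction_evidence(sam)
        _, cross = partition_evidence(correct_evidence(evidence, genome))
        regions = extract_confident_regions(cross, compute_coverage(sam))
        assert len(regions) == 2
        frag_set = {(f[0], f[1], f[2]) for f in truth[0].fragments}
        assert {(r.chrom, r.start, r.end) for r in regions} == frag_set
        a, b = regions
        assert a.right_partner == (b.chrom, b.start) or a.right_partner == (b.chrom, b.start)
        circles, _ = assemble_multifragment(regions, cross)
        assert len(circles) == 1
        assert {(f.chrom, f.start, f.end) for f in circles[0].fragments} == frag_set

    def test_coverage_gap_rejects_region(self, tmp_path):
        # large fragments so the engineered mid-fragment gap is far from any
        # junction-spanning read placement
        genome, _, truth, sam, _ = simulate_case(
            tmp_path, seed=31, n_single=0, n_multi2=1, n_multi3=0, depth=30,
            size_mixture=[(2000.0, 50.0, 1.0)],
        )
        evidence, _ = extract_junction_evidence(sam)
        _, cross = partition_evidence(correct_evidence(evidence, genome))
        cov = compute_coverage(sam)
        chrom, s, e, _ = truth[0].fragments[0]
        mid = (s + e) // 2
        cov[chrom][mid : mid + 50] = 0  # engineered 50-bp zero-coverage gap
        regions = extract_confident_regions(cross, cov)
        assert all(r.chrom != chrom for r in regions)

    def test_directed_path_without_cycle_gives_no_circle(self):
        r1 = ConfidentRegion("chr1", 0, 100, ("chr3", 0), ("chr2", 0))
        r2 = ConfidentRegion("chr2", 0, 100, ("chr1", 100), ("chr3", 500))
        r3 = ConfidentRegion("chr3", 400, 600, ("chr2", 100), ("chr9", 0))
        ev = [
            JunctionEvidence(
                f"r{i}", Placement(a[0], a[1] - 50, a[1], "+"), Placement(b[0], b[1], b[1] + 50, "+"), (a[0], 0, 10)
            )
            for i, (a, b) in enumerate(
                [(("chr1", 100), ("chr2", 0)), (("chr2", 100), ("chr3", 400))]
            )
        ]
        circles, longer = assemble_multifragment([r1, r2, r3], ev)
        assert circles == [] and longer == []

    def test_reciprocal_pair_is_minimal_cycle(self):
        r1 = ConfidentRegion("chr1", 0, 100, ("chr2", 300), ("chr2", 200))
        r2 = ConfidentRegion("chr2", 200, 300, ("chr1", 100), ("chr1", 0))
        ev = [
            JunctionEvidence(
                "a", Placement("chr1", 50, 100, "+"), Placement("chr2", 200, 250, "+"), ("chr1", 0, 10)
            ),
            JunctionEvidence(
                "b", Placement("chr2", 250, 300, "+"), Placement("chr1", 0, 50, "+"), ("chr2", 200, 210)
            ),
        ]
        circles, _ = assemble_multifragment([r1, r2], ev)
        assert len(circles) == 1
        assert circles[0].junction_support == [1, 1]
        # canonical rotation: lexicographically smallest fragment first
        assert circles[0].fragments[0].chrom == "chr1"

    def test_multifragment_recovery_with_exact_boundaries(self, tmp_path):
        genome, _, truth, sam, _ = simulate_case(
            tmp_path, seed=37, n_single=5, n_multi2=6, n_multi3=3, depth=30
        )
        evidence, _ = extract_junction_evidence(sam)
        _, cross = partition_evidence(correct_evidence(evidence, genome))
        regions = extract_confident_regions(cross, compute_coverage(sam))
        circles, _ = assemble_multifragment(regions, cross)
        truth_sets = {
            frozenset((f[0], f[1], f[2]) for f in c.fragments)
            for c in truth
            if len(c.fragments) > 1
        }
        found_sets = {
            frozenset((f.chrom, f.start, f.end) for f in c.fragments) for c in circles
        }
        assert len(truth_sets & found_sets) >= 0.9 * len(truth_sets)
        # no chimeric cycles mixing fragments of different truth circles
        assert not (found_sets - truth_sets)
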