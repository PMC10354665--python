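import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose oracles.py

from eccprofiler.caller import call_circles
from eccprofiler.genome import make_genome
from eccprofiler.simulate import SimParams, make_truth_circles, simulate_alignments


def simulate_case(out_dir: Path, seed: int = 7, n_chrom: int = 3, chrom_len: int = 100_000, **params):
    """Fresh genome + truth set + simulated SAM in out_dir."""
    genome, ann = make_genome(seed, n_chrom, [chrom_len] * n_chrom)
    p = SimParams(seed=seed, **params)
    truth = make_truth_circles(genome, p)
    sam = Path(out_dir) / "reads.sam"
    stats = simulate_alignments(genome, truth, p, sam, Path(out_dir) / "truth.bed")
    return genome, ann, truth, sam, stats


@pytest.fixture(scope="session")
def standard_sample(tmp_path_factory):
    """One simulated library (singles + multi-fragment circles + duplicates)
    with the full calling pipeline already run; shared by read-only tests."""
    out = tmp_path_factory.mktemp("std")
    genome, ann, truth, sam, stats = simulate_case(
        out, seed=7, n_single=40, n_multi2=5, n_multi3=3, depth=30, duplicate_fraction=0.1
    )
    res = call_circles(sam, genome)
    return {
        "genome": genome,
        "ann": ann,
        "truth": truth,
        "sam": sam,
        "sim_stats": stats,
        **res,
    }


def write_sam(path: Path, chrom_lengths: dict[str, int], lines: list[str]) -> Path:
    with open(path, "w", newline="\n") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for c, L in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{c}\tLN:{L}\n")
        for line in lines:
            fh.write(line + "\n")
    return path
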