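# eccprofiler

Detection and characterization of **extrachromosomal circular DNA (eccDNA)**
from paired-end sequencing alignments.

Small chromosome-derived DNA circles (typically a few hundred bp, with a
nucleosome-ladder size distribution) are abundant in tissues such as placenta
and in cell-free plasma, and their loci, sizes and junction features carry
information about the tissue of origin. `eccprofiler` implements the
split-read calling strategy used for circle-sequencing libraries, together
with the downstream profiling and enrichment analyses, and ships a simulator
of circle-seq libraries so the whole pipeline can be validated end to end
against planted ground truth.

## What it computes

**Circle calling.** A candidate junction is a read pair in which one read maps
uniquely and contiguously (the circle body anchor) while the other is a split
read: a soft-clipped primary alignment plus a supplementary alignment of the
clipped part, linked through the standard `SA` field. For a single-fragment
circle the split read runs from the circle end back to its start, so the
second split segment's start is the circle start *s* and the first segment's
end is the circle end *e*; the call is the interval [*s*, *e*).

**Direct-repeat junction correction.** If the k bases at the circle start
equal the k bases immediately after the circle end (a flanking direct repeat,
i.e. junction microhomology), the aligner may place the split boundary at any
of the k+1 sequence-identical offsets. Every junction is canonicalized to the
leftmost offset by extending exact sequence matches across both breakpoints,
so support for one physical junction always groups at one coordinate pair.
Duplicate-flagged reads are kept for junction discovery but excluded from the
quantitative support count.

**Multi-fragment circles.** Cross-chromosomal split reads define *confident
regions*: intervals with 100% read coverage whose both ends are junction
breakpoints joined to a different chromosome. Regions are chained through
their junctions into directed cycles; simple cycles of two or three fragments
on distinct chromosomes are reported as multi-chromosomal-fragment eccDNA.

**Profiling and enrichment.**
- size distributions: median, "shorter-than" quantiles and modal sizes
  (Gaussian-smoothed 1-bp histogram);
- junction features: flanking direct-repeat length (largest k with
  `genome[s:s+k] == genome[e:e+k]`), repeat fractions by size stratum, and
  end-nucleotide composition by size class;
- genome distribution in 1-Mb bins, compared between call sets with a
  two-sample Kolmogorov–Smirnov test;
- per-class junction enrichment with double normalization:
  `score = (loci in class / total loci) / (class bp / genome bp)`, which is 1
  in expectation under uniform placement;
- enhancer overlap of multi-chromosomal joined regions against a
  length-matched random-region null, tested with the **exact** one-tailed
  Wilcoxon signed-rank test (all 2^n sign assignments enumerated; with 5
  samples all above the null, p = 1/32 = 0.031);
- gene-level abundance matrices from supportive split reads (counts per
  million total split reads), recurrence sets ("present in at least two
  samples"), biomarker gene-set intersections, and export of the integer count
  matrix plus 150-bp breakpoint-flank FASTA (50 bp inside + 100 bp outside
  each breakpoint) for external differential-abundance and motif tools.

## Worked example

```python
from pathlib import Path
from eccprofiler.genome import make_genome
from eccprofiler.simulate import SimParams, make_truth_circles, simulate_alignments
from eccprofiler.caller import call_circles
from eccprofiler.features import size_profile, repeat_fraction_by_size

out = Path("demo"); out.mkdir(exist_ok=True)
genome, ann = make_genome(seed=1, n_chrom=3, lengths=[200_000] * 3)
params = SimParams(seed=1, n_single=300, n_multi2=10, n_multi3=5, depth=30)
truth = make_truth_circles(genome, params)
stats = simulate_alignments(genome, truth, params, out / "reads.sam", out / "truth.bed")
print(f"simulated {stats['pairs']} read pairs ({stats['junction_pairs']} junction-spanning)")

res = call_circles(out / "reads.sam", genome)
print(f"{len(res['calls'])} single-fragment calls, {len(res['multi'])} multi-fragment circles")

prof = size_profile(res["calls"])
print(f"median size {prof.median} bp; top size modes {sorted(prof.peaks[:2])}")
rep = repeat_fraction_by_size(res["calls"], genome)
print(f"fraction with >=2 bp junction direct repeats: {rep.fraction_ge2:.3f}")
```

prints

```
simulated 12431 read pairs (9424 junction-spanning)
300 single-fragment calls, 15 multi-fragment circles
median size 325 bp; top size modes [200, 350]
fraction with >=2 bp junction direct repeats: 0.337
```

All 300 planted single-fragment circles and all 15 planted multi-fragment
circles are recovered at exact breakpoints; the recovered size modes match the
simulated 201/348-bp bimodal mixture and the repeat fraction matches the
simulator's planted-repeat distribution (~36% of circles get a ≥2 bp repeat).

The same stages are available from the shell:

```bash
eccprofiler simulate --seed 1 --out sim/
eccprofiler call --sam sim/reads.sam --ref sim/genome.fa --out calls/
eccprofiler features --calls calls/calls_single.tsv --ref sim/genome.fa --out feat/
eccprofiler run --config config.yaml --out out/     # full pipeline, reruns are byte-identical
```

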