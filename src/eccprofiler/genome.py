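"""Toy reference genomes with internally consistent annotation tracks.

A :class:`ReferenceGenome` holds mutable chromosome sequences (the circle
simulator edits them to plant junction direct repeats).  :func:`make_genome`
additionally emits an :class:`AnnotationSet` with genes (exon/intron/UTR
structure on both strands), CpG islands, labelled repeat elements and
enhancers, plus the derived tracks used for junction classification:
promoters (2 kb upstream of genes), immediate downstream regions (2 kb
downstream), 2-kb CpG-island flanks, and distal intergenic regions (the
complement of all of the above).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_GENE_ID_RE = re.compile(r'gene_id "([^"]+)"')

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: repeat-element class vocabulary used by the simulator's repeat track
REPEAT_CLASSES = ("LINE", "SINE/Alu", "SINE/MIR", "LTR/ERVL", "simple_repeat", "srpRNA")

GENIC_CLASSES = ("5'UTR", "exon", "intron", "3'UTR")
DERIVED_CLASSES = ("promoter_2kb", "downstream_2kb", "CpG_up2kb", "CpG_down2kb")


class GenomeError(ValueError):
    pass


@dataclass
class ReferenceGenome:
    """Chromosome names, lengths and mutable A/C/G/T sequences."""

    chrom_names: list[str]
    sequences: dict[str, bytearray]

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise GenomeError("chromosome names must be unique")
        for name in self.chrom_names:
            seq = self.sequences[name]
            if not set(seq) <= set(b"ACGTN"):
                raise GenomeError(f"{name}: alphabet outside ACGTN")

    @property
    def lengths(self) -> dict[str, int]:
        return {c: len(self.sequences[c]) for c in self.chrom_names}

    @property
    def total_bp(self) -> int:
        return sum(len(self.sequences[c]) for c in self.chrom_names)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if start < 0 or end > len(self.sequences[chrom]):
            raise GenomeError(f"fetch {chrom}:{start}-{end} out of bounds")
        return self.sequences[chrom][start:end].decode()

    def base(self, chrom: str, pos: int) -> str:
        return chr(self.sequences[chrom][pos])

    def write_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w", newline="\n") as fh:
            for chrom in self.chrom_names:
                fh.write(f">{chrom}\n")
                seq = self.sequences[chrom]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width].decode() + "\n")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceGenome":
        names: list[str] = []
        seqs: dict[str, bytearray] = {}
        cur: bytearray | None = None
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    name = line[1:].split()[0]
                    names.append(name)
                    cur = bytearray()
                    seqs[name] = cur
                else:
                    assert cur is not None, "sequence before FASTA header"
                    cur.extend(line.upper().encode())
        return cls(names, seqs)


@dataclass
class Gene:
    name: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: tuple[int, int] | None = None
    utr3: tuple[int, int] | None = None


@dataclass
class AnnotationSet:
    """Interval tracks keyed by class label; intervals are (chrom, start, end)."""

    genes: list[Gene]
    tracks: dict[str, list[tuple[str, int, int]]]
    chrom_lengths: dict[str, int]

    def classes(self) -> list[str]:
        return list(self.tracks)

    def coverage_bp(self, label: str) -> int:
        """Merged (deduplicated) base-pair coverage of one class."""
        total = 0
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in self.tracks[label]:
            by_chrom.setdefault(chrom, []).append((s, e))
        for ivs in by_chrom.values():
            total += sum(e - s for s, e in merge_intervals(ivs))
        return total

    def write_bed(self, label: str, path: str | Path) -> None:
        rows = sorted(self.tracks[label])
        with open(path, "w", newline="\n") as fh:
            for chrom, s, e in rows:
                fh.write(f"{chrom}\t{s}\t{e}\t{label}\t0\t.\n")

    def write_gtf(self, path: str | Path) -> None:
        with open(path, "w", newline="\n") as fh:
            for g in sorted(self.genes, key=lambda g: (g.chrom, g.start)):
                attrs = f'gene_id "{g.name}"; gene_name "{g.name}";'
                fh.write(
                    f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )
                for s, e in g.exons:
                    fh.write(
                        f"{g.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
                    )
                for feat, iv in (("five_prime_utr", g.utr5), ("three_prime_utr", g.utr3)):
                    if iv is not None:
                        fh.write(
                            f"{g.chrom}\tsim\t{feat}\t{iv[0] + 1}\t{iv[1]}\t.\t{g.strand}\t.\t{attrs}\n"
                        )


def read_gtf_genes(path: str | Path) -> list[Gene]:
    """Gene records (gene feature lines with a gene_id attribute) from a GTF."""
    genes: list[Gene] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            m = _GENE_ID_RE.search(f[8])
            name = m.group(1) if m else f"{f[0]}:{f[3]}"
            genes.append(Gene(name, f[0], int(f[3]) - 1, int(f[4]), f[6]))
    return genes


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def complement_intervals(
    intervals: list[tuple[int, int]], length: int
) -> list[tuple[int, int]]:
    out = []
    pos = 0
    for s, e in merge_intervals([(max(0, s), min(length, e)) for s, e in intervals]):
        if s > pos:
            out.append((pos, s))
        pos = max(pos, e)
    if pos < length:
        out.append((pos, length))
    return out


def _random_sequence(rng: np.random.Generator, length: int) -> bytearray:
    return bytearray(_BASES[rng.integers(0, 4, size=length)].tobytes())


def derive_tracks(
    genes: list[Gene],
    cpg: list[tuple[str, int, int]],
    chrom_lengths: dict[str, int],
    flank: int = 2000,
) -> dict[str, list[tuple[str, int, int]]]:
    """Promoter/downstream/CpG-flank tracks plus the distal-intergenic complement.

    Promoters are strand-aware: 2 kb upstream of the transcription start (to the
    right of the gene on the minus strand).
    """
    promoters, downstream = [], []
    for g in genes:
        L = chrom_lengths[g.chrom]
        if g.strand == "+":
            promoters.append((g.chrom, max(0, g.start - flank), g.start))
            downstream.append((g.chrom, g.end, min(L, g.end + flank)))
        else:
            promoters.append((g.chrom, g.end, min(L, g.end + flank)))
            downstream.append((g.chrom, max(0, g.start - flank), g.start))
    cpg_up = [(c, max(0, s - flank), s) for c, s, e in cpg]
    cpg_down = [(c, e, min(chrom_lengths[c], e + flank)) for c, s, e in cpg]

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    for g in genes:
        occupied[g.chrom].append((g.start, g.end))
    for track in (promoters, downstream, cpg, cpg_up, cpg_down):
        for c, s, e in track:
            occupied[c].append((s, e))
    distal = []
    for c, L in chrom_lengths.items():
        for s, e in complement_intervals(occupied[c], L):
            distal.append((c, s, e))
    return {
        "promoter_2kb": promoters,
        "downstream_2kb": downstream,
        "CpG_up2kb": cpg_up,
        "CpG_down2kb": cpg_down,
        "distal_intergenic": distal,
    }


def make_genome(
    seed: int,
    n_chrom: int = 3,
    lengths: list[int] | None = None,
) -> tuple[ReferenceGenome, AnnotationSet]:
    """Random ACGT genome plus internally consistent annotation tracks.

    Chromosomes must be at least 50 kb so that genes, their 2-kb flanks and
    simulated circles all fit without clipping.
    """
    if n_chrom < 1:
        raise GenomeError("n_chrom must be >= 1")
    if lengths is None:
        lengths = [100_000] * n_chrom
    if len(lengths) != n_chrom:
        raise GenomeError("lengths must have n_chrom entries")
    if any(L < 50_000 for L in lengths):
        raise GenomeError("chromosome lengths must be >= 50 kb")

    rng = np.random.default_rng(seed)
    names = [f"chr{i + 1}" for i in range(n_chrom)]
    genome = ReferenceGenome(names, {n: _random_sequence(rng, L) for n, L in zip(names, lengths)})

    genes: list[Gene] = []
    cpg: list[tuple[str, int, int]] = []
    repeats: dict[str, list[tuple[str, int, int]]] = {c: [] for c in REPEAT_CLASSES}
    enhancers: list[tuple[str, int, int]] = []
    gi = 0
    for chrom, L in zip(names, lengths):
        # genes every ~12 kb, 2.5 kb margins for promoter/downstream flanks
        pos = 3000
        while pos + 9000 < L - 3000:
            glen = int(rng.integers(2000, 7001))
            strand = "+" if rng.random() < 0.5 else "-"
            gs, ge = pos, pos + glen
            n_ex = int(rng.integers(2, 5))
            bounds = np.sort(rng.choice(np.arange(gs + 100, ge - 100), size=2 * n_ex - 2, replace=False))
            cuts = [gs, *bounds.tolist(), ge]
            exons = [(cuts[i], cuts[i + 1]) for i in range(0, len(cuts) - 1, 2)]
            utr_len = 200
            if strand == "+":
                utr5 = (gs, min(gs + utr_len, exons[0][1]))
                utr3 = (max(ge - utr_len, exons[-1][0]), ge)
            else:
                utr5 = (max(ge - utr_len, exons[-1][0]), ge)
                utr3 = (gs, min(gs + utr_len, exons[0][1]))
            genes.append(Gene(f"GENE{gi}", chrom, gs, ge, strand, exons, utr5, utr3))
            gi += 1
            pos = ge + int(rng.integers(5000, 9001))
        n_cpg = max(1, L // 25_000)
        for s in rng.integers(0, L - 1200, size=n_cpg):
            cpg.append((chrom, int(s), int(s) + int(rng.integers(300, 1200))))
        for cls in REPEAT_CLASSES:
            for s in rng.integers(0, L - 600, size=max(1, L // 30_000)):
                repeats[cls].append((chrom, int(s), int(s) + int(rng.integers(150, 600))))
        for s in rng.integers(0, L - 2100, size=max(1, L // 20_000)):
            enhancers.append((chrom, int(s), int(s) + int(rng.integers(300, 2100))))

    chrom_lengths = dict(zip(names, lengths))
    tracks: dict[str, list[tuple[str, int, int]]] = {
        "exon": [(g.chrom, s, e) for g in genes for s, e in g.exons],
        "intron": [],
        "5'UTR": [(g.chrom, *g.utr5) for g in genes if g.utr5],
        "3'UTR": [(g.chrom, *g.utr3) for g in genes if g.utr3],
        "CpG_island": cpg,
        "enhancer": enhancers,
    }
    for g in genes:
        body = complement_intervals([(s - g.start, e - g.start) for s, e in g.exons], g.end - g.start)
        tracks["intron"].extend((g.chrom, g.start + s, g.start + e) for s, e in body)
    tracks.update({f"repeat:{c}": ivs for c, ivs in repeats.items()})
    tracks.update(derive_tracks(genes, cpg, chrom_lengths))

    for label, ivs in tracks.items():
        for chrom, s, e in ivs:
            if s < 0 or e > chrom_lengths[chrom]:
                raise GenomeError(f"{label} interval {chrom}:{s}-{e} out of bounds")
    return genome, AnnotationSet(genes, tracks, chrom_lengths)
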