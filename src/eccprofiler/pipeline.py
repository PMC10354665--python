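"""End-to-end pipeline orchestration.

A single YAML config drives: genome + annotation simulation, per-sample read
simulation, circle calling, size/repeat/end-base profiling, genome binning and
element enrichment, the enhancer-overlap test on multi-chromosomal joined
regions, differential-input export and recurrence/biomarker analysis.  Every
stage is seeded from the config seed, and a rerun with an identical config is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import caller, differential, enrichment, features
from .genome import make_genome
from .simulate import SimParams, make_truth_circles, simulate_alignments

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "genome": {"n_chrom": 3, "lengths": [100_000, 100_000, 100_000]},
    "simulate": {
        "n_single": 60,
        "n_multi2": 6,
        "n_multi3": 2,
        "depth": 30,
        "chemistry": "rca",
    },
    "groups": {"case": 2, "control": 2},
    "shared_per_group": {"n_single": 8},
    "call": {"min_mapq": 20, "min_support": 1, "keep_duplicates": True},
    "enhancer_test": {"n_draws": 5},
    "recurrent": {"min_samples": 2, "tolerance_bp": 0},
}


class ConfigError(ValueError):
    pass


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        cfg = path_or_dict
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (cfg or {}).items():
        if isinstance(val, dict) and isinstance(merged.get(key), dict):
            merged[key].update(val)
        else:
            merged[key] = val
    if "genome" not in merged and "reference" not in merged:
        raise ConfigError("config must name a reference FASTA or a genome simulation block")
    if merged.get("reference") is not None and not Path(merged["reference"]).exists():
        raise ConfigError(f"reference FASTA not found: {merged['reference']}")
    return merged


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def run_pipeline(config, out_dir: str | Path) -> dict:
    """Run every stage in dependency order; returns a manifest of outputs."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    genome, ann = make_genome(seed, cfg["genome"]["n_chrom"], cfg["genome"]["lengths"])
    genome.write_fasta(out / "genome.fa")
    ann.write_gtf(out / "genes.gtf")
    for label in ("CpG_island", "enhancer"):
        ann.write_bed(label, out / f"{label}.bed")

    samples: list[str] = []
    groups: dict[str, str] = {}
    i = 0
    for grp in sorted(cfg["groups"]):
        for _ in range(int(cfg["groups"][grp])):
            sid = f"{grp}{i}"
            samples.append(sid)
            groups[sid] = grp
            i += 1

    calls_by_sample: dict[str, list[caller.CircleCall]] = {}
    totals: dict[str, int] = {}
    joined_regions: dict[str, list] = {}
    manifest: dict = {"config": cfg, "samples": {}}
    group_ids = {g: k for k, g in enumerate(sorted(cfg["groups"]))}
    for j, sid in enumerate(samples):
        params = SimParams(seed=seed * 1000 + j + 1, **cfg["simulate"])
        # each sample draws its own circles on a private copy of the genome;
        # circles shared within a group (recurrence signal) are planted first
        # from the group seed, so they land identically in every group member
        sample_genome, _ = make_genome(seed, cfg["genome"]["n_chrom"], cfg["genome"]["lengths"])
        occupied = {c: [] for c in sample_genome.chrom_names}
        shared_params = SimParams(
            seed=seed * 100 + group_ids[groups[sid]] + 1,
            **{**cfg["simulate"], "n_multi2": 0, "n_multi3": 0, **cfg["shared_per_group"]},
        )
        truth = make_truth_circles(sample_genome, shared_params, occupied)
        truth += make_truth_circles(sample_genome, params, occupied, id_offset=len(truth))
        sam = out / f"{sid}.sam"
        stats = simulate_alignments(sample_genome, truth, params, sam, out / f"{sid}.truth.bed")
        res = caller.call_circles(
            sam,
            sample_genome,
            min_mapq=cfg["call"]["min_mapq"],
            min_support=cfg["call"]["min_support"],
            keep_duplicates=cfg["call"]["keep_duplicates"],
            sample_id=sid,
        )
        calls_by_sample[sid] = res["calls"]
        totals[sid] = max(1, len(res["evidence"]))
        joined_regions[sid] = [(r.chrom, r.start, r.end) for r in res["regions"]]
        _write_tsv(
            pd.DataFrame(
                [
                    (c.chrom, c.start, c.end, f"{sid}_ecc{k}", c.n_split_support, c.n_evidence_reads, c.direct_repeat_len)
                    for k, c in enumerate(res["calls"])
                ],
                columns=["chrom", "start", "end", "name", "n_split_support", "n_evidence_reads", "direct_repeat_len"],
            ),
            out / f"{sid}.calls.tsv",
        )
        _write_tsv(
            pd.DataFrame(
                [
                    (k, f.chrom, f.start, f.end, supp)
                    for k, mc in enumerate(res["multi"])
                    for f, supp in zip(mc.fragments, mc.junction_support)
                ],
                columns=["cycle_id", "chrom", "start", "end", "junction_support"],
            ),
            out / f"{sid}.multi.tsv",
        )
        manifest["samples"][sid] = {
            "sim": stats,
            "n_calls": len(res["calls"]),
            "n_multi": len(res["multi"]),
            "sam_hash": _file_hash(sam),
        }

        if res["calls"]:
            prof = features.size_profile(res["calls"])
            _write_tsv(
                pd.DataFrame({"size": prof.histogram()[0], "count": prof.histogram()[1]}),
                out / f"{sid}.size_hist.tsv",
            )
            rep = features.repeat_fraction_by_size(res["calls"], sample_genome)
            _write_tsv(rep.by_size_bin, out / f"{sid}.repeat_profile.tsv")
            _write_tsv(
                features.end_nucleotide_composition(res["calls"], sample_genome),
                out / f"{sid}.end_bases.tsv",
            )
            bins = enrichment.bin_distribution(res["calls"], sample_genome.lengths, bin_width=50_000)
            _write_tsv(bins.table, out / f"{sid}.bins.tsv")
            _write_tsv(
                enrichment.element_enrichment(res["calls"], ann), out / f"{sid}.element_enrichment.tsv"
            )
            differential.export_flank_fasta(res["calls"], sample_genome, out / f"{sid}.flanks.fa")

    enh = enrichment.enhancer_enrichment_test(
        {s: r for s, r in joined_regions.items() if r},
        ann.tracks["enhancer"],
        genome.lengths,
        n_draws=int(cfg["enhancer_test"]["n_draws"]),
        seed=seed + 17,
    ) if any(joined_regions.values()) else None
    if enh is not None:
        with open(out / "enhancer_test.json", "w", newline="\n") as fh:
            json.dump(
                {
                    "observed": enh.observed,
                    "null_mean": enh.null_summary,
                    "p_value": enh.test.p_value,
                    "min_attainable_p": enh.min_attainable_p,
                },
                fh,
                sort_keys=True,
                indent=2,
            )
            fh.write("\n")

    matrix = differential.gene_abundance(calls_by_sample, ann.genes, totals)
    differential.export_differential_inputs(matrix, groups, out / "counts.tsv", out / "design.tsv")
    recurrent = differential.recurrent_eccdna(
        calls_by_sample,
        groups,
        min_samples=int(cfg["recurrent"]["min_samples"]),
        tolerance_bp=int(cfg["recurrent"]["tolerance_bp"]),
        genes=ann.genes,
    )
    for grp, rset in recurrent.items():
        with open(out / f"recurrent_{grp}.txt", "w", newline="\n") as fh:
            for chrom, s, e in rset.members:
                fh.write(f"{chrom}\t{s}\t{e}\n")
        with open(out / f"recurrent_{grp}_genes.txt", "w", newline="\n") as fh:
            for g in sorted(rset.gene_set):
                fh.write(g + "\n")

    with open(out / "manifest.json", "w", newline="\n") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=2, default=str)
        fh.write("\n")
    return manifest
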