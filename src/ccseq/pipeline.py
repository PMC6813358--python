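"""Configuration-driven pipeline runner with a machine-readable run log.

A YAML config names the stages to run and their parameters; unknown keys
are rejected so typos fail before any work starts, and every stochastic
stage carries an explicit seed so a config reproduces its outputs
byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import yaml

from ccseq import fileio
from ccseq.calibration import to_hpm
from ccseq.cognate import fractionate_map
from ccseq.signal_analysis import call_peaks
from ccseq.simulate import (
    ReadSimConfig,
    make_genome,
    random_cleavage_model,
    simulate_break_map,
    simulate_read_pairs,
)
from ccseq.terminal_mapping import apply_region_mask, map_read_pairs

log = logging.getLogger(__name__)

_SCHEMA: dict[str, set[str]] = {
    "": {"schema_version", "output_dir", "simulate", "map", "normalize", "cognate", "peaks"},
    "simulate": {
        "seed", "genome_length", "gc", "n_sites", "overhang", "ssb_w_prob",
        "ssb_c_prob", "depth", "read_length", "frag_mean", "frag_sd",
        "terminal_mismatch_prob", "indel_prob",
    },
    "map": {"sam", "library_mode", "mapq_min", "max_end_mismatch", "mask_bed", "mask_mode"},
    "normalize": {"enabled"},
    "cognate": {"offset", "alpha", "hi", "min_total"},
    "peaks": {"threshold"},
}

_NEEDS_SEED = {"simulate"}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    validate_config(config)
    return config


def validate_config(config: dict) -> None:
    unknown = set(config) - _SCHEMA[""]
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for stage, allowed in _SCHEMA.items():
        if not stage or stage not in config:
            continue
        block = config[stage] or {}
        extra = set(block) - allowed
        if extra:
            raise ValueError(f"unknown keys in {stage!r} block: {sorted(extra)}")
        if stage in _NEEDS_SEED and "seed" not in block:
            raise ValueError(f"stage {stage!r} requires an explicit seed")
    if "output_dir" not in config:
        raise ValueError("config requires output_dir")
    if "map" in config and "simulate" not in config and "sam" not in (config["map"] or {}):
        raise ValueError("map stage requires 'sam' unless a simulate stage provides reads")


def run_pipeline(config: dict) -> dict:
    """Run the configured stages; returns the run log (also written to disk)."""
    validate_config(config)
    outdir = Path(config["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    run_log: dict = {
        "started": datetime.now(timezone.utc).isoformat(),
        "config": config,
        "stages": [],
    }

    def record(stage: str, **info) -> None:
        run_log["stages"].append(
            {"stage": stage, "time": datetime.now(timezone.utc).isoformat(), **info}
        )

    sam_path = None
    genome = None
    if "simulate" in config:
        p = dict(config["simulate"])
        genome = make_genome(p.get("genome_length", 100_000), p.get("gc", 0.40), p["seed"])
        model = random_cleavage_model(
            genome,
            n_sites=p.get("n_sites", 200),
            overhang=p.get("overhang", 4),
            ssb_w_prob=p.get("ssb_w_prob", 0.0),
            ssb_c_prob=p.get("ssb_c_prob", 0.0),
            seed=p["seed"] + 1,
        )
        truth = simulate_break_map(model, depth=p.get("depth", 1.0), seed=p["seed"] + 2)
        rc = ReadSimConfig(
            read_length=p.get("read_length", 75),
            frag_mean=p.get("frag_mean", 350.0),
            frag_sd=p.get("frag_sd", 50.0),
            terminal_mismatch_prob=p.get("terminal_mismatch_prob", 0.0),
            indel_prob=p.get("indel_prob", 0.0),
            seed=p["seed"] + 3,
        )
        records = simulate_read_pairs(truth, genome, rc)
        sam_path = outdir / "simulated.sam"
        fileio.write_sam(records, genome.contig_lengths(), sam_path)
        fileio.write_fasta(genome.contigs, outdir / "genome.fa")
        fileio.write_two_strand_tsv(truth, outdir / "truth.tsv")
        record("simulate", n_sites=len(model.sites), n_pairs=len(records) // 2)

    bmap = None
    if "map" in config:
        p = dict(config.get("map") or {})
        path = p.get("sam", sam_path)
        pairs = fileio.read_alignments(path)
        bmap, stats = map_read_pairs(
            pairs,
            library_mode=p.get("library_mode", "single"),
            mapq_min=p.get("mapq_min", 0),
            max_end_mismatch=p.get("max_end_mismatch", 1),
        )
        if "mask_bed" in p:
            mask = fileio.read_bed_intervals(p["mask_bed"])
            bmap = apply_region_mask(bmap, mask, p.get("mask_mode", "exclude"))
        fileio.write_two_strand_tsv(bmap, outdir / "breakmap.tsv")
        record("map", **stats.as_dict())

    track = None
    if bmap is not None and (config.get("normalize") or {}).get("enabled", True):
        track = to_hpm(bmap)
        fileio.write_bedgraph(track, outdir / "watson.bedgraph", "W")
        fileio.write_bedgraph(track, outdir / "crick.bedgraph", "C")
        record("normalize", total_mapped_pairs=track.total_mapped_pairs)

    if "cognate" in config and bmap is not None:
        p = dict(config.get("cognate") or {})
        result = fractionate_map(
            bmap,
            offset=p.get("offset", 3),
            alpha=p.get("alpha", 0.05),
            hi=p.get("hi", 0.95),
            min_total=p.get("min_total", 8),
        )
        result.sites.to_csv(outdir / "cognate_sites.tsv", sep="\t", index=False)
        with open(outdir / "cognate_summary.json", "w") as fh:
            json.dump(
                {"n_tested": result.n_tested, "percentages": result.percentages},
                fh,
                indent=2,
            )
        record("cognate", n_tested=result.n_tested, **result.percentages)

    if "peaks" in config and track is not None:
        p = dict(config.get("peaks") or {})
        peaks = call_peaks(track, threshold=p.get("threshold", 0.05))
        with open(outdir / "peaks.tsv", "w") as fh:
            fh.write("contig\tpos\thpm\n")
            for contig, pos, v in peaks:
                fh.write(f"{contig}\t{pos}\t{v:g}\n")
        record("peaks", n_peaks=len(peaks))

    run_log["finished"] = datetime.now(timezone.utc).isoformat()
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, default=str)
    return run_log
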