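"""Linear in-process pipeline: filter → tag → phase-sv → phase-meth →
trio → stats, with fail-fast input validation and a JSON run manifest.

Each stage is optional (enable exactly the subparts you need); a stage
enabled without its inputs aborts before anything runs. The manifest
records every stage's parameters and outputs and is written
atomically, so a crashed run never leaves a half-written manifest.
"""

from __future__ import annotations

import dataclasses
import json
import os
import tempfile
from pathlib import Path

from . import __version__
from .config import Config
from .haplotag import read_observation_tsv, tag_reads
from .meth_phaser import haplotype_methylation_frequency, phase_methylation
from .metrics import compare_phasing, block_n50, phase_blocks, phased_fraction, region_report
from .snv_filter import apply_quality_filter, estimate_quality_threshold
from .sv_phaser import SVPhasingParams, build_tag_interval_index, phase_sv_set
from .trio_phaser import TrioParams, apply_trio_phasing, genotype_map
from . import variant_io as vio

STAGE_ORDER = ("filter_snv", "tag_reads", "phase_sv", "phase_meth", "trio", "stats")

#: required inputs per stage; the SNV VCF for trio/stats may be
#: superseded by an earlier stage's output within the same run
_STAGE_INPUTS = {
    "filter_snv": ("snv_vcf",),
    "tag_reads": ("snv_vcf", "obs_tsv"),
    "phase_sv": ("sv_vcf", "tags_tsv"),
    "phase_meth": ("meth_tsv", "tags_tsv"),
    "trio": ("snv_vcf", "father_vcf", "mother_vcf"),
    "stats": ("snv_vcf", "truth_vcf"),
}

#: inputs that an earlier stage can provide in-run
_PRODUCED_BY = {"tags_tsv": "tag_reads"}


class PipelineError(RuntimeError):
    pass


def run_pipeline(
    config: Config,
    out_dir: str | Path,
    stages: list[str] | None = None,
    **inputs: str | None,
) -> dict:
    """Run the enabled stages in order and return the manifest.

    ``inputs`` accepts snv_vcf, sv_vcf, tags_tsv, obs_tsv, meth_tsv,
    father_vcf, mother_vcf, truth_vcf, regions_bed (paths or None).
    ``stages`` defaults to every stage whose inputs were provided.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {k: v for k, v in inputs.items() if v is not None}
    unknown = set(paths) - {p for req in _STAGE_INPUTS.values() for p in req} - {"regions_bed"}
    if unknown:
        raise PipelineError(f"unknown pipeline inputs: {sorted(unknown)}")

    if stages is None:
        stages = []
        for s in STAGE_ORDER:
            available = set(paths) | {k for k, producer in _PRODUCED_BY.items()
                                      if producer in stages}
            if all(k in available for k in _STAGE_INPUTS[s]):
                stages.append(s)
    bad = [s for s in stages if s not in STAGE_ORDER]
    if bad:
        raise PipelineError(f"unknown stages: {bad}")
    stages = [s for s in STAGE_ORDER if s in stages]

    # fail-fast validation before any stage runs
    for stage in stages:
        for key in _STAGE_INPUTS[stage]:
            provided_in_run = _PRODUCED_BY.get(key) in stages
            if key not in paths and not provided_in_run:
                raise PipelineError(f"stage {stage!r} requires input {key!r}")
            if key in paths and not Path(paths[key]).exists():
                raise PipelineError(f"stage {stage!r}: input file not found: {paths[key]}")

    manifest: dict = {
        "tool": "phasekit",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    snv_current = paths.get("snv_vcf")

    for stage in stages:
        record: dict = {"inputs": {}, "outputs": {}}
        if stage == "filter_snv":
            records = vio.read_vcf(snv_current, rnames_key=config.rnames_key)
            quals = [r.qual for r in records if r.qual is not None]
            result = estimate_quality_threshold(quals, config.bins, config.smooth_window)
            filtered = apply_quality_filter(records, result, mode=config.filter_mode)
            out_vcf = out_dir / "snv.filtered.vcf"
            vio.write_phased_vcf(filtered, out_vcf, sample=config.sample,
                                 rnames_key=config.rnames_key)
            report = out_dir / "snv.threshold.json"
            _write_json(dataclasses.asdict(result), report)
            record["inputs"]["snv_vcf"] = str(snv_current)
            record["outputs"] = {"vcf": str(out_vcf), "threshold_report": str(report)}
            snv_current = str(out_vcf)
        elif stage == "tag_reads":
            hets = [r for r in vio.read_vcf(snv_current, rnames_key=config.rnames_key)
                    if r.phased and r.is_het]
            obs = read_observation_tsv(paths["obs_tsv"])
            tags = tag_reads(obs, hets)
            out_tsv = out_dir / "reads.tags.tsv"
            vio.write_haplotag_table(tags, out_tsv)
            record["inputs"] = {"snv_vcf": str(snv_current), "obs_tsv": paths["obs_tsv"]}
            record["outputs"] = {"tags_tsv": str(out_tsv), "n_tagged": len(tags)}
            paths["tags_tsv"] = str(out_tsv)
        elif stage == "phase_sv":
            svs = vio.read_vcf(paths["sv_vcf"], rnames_key=config.rnames_key)
            tag_list = vio.read_haplotag_table(paths["tags_tsv"])
            tags = vio.tag_mapping(tag_list)
            index = build_tag_interval_index(tag_list) if config.overlap_fallback else None
            params = SVPhasingParams(
                conflict_threshold=config.conflict_threshold,
                min_tagged_reads=config.min_tagged_reads,
                het_only=config.het_only,
            )
            phased, summary = phase_sv_set(svs, tags, params, index)
            out_vcf = out_dir / "sv.phased.vcf"
            vio.write_phased_vcf(phased, out_vcf, sample=config.sample,
                                 rnames_key=config.rnames_key)
            report = out_dir / "sv.summary.json"
            _write_json(summary.as_dict(), report)
            record["inputs"] = {"sv_vcf": paths["sv_vcf"], "tags_tsv": paths["tags_tsv"]}
            record["outputs"] = {"vcf": str(out_vcf), "summary": str(report)}
        elif stage == "phase_meth":
            calls = vio.read_methylation_tsv(paths["meth_tsv"])
            tags = vio.tag_mapping(vio.read_haplotag_table(paths["tags_tsv"]))
            phased = phase_methylation(calls, tags)
            out_tsv = out_dir / "methylation.phased.tsv"
            vio.write_methylation_tsv(phased, out_tsv)
            freq, n_ambiguous = haplotype_methylation_frequency(phased, config.llr_cutoff)
            freq_tsv = out_dir / "methylation.frequency.tsv"
            freq.to_csv(freq_tsv, sep="\t", index=False)
            record["inputs"] = {"meth_tsv": paths["meth_tsv"], "tags_tsv": paths["tags_tsv"]}
            record["outputs"] = {"phased_tsv": str(out_tsv), "frequency_tsv": str(freq_tsv),
                                 "n_ambiguous": n_ambiguous}
        elif stage == "trio":
            child = vio.read_vcf(snv_current, rnames_key=config.rnames_key)
            father = genotype_map(vio.read_vcf(paths["father_vcf"]))
            mother = genotype_map(vio.read_vcf(paths["mother_vcf"]))
            params = TrioParams(
                tolerance=config.tolerance, min_snps=config.min_snps,
                orient_h1=config.orient_h1, merge_confirmed=config.merge_confirmed,
                flip=config.flip,
            )
            updated, blocks = apply_trio_phasing(child, father, mother, params)
            out_vcf = out_dir / "snv.trio.vcf"
            vio.write_phased_vcf(updated, out_vcf, sample=config.sample,
                                 rnames_key=config.rnames_key)
            report = out_dir / "trio.blocks.tsv"
            _write_block_report(blocks, report)
            record["inputs"] = {"snv_vcf": str(snv_current),
                                "father_vcf": paths["father_vcf"],
                                "mother_vcf": paths["mother_vcf"]}
            record["outputs"] = {"vcf": str(out_vcf), "block_report": str(report)}
            snv_current = str(out_vcf)
        elif stage == "stats":
            pred = vio.read_vcf(snv_current, rnames_key=config.rnames_key)
            truth = vio.read_vcf(paths["truth_vcf"], rnames_key=config.rnames_key)
            comparison = compare_phasing(truth, pred)
            blocks = phase_blocks(pred)
            report = {
                "n_common_het": comparison.n_common_het,
                "switch_errors": comparison.switch_errors,
                "switch_rate": comparison.switch_rate,
                "hamming_errors": comparison.hamming_errors,
                "hamming_rate": comparison.hamming_rate,
                "block_n50_bp": block_n50(blocks),
                "n_phase_blocks": len(blocks),
                "phased_fraction": phased_fraction(pred),
            }
            out_json = out_dir / "phasing.stats.json"
            _write_json(report, out_json)
            record["inputs"] = {"snv_vcf": str(snv_current), "truth_vcf": paths["truth_vcf"]}
            record["outputs"] = {"report": str(out_json)}
            if "regions_bed" in paths:
                regions = vio.read_bed(paths["regions_bed"])
                table = region_report(pred, blocks, regions)
                region_tsv = out_dir / "regions.report.tsv"
                table.to_csv(region_tsv, sep="\t", index=False)
                record["inputs"]["regions_bed"] = paths["regions_bed"]
                record["outputs"]["region_report"] = str(region_tsv)
        manifest["stages"][stage] = record

    _write_json(manifest, out_dir / "manifest.json")
    return manifest


def _write_json(payload: dict, path: Path) -> None:
    """Atomic JSON write (tmp file + rename)."""
    fd, tmp = tempfile.mkstemp(dir=str(path.parent), suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)
            fh.write("\n")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _write_block_report(blocks, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("#ps\tn_informative\tvotes_h1_paternal\tvotes_h1_maternal\t"
                 "n_mendelian_conflicts\tdiscordance\tconfirmed\tflipped\n")
        for b in blocks:
            fh.write(f"{b.ps}\t{b.n_informative}\t{b.votes_h1_paternal}\t"
                     f"{b.votes_h1_maternal}\t{b.n_mendelian_conflicts}\t"
                     f"{b.discordance:.6g}\t{b.confirmed}\t{b.flipped}\n")
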