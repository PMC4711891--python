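"""End-to-end pipeline orchestration, configuration and run manifests.

A single YAML config drives every stage; all randomness derives from one
global seed through stable per-stage labels, so a run is reproducible and
the per-stage streams are independent.  Each run writes a manifest with the
resolved config and SHA-256 checksums of every output, so identical configs
can be verified to reproduce identical deterministic outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as mio
from .assays import simulate_dntp, simulate_qpcr, simulate_repletion
from .coverage import coverage, merge_highest_coverage, sliding_window
from .load import mutation_load, per_allele_table
from .mapping import DEFAULT_MAX_MISMATCHES, DEFAULT_SEED_KMER, map_reads
from .pileup import build_pileup
from .quant import ddct, dntp_relative, pool_balance, recovery_fraction
from .reference import generate_reference, rotate_reference
from .simulate import ReadSimParams, simulate_reads

logger = logging.getLogger("mtload")


def derive_seed(global_seed: int, label: str) -> int:
    """Per-stage seed: global seed hashed with a stable stage label."""
    digest = hashlib.sha256(f"{global_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run."""

    seed: int = 0
    outdir: str = "mtload_out"
    reference: dict = field(default_factory=dict)  # length, ncr_span
    reads: dict = field(default_factory=dict)  # ReadSimParams fields (minus seed)
    mapper: dict = field(default_factory=dict)  # max_mismatches, seed_kmer_length
    window: int = 2000
    sample: str = "sample"
    run_label: str = "run1"
    qpcr: dict | None = None  # group_specs, ct_noise_sd, reference_group
    repletion: dict | None = None  # timepoints, profiles, noise_sd, n_lines, baseline
    dntp: dict | None = None  # group_means, cv, n, control_group, exclude_species

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config must set a global integer seed")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class RunManifest:
    config: dict
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    stages: list[dict] = field(default_factory=list)
    results: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "outputs": self.outputs,
                    "stages": self.stages,
                    "results": self.results,
                },
                fh,
                indent=2,
                default=str,
            )


def run_sequencing_stages(
    config: PipelineConfig, outdir: Path, manifest: RunManifest
) -> dict:
    """simulate -> map (original + rotated) -> merge -> pileup -> mutation load."""
    ref = generate_reference(
        length=config.reference.get("length", 16_299),
        ncr_span=tuple(config.reference["ncr_span"])
        if "ncr_span" in config.reference
        else None,
        seed=derive_seed(config.seed, "reference"),
    )
    params = ReadSimParams(
        seed=derive_seed(config.seed, "reads"), **config.reads
    )
    reads, truth = simulate_reads(ref, params)
    logger.info("simulated %d reads (%d bases)", len(reads), reads.total_bases)

    rot = rotate_reference(ref)
    kw = dict(
        max_mismatches=config.mapper.get("max_mismatches", DEFAULT_MAX_MISMATCHES),
        seed_kmer_length=config.mapper.get("seed_kmer_length", DEFAULT_SEED_KMER),
    )
    aln_orig = map_reads(reads, ref, ref_version="original", **kw)
    aln_rot = map_reads(reads, rot, ref_version="rotated", **kw)
    logger.info("mapped %d / %d (original / rotated)", len(aln_orig), len(aln_rot))

    prof_orig = coverage(aln_orig, ref, "original")
    prof_rot = coverage(aln_rot, ref, "rotated")
    pile_orig = build_pileup(aln_orig, ref, "original")
    pile_rot = build_pileup(aln_rot, ref, "rotated")
    merged_prof, merged_pile = merge_highest_coverage(
        prof_orig, prof_rot, pile_orig, pile_rot
    )
    windowed = sliding_window(merged_prof, config.window)
    report = mutation_load(merged_pile, sample=config.sample, run=config.run_label)

    mio.write_fasta(ref, outdir / "reference.fa")
    mio.write_fastq(reads, outdir / "reads.fastq")
    mio.write_truth_table(truth, outdir / "truth.tsv")
    mio.write_sam(aln_orig, ref, outdir / "aligned_original.sam")
    mio.write_sam(aln_rot, rot, outdir / "aligned_rotated.sam")
    mio.write_pileup_tsv(merged_pile, outdir / "pileup_merged.tsv")
    mio.write_coverage_tsv(merged_prof.depth, outdir / "coverage_merged.tsv")
    mio.write_coverage_tsv(windowed.values, outdir / "coverage_windowed.tsv")
    mio.write_tsv(per_allele_table([report]), outdir / "mutation_load.tsv")
    with open(outdir / "mutation_load.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    return {
        "reads": len(reads),
        "emitted_bases": reads.total_bases,
        "injected_errors": truth.total_errors,
        "mapped_original": len(aln_orig),
        "mapped_rotated": len(aln_rot),
        "ml_total_e4": report.ml_total,
        "ml_pooled_e4": report.ml_pooled,
        "per_allele_e4": report.per_allele,
    }


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every configured stage and write outputs plus a manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.__dict__.copy())
    logger.info("run_pipeline seed=%d outdir=%s", config.seed, outdir)

    def stage(name, fn):
        t0 = time.time()
        try:
            result = fn()
        except Exception as err:
            manifest.stages.append({"stage": name, "status": "failed", "error": str(err)})
            manifest.write(outdir / "manifest.json")
            raise RuntimeError(f"stage {name!r} failed: {err}") from err
        manifest.stages.append(
            {"stage": name, "status": "ok", "seconds": round(time.time() - t0, 3)}
        )
        if result:
            manifest.results[name] = result

    if config.reads:
        stage("sequencing", lambda: run_sequencing_stages(config, outdir, manifest))

    if config.qpcr:
        def _qpcr():
            spec = config.qpcr
            table = simulate_qpcr(
                [tuple(s) for s in spec["group_specs"]],
                ct_noise_sd=spec.get("ct_noise_sd", 0.15),
                seed=derive_seed(config.seed, "qpcr"),
                n_replicates=spec.get("n_replicates", 3),
            )
            mio.write_tsv(table, outdir / "ct_table.tsv")
            res = ddct(table, spec["reference_group"], test=spec.get("test", "t"))
            mio.write_tsv(res.group_stats, outdir / "copy_number.tsv")
            return {
                r["group"]: r["percent"]
                for r in res.group_stats.to_dict("records")
            }
        stage("qpcr", _qpcr)

    if config.repletion:
        def _repletion():
            spec = config.repletion
            tc = simulate_repletion(
                spec["timepoints"],
                spec["profiles"],
                noise_sd=spec.get("noise_sd", 0.0),
                n_lines=spec.get("n_lines", 4),
                seed=derive_seed(config.seed, "repletion"),
            )
            mio.write_tsv(tc, outdir / "repletion_timecourse.tsv")
            res = recovery_fraction(tc, spec.get("baseline", spec["timepoints"][0]))
            mio.write_tsv(res.condition_stats, outdir / "recovery.tsv")
            final = spec["timepoints"][-1]
            return {
                cond: res.condition_percent(cond, final)
                for cond in spec["profiles"]
            }
        stage("repletion", _repletion)

    if config.dntp:
        def _dntp():
            spec = config.dntp
            panel = simulate_dntp(
                spec["group_means"],
                cv=spec.get("cv", 0.0),
                n=spec.get("n", 5),
                seed=derive_seed(config.seed, "dntp"),
            )
            mio.write_tsv(panel, outdir / "dntp_panel.tsv")
            exclude = tuple(spec.get("exclude_species", ()))
            summary = dntp_relative(
                panel, spec["control_group"], exclude_species=exclude
            )
            mio.write_tsv(summary.relative, outdir / "dntp_relative.tsv")
            balance = {
                g: pool_balance(panel, g, exclude_species=exclude)
                for g in panel["group"].unique()
            }
            with open(outdir / "dntp_balance.json", "w") as fh:
                json.dump(balance, fh, indent=2)
            return {
                "relative_percent": {
                    r["species"]: r["relative_percent"]
                    for r in summary.relative.to_dict("records")
                },
                "cv": {g: b["cv"] for g, b in balance.items()},
            }
        stage("dntp", _dntp)

    for path in sorted(outdir.iterdir()):
        if path.is_file() and path.name != "manifest.json":
            manifest.outputs[path.name] = _sha256(path)
    manifest.write(outdir / "manifest.json")
    return manifest
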