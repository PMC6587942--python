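"""End-to-end orchestration: simulate (or load) -> genotype matrix ->
haplotype blocks -> sweep scan -> pedigree classification -> candidate genes
-> report, with every intermediate written to the output directory and a
manifest recording parameters and output checksums.

Runs are deterministic: identical configuration and seed reproduce the
output files byte for byte (the manifest records no timestamps; stage
timings go to the log only).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .annotate_genes import aggregate_candidates, write_candidates
from .genotype_io import read_gff, read_metadata, read_vcf
from .ld_blocks import partition_blocks, write_blocks
from .pedigree_blocks import (
    classify_blocks,
    default_subgenome_map,
    family_report,
    format_report,
    subgenome_tally,
    write_classifications,
)
from .sim_pedigree import SimConfig, simulate_panel, write_panel
from .sweep_scan import scan, select_candidates, write_scan

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Inputs (paths or a simulation config) plus all module thresholds."""

    outdir: str | Path = "hapblock_run"
    vcf: str | None = None
    gff: str | None = None
    metadata: str | None = None
    sim: SimConfig | None = None
    maf_min: float = 0.05
    max_missing: float = 0.2
    cu_min: float = 0.98
    cl_min: float = 0.7
    win_size: int = 100_000
    step: int = 10_000
    tail: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.sim is None and self.vcf is None:
            raise ValueError("either a simulation config or a VCF path is required")
        if not (0 <= self.maf_min < 0.5 and 0 <= self.max_missing <= 1):
            raise ValueError("maf_min/max_missing out of range")
        if not (0 < self.tail <= 1 and 0 < self.cl_min <= self.cu_min <= 1):
            raise ValueError("thresholds out of range")
        if self.win_size < 1 or self.step < 1:
            raise ValueError("win_size/step must be positive")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written as JSON)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": {
            k: v for k, v in asdict(config).items() if k not in ("sim", "outdir")
        },
        "sim": asdict(config.sim) if config.sim is not None else None,
        "stages": {},
        "outputs": {},
    }
    outputs: dict[str, Path] = {}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                fn()
            except Exception as exc:
                (out / f"{name}.partial").write_text(str(exc) + "\n")
                raise PipelineError(name, exc) from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return fn

        return deco

    state: dict = {}

    @stage("simulate")
    def _simulate():
        if config.sim is None:
            state["vcf"], state["gff"], state["metadata"] = config.vcf, config.gff, config.metadata
            return
        sim = SimConfig(**{**asdict(config.sim), "seed": config.sim.seed})
        matrix, ped, group, genes, truth = simulate_panel(sim)
        paths = write_panel(out / "sim", matrix, ped, group, genes, truth)
        outputs.update({f"sim_{k}": v for k, v in paths.items()})
        state["vcf"], state["gff"], state["metadata"] = str(paths["vcf"]), str(paths["gff"]), str(paths["metadata"])

    @stage("read")
    def _read():
        state["matrix"] = read_vcf(state["vcf"], maf_min=config.maf_min, max_missing=config.max_missing)
        state["genes"] = read_gff(state["gff"]) if state["gff"] else []
        ped, groups = read_metadata(state["metadata"]) if state["metadata"] else (None, {})
        state["ped"], state["groups"] = ped, groups
        manifest["stages"]["read"] = {
            "n_sites": state["matrix"].n_sites,
            "n_samples": state["matrix"].n_samples,
            "n_genes": len(state["genes"]),
        }

    @stage("blocks")
    def _blocks():
        blocks = partition_blocks(state["matrix"], cu_min=config.cu_min, cl_min=config.cl_min)
        state["blocks"] = blocks
        outputs["blocks_bed"] = out / "blocks.tsv"
        outputs["block_haplotypes"] = out / "block_haplotypes.tsv"
        write_blocks(blocks, outputs["blocks_bed"], outputs["block_haplotypes"])
        manifest["stages"]["blocks"] = {"n_blocks": len(blocks)}

    @stage("scan")
    def _scan():
        regions_by_trait = {}
        stats = None
        for trait, group in state["groups"].items():
            stats = scan(state["matrix"], group, win_size=config.win_size, step=config.step)
            regions = select_candidates(stats, tail=config.tail)
            regions_by_trait[trait] = regions
            outputs[f"windows_{trait}"] = out / f"windows_{trait}.tsv"
            outputs[f"sweeps_{trait}"] = out / f"sweeps_{trait}.bed"
            write_scan(stats, regions, outputs[f"windows_{trait}"], outputs[f"sweeps_{trait}"])
        state["regions_by_trait"] = regions_by_trait
        manifest["stages"]["scan"] = {
            t: {"n_windows": 0 if stats is None else int(len(stats)), "n_regions": len(r)}
            for t, r in regions_by_trait.items()
        }

    @stage("classify")
    def _classify():
        if state["ped"] is None:
            state["classifications"] = []
            manifest["stages"]["classify"] = {"skipped": "no pedigree in metadata"}
            return
        cls = classify_blocks(state["blocks"], state["ped"])
        state["classifications"] = cls
        report = family_report(cls)
        outputs["classifications"] = out / "classifications.tsv"
        write_classifications(cls, outputs["classifications"])
        outputs["family_report"] = out / "family_report.tsv"
        outputs["family_report"].write_text(format_report(report) + "\n")
        try:
            sg_map = default_subgenome_map(state["matrix"].chromosomes())
            tally = subgenome_tally(state["blocks"], sg_map)
            outputs["subgenome_tally"] = out / "subgenome_tally.tsv"
            lines = ["subgenome\tn_blocks\tpct"]
            for sg, (nb, pct) in tally.items():
                lines.append(f"{sg}\t{nb}\t{'undefined' if pct is None else pct}")
            outputs["subgenome_tally"].write_text("\n".join(lines) + "\n")
        except ValueError:
            logger.info("chromosome names carry no subgenome convention; tally skipped")
        manifest["stages"]["classify"] = {
            c: sum(1 for x in cls if x.category == c)
            for c in ("family_shared", "parentA_inherited", "parentB_inherited", "recombined", "other")
        }

    @stage("annotate")
    def _annotate():
        if not state["genes"] or not state.get("regions_by_trait"):
            manifest["stages"]["annotate"] = {"skipped": "no annotation or no sweep regions"}
            return
        sets, cross, summary = aggregate_candidates(state["regions_by_trait"], state["blocks"], state["genes"])
        outputs["candidate_genes"] = out / "candidate_genes.tsv"
        outputs["trait_blocks"] = out / "trait_blocks.tsv"
        write_candidates(sets, cross, outputs["candidate_genes"], outputs["trait_blocks"])
        manifest["stages"]["annotate"] = summary

    @stage("manifest")
    def _manifest():
        manifest["outputs"] = {k: {"path": str(p), "sha256": _sha256(Path(p))} for k, p in sorted(outputs.items())}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return manifest
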