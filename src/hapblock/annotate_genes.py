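"""Mapping of sweep regions and haplotype blocks to genes, and per-trait
candidate-gene aggregation.

A gene belongs to an interval when their 1-based inclusive coordinates
overlap by at least one bp (optionally at least ``min_overlap_frac`` of the
gene's length). A block is trait-linked when it overlaps at least one of the
trait's candidate genes; per-trait counts may share blocks and genes, and
the union across traits is reported alongside the per-trait sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotype_io import GeneAnnotation
from .ld_blocks import HaplotypeBlock
from .sweep_scan import SweepRegion


@dataclass
class CandidateGeneSet:
    """Unique candidate genes of one trait with their source regions."""

    trait: str
    gene_ids: list[str] = field(default_factory=list)
    sources: dict[str, list[str]] = field(default_factory=dict)


def genes_in_interval(
    annotation: Sequence[GeneAnnotation],
    chrom: str,
    start: int,
    end: int,
    min_overlap_frac: float = 0.0,
) -> list[str]:
    """Gene ids overlapping [start, end] on ``chrom`` by >= 1 bp (and by
    >= ``min_overlap_frac`` of the gene length, if given); strand ignored."""
    if start > end:
        raise ValueError(f"interval start {start} > end {end}")
    hits = []
    for g in annotation:
        if g.chrom != chrom:
            continue
        ov = min(g.end, end) - max(g.start, start) + 1
        if ov >= 1 and ov >= min_overlap_frac * (g.end - g.start + 1):
            hits.append(g.gene_id)
    return hits


def _as_interval(region) -> tuple[str, int, int, str]:
    if isinstance(region, SweepRegion):
        return region.chrom, region.start, region.end, f"{region.chrom}:{region.start}-{region.end}"
    chrom, start, end = region
    return chrom, int(start), int(end), f"{chrom}:{start}-{end}"


def aggregate_candidates(
    regions_by_trait: dict[str, Iterable],
    blocks: Sequence[HaplotypeBlock],
    annotation: Sequence[GeneAnnotation],
    min_overlap_frac: float = 0.0,
) -> tuple[dict[str, CandidateGeneSet], pd.DataFrame, dict]:
    """Per-trait candidate-gene sets plus the blocks x candidate-genes table.

    Returns (candidate sets by trait, cross table with one row per
    (trait, block, gene) intersection, summary dict with per-trait and union
    counts for genes and trait-linked blocks).
    """
    gene_chroms = {g.chrom for g in annotation}
    sets: dict[str, CandidateGeneSet] = {}
    for trait, regions in regions_by_trait.items():
        cs = CandidateGeneSet(trait=trait)
        for region in regions:
            chrom, start, end, label = _as_interval(region)
            if chrom not in gene_chroms:
                raise ValueError(f"trait {trait!r}: chromosome {chrom!r} absent from annotation")
            for gid in genes_in_interval(annotation, chrom, start, end, min_overlap_frac):
                if gid not in cs.sources:
                    cs.gene_ids.append(gid)
                    cs.sources[gid] = []
                cs.sources[gid].append(label)
        sets[trait] = cs

    by_id = {g.gene_id: g for g in annotation}
    rows = []
    for trait, cs in sets.items():
        genes = [by_id[g] for g in cs.gene_ids]
        for b in blocks:
            for g in genes:
                if g.chrom == b.chrom and min(g.end, b.end) - max(g.start, b.start) + 1 >= 1:
                    rows.append(dict(trait=trait, block_id=b.block_id, gene_id=g.gene_id))
    cross = pd.DataFrame(rows, columns=["trait", "block_id", "gene_id"])

    union_genes = set()
    union_blocks = set()
    per_trait = {}
    for trait, cs in sets.items():
        linked = set(cross.loc[cross["trait"] == trait, "block_id"])
        per_trait[trait] = dict(n_genes=len(cs.gene_ids), n_blocks=len(linked))
        union_genes.update(cs.gene_ids)
        union_blocks.update(linked)
    summary = dict(
        per_trait=per_trait,
        sum_genes=sum(v["n_genes"] for v in per_trait.values()),
        union_genes=len(union_genes),
        sum_blocks=sum(v["n_blocks"] for v in per_trait.values()),
        union_blocks=len(union_blocks),
    )
    return sets, cross, summary


def write_candidates(sets: dict[str, CandidateGeneSet], cross: pd.DataFrame, genes_path, blocks_path) -> None:
    from pathlib import Path

    lines = ["trait\tgene_id\tsource_regions"]
    for trait, cs in sets.items():
        for gid in cs.gene_ids:
            lines.append(f"{trait}\t{gid}\t{','.join(cs.sources[gid])}")
    Path(genes_path).write_text("\n".join(lines) + "\n")
    cross.to_csv(blocks_path, sep="\t", index=False)
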