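#!/usr/bin/env python
"""Map candidate sweep regions and haplotype blocks to genes: per-trait
candidate-gene sets and the trait-linked-block cross table.

Reads results/analysis/sim/ plus the outputs of 02/03; writes
candidate_genes.tsv and trait_blocks.tsv under results/analysis/.
"""

from pathlib import Path

from hapblock.annotate_genes import aggregate_candidates, write_candidates
from hapblock.genotype_io import read_gff, read_metadata, read_vcf
from hapblock.ld_blocks import partition_blocks
from hapblock.sweep_scan import scan, select_candidates

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main():
    sim = OUT / "sim"
    if not (sim / "panel.vcf").exists():
        raise SystemExit("run analysis/01_simulate_panel.py first")
    matrix = read_vcf(sim / "panel.vcf", maf_min=0.05, max_missing=0.2)
    genes = read_gff(sim / "genes.gff3")
    _, groups = read_metadata(sim / "metadata.tsv")
    blocks = partition_blocks(matrix)
    regions_by_trait = {t: select_candidates(scan(matrix, g), tail=0.01) for t, g in groups.items()}
    sets, cross, summary = aggregate_candidates(regions_by_trait, blocks, genes)
    write_candidates(sets, cross, OUT / "candidate_genes.tsv", OUT / "trait_blocks.tsv")
    for trait, v in summary["per_trait"].items():
        print(f"{trait}: {v['n_genes']} candidate genes in {v['n_blocks']} trait-linked blocks")
    print(f"union: {summary['union_genes']} genes, {summary['union_blocks']} blocks "
          f"(sums {summary['sum_genes']} / {summary['sum_blocks']})")


if __name__ == "__main__":
    main()
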