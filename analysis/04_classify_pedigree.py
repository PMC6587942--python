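#!/usr/bin/env python
"""Classify every detected haplotype block across the pedigree
(family-shared / parent-specific inherited / recombined / other), produce
the family accounting report and the At/Dt subgenome tally.

Reads results/analysis/sim/; writes classifications.tsv, family_report.tsv
and subgenome_tally.tsv under results/analysis/.
"""

from pathlib import Path

from hapblock.genotype_io import read_metadata, read_vcf
from hapblock.ld_blocks import partition_blocks
from hapblock.pedigree_blocks import (
    classify_blocks,
    default_subgenome_map,
    family_report,
    format_report,
    subgenome_tally,
    write_classifications,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main():
    sim = OUT / "sim"
    if not (sim / "panel.vcf").exists():
        raise SystemExit("run analysis/01_simulate_panel.py first")
    matrix = read_vcf(sim / "panel.vcf", maf_min=0.05, max_missing=0.2)
    ped, _ = read_metadata(sim / "metadata.tsv")
    blocks = partition_blocks(matrix)
    cls = classify_blocks(blocks, ped)
    write_classifications(cls, OUT / "classifications.tsv")

    report = family_report(cls)
    (OUT / "family_report.tsv").write_text(format_report(report) + "\n")
    print(format_report(report))

    tally = subgenome_tally(blocks, default_subgenome_map(matrix.chromosomes()))
    lines = ["subgenome\tn_blocks\tpct"]
    for sg, (n, pct) in tally.items():
        lines.append(f"{sg}\t{n}\t{pct}")
        print(f"{sg}: {n} blocks ({pct}%)")
    (OUT / "subgenome_tally.tsv").write_text("\n".join(lines) + "\n")


if __name__ == "__main__":
    main()
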