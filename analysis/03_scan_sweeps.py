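#!/usr/bin/env python
"""Sliding-window selective-sweep scan (100 kb windows, 10 kb step) between
the tolerant and sensitive groups: theta-pi per group, Fst and
ln(pi_tolerant/pi_sensitive), then joint top-1%-tail candidate selection.

Reads results/analysis/sim/; writes windows.tsv and sweeps.bed under
results/analysis/ and reports whether the planted sweep interval was hit.
"""

from pathlib import Path

from hapblock.genotype_io import read_metadata, read_vcf
from hapblock.sweep_scan import scan, select_candidates, write_scan

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"
PLANTED = ("A01", 400_001, 500_000)  # sweep interval configured in 01


def main():
    sim = OUT / "sim"
    if not (sim / "panel.vcf").exists():
        raise SystemExit("run analysis/01_simulate_panel.py first")
    matrix = read_vcf(sim / "panel.vcf", maf_min=0.05, max_missing=0.2)
    _, groups = read_metadata(sim / "metadata.tsv")
    group = groups["stress"]
    stats = scan(matrix, group, win_size=100_000, step=10_000)
    regions = select_candidates(stats, tail=0.01)
    write_scan(stats, regions, OUT / "windows.tsv", OUT / "sweeps.bed")

    c, s, e = PLANTED
    hit = any(r.chrom == c and r.start <= e and r.end >= s for r in regions)
    print(f"{len(stats)} windows scanned; {len(regions)} candidate sweep regions")
    for r in regions:
        print(f"  {r.chrom}:{r.start}-{r.end}  peak Fst {r.peak_fst:.3f}  peak ln-ratio {r.peak_ln_ratio:.3f}")
    print(f"planted interval {c}:{s}-{e} {'recovered' if hit else 'NOT recovered'}")


if __name__ == "__main__":
    main()
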