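# hapblock

Haplotype-block detection, selective-sweep scanning and pedigree
inheritance/recombination accounting for panels of near-homozygous
(inbred or allohaploid) lines — the analysis design used in resequencing
surveys of crop pedigrees such as the Upland cotton (*Gossypium hirsutum*)
CRI-12 family, where a focal cultivar, its two parents, five progeny and a
set of unrelated trait-contrasted varieties are compared genome-wide.

Because every line is effectively a single haplotype per locus, genotypes
are coded 0/1/missing per sample and haplotype frequencies are directly
countable. On top of that representation the package implements:

* **Haplotype blocks (Gabriel criteria).** For adjacent SNP pairs the
  normalized association |D′| = D/D<sub>max</sub> (D = p<sub>AB</sub> −
  p<sub>A</sub>p<sub>B</sub>) is given one-sided 95% confidence bounds from
  the multinomial likelihood of the 2×2 haplotype counts evaluated on a
  |D′| grid (step 0.001, allele frequencies fixed at observed values). A
  pair is in *strong LD* when CU ≥ 0.98 and CL ≥ 0.7; a sequential scan
  extends the current block while adjacent pairs pass and starts the next
  block where they fail.
* **Selective-sweep scan.** In sliding windows (default 100 kb, step
  10 kb): per-group nucleotide diversity θπ (mean pairwise differences per
  bp), F<sub>ST</sub> = (π<sub>Between</sub> − π<sub>Within</sub>)/π<sub>Between</sub>
  with π<sub>Within</sub> the unweighted mean of the two group diversities,
  and ln(θπ<sub>tolerant</sub>/θπ<sub>sensitive</sub>). Candidate sweep
  regions are windows jointly in the top 1% of F<sub>ST</sub> and the
  bottom 1% of the log ratio, merged when contiguous.
* **Pedigree block classification.** Each detected block is labelled
  family-shared, parentA/parentB-inherited, recombined (the focal string is
  a minimal alternating mosaic of the two parental strings, transmitted to
  all progeny), or other — with the accounting report and At/Dt subgenome
  tally in the printed-fraction conventions of such surveys.
* **Synthetic panels with ground truth.** A simulator plants LD blocks
  (two-haplotype founder pools, so all intra-block pairs are in complete
  LD), transmits them through focal and progeny meioses with
  Poisson-distributed crossovers snapped to inter-block gaps, and plants a
  group-differentiated low-diversity sweep region — emitting VCF, GFF3,
  metadata and truth tables for parameter-recovery testing.

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
panel with known truth and write their tables under `results/analysis/`:

```
$ python analysis/01_simulate_panel.py
panel: 3907 SNPs x 20 samples on 26 chromosomes
planted blocks: 650; crossovers recorded: 290
planted sweep: A01:400001-500000 (freq delta 0.8)

$ python analysis/02_detect_blocks.py
detected 651 blocks (650 planted); exact boundary recovery 100.0%

$ python analysis/03_scan_sweeps.py
2312 windows scanned; 1 candidate sweep regions
  A01:350001-530000  peak Fst 0.778  peak ln-ratio -2.270
planted interval A01:400001-500000 recovered

$ python analysis/04_classify_pedigree.py
total_blocks	651
family_shared	22	3.38%
parentA_inherited	33	150.00%
parentB_inherited	30	136.36%
...
```

Every planted block boundary is recovered exactly, the single candidate
sweep region covers the planted interval (peak F<sub>ST</sub> 0.778 against
a ~0 background, log diversity ratio −2.27, i.e. ~10-fold reduced tolerant
diversity), and the pedigree report counts each category. Parent-specific
percentages above 100% are not a bug: following the printed convention of
these surveys they are taken against the family-shared count, which on this
synthetic panel is smaller than the parent-specific counts.
`analysis/06_family_accounting.py` reruns the same arithmetic on the
published counts of the CRI-12 survey (23,752/58,116 → 40.87%;
1,003/23,752 → 4.22%; 3,420/23,752 → 14.40%; 118+126+176 = 420 genes in
2+2+20 = 24 blocks).

The same stages are available as a CLI (`hapblock simulate|blocks|scan|
classify|annotate|run`) and as the `run_pipeline` library entry point,
which writes every intermediate plus a checksummed manifest and is
byte-reproducible for a fixed seed.

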