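# Methods

## Data model

Samples are near-homozygous inbred (or allohaploid) lines, treated as one
haplotype per locus: allele codes 0 (reference), 1 (alternate), −1
(missing). Residual heterozygous VCF calls are recoded missing (with a
logged per-sample rate) rather than phased — in highly selfed material they
are far more likely to be noise than true heterozygosity. Multiallelic and
non-SNP records are skipped. Default site filters are minor-allele
frequency ≥ 0.05 and missingness ≤ 0.2; both are configurable, and raising
the MAF threshold can only shrink the retained site set. Missing data are
handled by pairwise-complete observation throughout: a sample is dropped
from exactly the LD pair or diversity term it is missing in, never
globally.

Coordinates are 1-based inclusive (VCF/GFF3 convention). Window arithmetic
converts to half-open intervals only at the boundary of the computation.

## Linkage disequilibrium and block partition

For sites with countable haplotype frequencies, D = p_AB − p_A·p_B,
|D′| = |D|/Dmax with Dmax = min(p_A(1−p_B), (1−p_A)p_B) for D ≥ 0 and
min(p_A·p_B, (1−p_A)(1−p_B)) otherwise; r² = D²/(p_A(1−p_A)p_B(1−p_B)).
Confidence bounds on |D′| follow the deterministic grid-likelihood
construction used by Haploview-style block callers: the multinomial
likelihood of the four observed haplotype counts is evaluated on a |D′|
grid (step 0.001; allele frequencies fixed at observed values; haplotype
frequencies reconstructed from each grid value in the direction of the
observed D), normalized into a distribution over the grid; CL and CU are
its 5th and 95th percentiles. A pair is in strong LD when CU ≥ 0.98 and
CL ≥ 0.7 (both configurable). Monomorphic pairs and pairs with fewer than
two complete haplotypes are undefined and never count as strong LD.

Blocks are built by a sequential adjacent-pair scan per chromosome: extend
while the adjacent pair is in strong LD, close and restart where it is
not, and discard single-SNP runs (a one-SNP "block" carries no haplotype
string). This is O(S) and follows the break rule as stated for the
original analysis; it deliberately omits Haploview's exhaustive all-pairs
"spine of LD" search, so a sparse interior SNP in weak LD splits a block
here that the exhaustive search might bridge. A point-estimate break
threshold (|D′| ≥ 0.7 to extend) is also exposed; with default bounds it is
implied by CL ≥ 0.7 and has no independent effect.

With ~20 haploid samples the lower bound is the binding constraint: for a
two-haplotype pair with counts (c, 0, 0, 20−c), CL first reaches 0.7 at
c = 7 — even perfect |D′| = 1 cannot be called strong LD with a rarer
minor haplotype. This drives the simulator design below.

## Sweep scan

Per-site diversity within a group with n called haplotypes and c alternate
alleles is 2c(n−c)/(n(n−1)) — the mean over distinct pairs, i.e. the
unbiased estimator implied by "average number of pairwise differences
within the same population". Between groups it is
(c₁(n₂−c₂) + (n₁−c₁)c₂)/(n₁n₂). Window values sum the per-site terms over
the window's SNPs and divide by the window span in bp (per-bp
normalization by span, not SNP count); windows report NaN statistics when
empty. π_Within is the unweighted mean of the two group diversities and
Fst = (π_Between − π_Within)/π_Between, undefined when π_Between = 0.

Two consequences of this estimator pair are worth stating. Under random
group labels E[π_Within] = E[π_Between], so permuted-label Fst has mean ≈ 0
(verified to |0.02| over 200 permutations in the tests). Conversely, a
panel in which both groups contain literally the same haplotypes gives the
small-sample artifact Fst = −1/(n−1), because the cross-group pair set then
includes each haplotype paired with its own copy; zero differentiation in
expectation, not identically zero. A frequency-naive estimator would give 0
there but carries a +1/n permutation bias; we keep the unbiased pairwise
form.

Window tiling starts only full windows (1, 1+step, …); a chromosome
shorter than one window yields a single truncated window normalized by its
actual span. Chromosome length defaults to the last SNP position.
Candidate windows are those jointly in the top `tail` (default 1%)
fraction of Fst and the bottom `tail` fraction of ln(θπ_R/θπ_S) — the
bottom tail because a sweep in the tolerant group reduces its diversity.
The cutoff is the k-th extreme value (k = ⌈tail·n⌉) and ties at the cutoff
are all included, so degenerate all-equal inputs select everything rather
than an arbitrary subset. Selected windows overlapping or adjacent on a
chromosome merge into one sweep region. The window/step defaults (100 kb /
10 kb) and the 1% joint tail are the stated defaults of the analysis; both
are flags.

## Pedigree classification

Blocks are detected once on the pooled panel, so per-sample haplotype
strings share coordinates and "shared" reduces to string identity; a
sample with any missing call in a block has a null string that matches
nothing. Categories are assigned in priority order (family_shared →
parent-specific inherited → recombined → other); they are mutually
exclusive and exhaustive by construction. The recombined test searches for
the minimal number of breakpoints splitting the focal string into
segments that alternate between the parents, each segment identical to the
corresponding parental substring, with every progeny carrying the focal
string; the search is a two-state dynamic program over SNP boundaries
(blocks are short), switching as early as minimality allows so that ties
break leftmost. A flag relaxes "every progeny" to ≥ k progeny.

The accounting report keeps the printed-fraction conventions of the
source analysis: family-shared percentage against the total block count,
but parent-specific percentages against an explicit denominator, by
default the family-shared count — an unusual choice preserved
deliberately, which on panels where parent-specific counts exceed the
family-shared count yields percentages above 100 (the worked example shows
this). Percentages are computed from integer counts with half-up rounding
to two decimals and are never stored as running floats. The subgenome
tally maps chromosome names (A*/D* → At/Dt by default) and reports counts
and percentages.

## Synthetic panels

The generator's defaults are the study conditions the analysis assumes: 26
chromosomes × 1 Mb, 20 lines (parents, focal, 5 progeny, 12 unrelated
panel lines split 6/6 into tolerant/sensitive), 25 planted blocks per
chromosome of 2–10 kb (4–8 SNPs), Poisson(2) crossovers per meiosis, and a
100 kb sweep region on A01 with allele-frequency difference 0.8 between
the trait groups.

Design choices, and why:

* **Two complementary founder haplotypes per block.** Every line carries
  one of two pool haplotypes, so all intra-block pairs are in complete LD
  (|D′| = 1) and every planted block is in principle detectable. The pool
  frequency is drawn Uniform(0.45, 0.55) and the panel *realizes* it
  exactly: carrier sets are balanced subset draws keeping the
  minor-haplotype count in [7, 13] of 20, the range where the
  grid-likelihood lower bound can reach 0.7 at this sample size. With iid
  Bernoulli assignment instead, ~5–10% of blocks would draw minor counts
  below 7 and be undetectable under the Gabriel criteria regardless of the
  true LD — defeating the generator's purpose of a clean recovery surface
  for the detector. This balancing is the generator's deliberate departure
  from naive frequency jitter and is the main feature separating the
  synthetic panel from real data, where rare haplotypes are common and
  detection is correspondingly incomplete.
* **Crossovers snapped to inter-block gaps** (default): crossover
  positions are drawn uniformly, then moved to the nearest gap midpoint,
  so every truth block travels intact with a single founder origin and
  block recovery has an exact answer. A flag permits intra-block
  crossovers for robustness testing. Snapped crossovers keep their
  multiplicity (two crossovers snapped to the same point cancel pairwise),
  so recorded crossover counts remain exactly Poisson.
* **Pedigree transmission.** The focal line is one recombinant gamete per
  chromosome from parentA × parentB, instantly fixed (inbred fixation
  modeled as gamete duplication); each progeny is a recombinant gamete
  from the focal line × one unrelated panel line chosen once per progeny.
  Progeny therefore match the focal haplotype at roughly half their
  blocks, which keeps the inherited categories sparse relative to the real
  pedigree — the classification logic, not the category frequencies, is
  what the synthetic panel validates.
* **Sweep region.** Sites inside the region are drawn independently per
  line: alternate-allele frequency 0.98 in the tolerant group and
  0.98 − delta in the sensitive group and family founders, giving both
  strong differentiation (window Fst ≈ 0.8 at delta 0.8) and ~7-fold
  reduced tolerant diversity. With delta = 0 no sweep is planted: the
  region carries neutral independent sites with a shared per-site
  frequency ~ Uniform(0.2, 0.8), so its windows are exchangeable with
  background and measure the null selection rate. Site independence means
  the planted sweep also induces group-structured LD, which the block
  scanner may legitimately call as extra blocks inside the region.
* Mutation during the pedigree, coalescent realism and homoeologous
  subgenome exchange are out of scope; chromosome names follow the
  allotetraploid A01–A13/D01–D13 convention so the subgenome tally applies.

## Problem sizes and numerical choices

The test suite and the acceptance script run scaled-down panels chosen as
the smallest sizes that still exercise every code path meaningfully:
2-chromosome panels (50 planted blocks, 20 samples) for block recovery and
classification, 4-chromosome panels for the sweep studies (100 seeds for
recovery and for the null), 10,000 meioses for the crossover-rate check,
and 1,000 random 2×2 tables (with a subsample of 40 for the slower
scipy-multinomial bound oracle) for LD oracle equivalence. The |D′| grid
step is 0.001; likelihoods are clipped at 1e−300 before logs; percentile
lookups use the first grid value whose cumulative mass reaches the
percentile. Pipeline outputs format floats with %.6g and the manifest
records no timestamps, so fixed-seed reruns are byte-identical.

## Known limitations

* The sequential adjacent-pair scan splits blocks at any single weak
  interior pair; exhaustive Gabriel search does not. Block counts are
  therefore not comparable between the two variants on real data.
* The confidence bounds condition on observed allele frequencies (fixed
  margins); this is the standard construction but understates uncertainty
  at very small n.
* Classification operates on exact string identity; genotyping error in
  real panels would need a mismatch tolerance the source analysis does not
  define.
* The published many-to-few recombination accounting (thousands of parent
  blocks "recombining" into ~1,000 focal blocks) never states its matching
  rule; the segment-mosaic definition implemented here is this package's
  operationalization of "recombined", and its counts are not expected to
  reproduce the published ones on real data.
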