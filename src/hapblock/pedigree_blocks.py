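"""Classification of haplotype blocks across a two-parent -> focal ->
progeny pedigree.

Blocks are detected once on the pooled panel, so coordinates are common to
all samples and "shared" means an identical allele string over the block's
SNPs. Each block receives exactly one category, tested in priority order:

1. ``family_shared`` — all family members (both parents, the focal cultivar
   and every progeny) carry identical strings;
2. ``parentA_inherited`` / ``parentB_inherited`` — the focal string equals
   one parent's, differs from the other's, and every progeny matches the
   focal string;
3. ``recombined`` — the focal string matches neither parent in full but
   splits at >= 1 SNP boundary into contiguous segments, alternating between
   the parents, with each segment identical to the corresponding parental
   sub-string; every progeny matches the focal string. The minimal-breakpoint
   mosaic is reported, ties broken leftmost.
4. ``other`` — anything else (including missing haplotypes, which never
   match).

The accounting report reproduces the printed-fraction conventions of the
source analysis: the family-shared proportion is taken against the total
block count, while parent-specific proportions are taken against an
explicit denominator (canonically the family-shared count).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .genotype_io import PedigreeSpec
from .ld_blocks import HaplotypeBlock

CATEGORIES = ("family_shared", "parentA_inherited", "parentB_inherited", "recombined", "other")


@dataclass
class BlockClassification:
    block_id: int
    category: str
    matching_parents: list[str] = field(default_factory=list)
    breakpoints: list[int] = field(default_factory=list)  # bp position starting each new segment
    segments: list[tuple[int, int, str]] = field(default_factory=list)  # (first_snp, last_snp, parent)
    reason: str = ""


@dataclass
class FamilyReport:
    """Category counts with printed-style percentages (half-up, 2 decimals).

    Percentages recompute exactly from the stored counts; ``None`` marks an
    undefined proportion (zero denominator).
    """

    total_blocks: int
    n_family_shared: int
    n_parentA_inherited: int
    n_parentB_inherited: int
    n_recombined: int
    n_other: int
    parent_denominator: int
    pct_family_shared: float | None
    pct_parentA_inherited: float | None
    pct_parentB_inherited: float | None
    pct_recombined: float | None


def _pct(num: int, den: int) -> float | None:
    if den == 0:
        return None
    return float((Decimal(num) * 100 / Decimal(den)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def block_haplotype_equal(block: HaplotypeBlock, sample1: str, sample2: str) -> bool:
    """True iff both samples carry identical, non-missing allele strings."""
    for s in (sample1, sample2):
        if s not in block.haplotypes:
            raise KeyError(f"sample {s!r} has no haplotype in block {block.block_id}")
    h1, h2 = block.haplotypes[sample1], block.haplotypes[sample2]
    if h1 is None or h2 is None:
        return False
    return h1 == h2


def _mosaic_breakpoints(focal: str, hap_a: str, hap_b: str) -> list[tuple[int, int, int]] | None:
    """Minimal-breakpoint segmentation of ``focal`` as an alternating mosaic
    of the parents; returns [(first_idx, last_idx, parent 0/1)] or None.
    Ties between equally minimal segmentations break leftmost."""
    m = len(focal)
    match = [
        [focal[i] == hap_a[i] for i in range(m)],
        [focal[i] == hap_b[i] for i in range(m)],
    ]
    if any(not match[0][i] and not match[1][i] for i in range(m)):
        return None
    INF = m + 10
    suf = [[INF, INF] for _ in range(m)]
    for p in (0, 1):
        suf[m - 1][p] = 0 if match[p][m - 1] else INF
    for i in range(m - 2, -1, -1):
        for p in (0, 1):
            if match[p][i]:
                suf[i][p] = min(suf[i + 1][p], 1 + suf[i + 1][1 - p])
    best = min(suf[0])
    if best >= INF or best < 1:
        return None

    def walk(p0: int) -> list[tuple[int, int, int]]:
        segs = []
        p, seg_start = p0, 0
        for i in range(m - 1):
            # switch as early as minimality allows -> leftmost breakpoints
            if match[1 - p][i + 1] and 1 + suf[i + 1][1 - p] == suf[i][p]:
                segs.append((seg_start, i, p))
                p, seg_start = 1 - p, i + 1
        segs.append((seg_start, m - 1, p))
        return segs

    starts = [p for p in (0, 1) if suf[0][p] == best]
    candidates = [walk(p) for p in starts]
    if len(candidates) == 2:
        key = lambda segs: [s[1] for s in segs[:-1]]
        candidates.sort(key=lambda segs: (key(segs), segs[0][2]))
    return candidates[0]


def classify_block(
    block: HaplotypeBlock,
    pedigree: PedigreeSpec,
    min_progeny_match: int | None = None,
) -> BlockClassification:
    """Assign the block its pedigree category (see module docstring).

    ``min_progeny_match`` relaxes the all-progeny requirement of the
    inherited/recombined categories to >= k matching progeny (default: all).
    """
    need = len(pedigree.progeny) if min_progeny_match is None else min_progeny_match
    members = pedigree.members()
    missing = [s for s in members if s not in block.haplotypes]
    if missing:
        return BlockClassification(block.block_id, "other", reason=f"samples absent: {missing}")
    haps = {s: block.haplotypes[s] for s in members}
    if any(h is None for h in haps.values()):
        nulls = [s for s, h in haps.items() if h is None]
        return BlockClassification(block.block_id, "other", reason=f"missing haplotype: {nulls}")

    ha, hb, hf = haps[pedigree.parentA], haps[pedigree.parentB], haps[pedigree.focal]
    n_match = sum(haps[p] == hf for p in pedigree.progeny)
    if ha == hb == hf and n_match == len(pedigree.progeny):
        return BlockClassification(block.block_id, "family_shared", matching_parents=[pedigree.parentA, pedigree.parentB])
    prog_ok = n_match >= need
    if hf == ha and hf != hb and prog_ok:
        return BlockClassification(block.block_id, "parentA_inherited", matching_parents=[pedigree.parentA])
    if hf == hb and hf != ha and prog_ok:
        return BlockClassification(block.block_id, "parentB_inherited", matching_parents=[pedigree.parentB])
    if hf != ha and hf != hb and prog_ok:
        segs = _mosaic_breakpoints(hf, ha, hb)
        if segs is not None:
            parents = (pedigree.parentA, pedigree.parentB)
            return BlockClassification(
                block.block_id,
                "recombined",
                matching_parents=[parents[p] for _, _, p in segs],
                breakpoints=[int(block.positions[s]) for s, _, _ in segs[1:]],
                segments=[(int(block.positions[s]), int(block.positions[e]), parents[p]) for s, e, p in segs],
            )
    return BlockClassification(block.block_id, "other")


def classify_blocks(
    blocks: list[HaplotypeBlock],
    pedigree: PedigreeSpec,
    min_progeny_match: int | None = None,
) -> list[BlockClassification]:
    return [classify_block(b, pedigree, min_progeny_match) for b in blocks]


def family_report(
    classifications: list[BlockClassification],
    total_blocks: int | None = None,
    parent_denominator: int | None = None,
) -> FamilyReport:
    """Accounting report over classifications. ``total_blocks`` defaults to
    the number of classifications; ``parent_denominator`` (the divisor of the
    parent-specific proportions, canonically the family-shared count) defaults
    to the family-shared count."""
    counts = {c: 0 for c in CATEGORIES}
    for cl in classifications:
        counts[cl.category] += 1
    return report_from_counts(
        n_family_shared=counts["family_shared"],
        n_parentA=counts["parentA_inherited"],
        n_parentB=counts["parentB_inherited"],
        n_recombined=counts["recombined"],
        n_other=counts["other"],
        total_blocks=len(classifications) if total_blocks is None else total_blocks,
        parent_denominator=parent_denominator,
    )


def report_from_counts(
    n_family_shared: int,
    n_parentA: int,
    n_parentB: int,
    n_recombined: int = 0,
    n_other: int = 0,
    total_blocks: int | None = None,
    parent_denominator: int | None = None,
) -> FamilyReport:
    """Build the report directly from category counts (e.g. published totals)."""
    total = (
        n_family_shared + n_parentA + n_parentB + n_recombined + n_other
        if total_blocks is None
        else total_blocks
    )
    den = n_family_shared if parent_denominator is None else parent_denominator
    return FamilyReport(
        total_blocks=total,
        n_family_shared=n_family_shared,
        n_parentA_inherited=n_parentA,
        n_parentB_inherited=n_parentB,
        n_recombined=n_recombined,
        n_other=n_other,
        parent_denominator=den,
        pct_family_shared=_pct(n_family_shared, total),
        pct_parentA_inherited=_pct(n_parentA, den),
        pct_parentB_inherited=_pct(n_parentB, den),
        pct_recombined=_pct(n_recombined, total),
    )


def subgenome_tally(
    blocks: list[HaplotypeBlock],
    subgenome_map: dict[str, str],
) -> dict[str, tuple[int, float | None]]:
    """Block counts and percentages per subgenome (e.g. At/Dt)."""
    counts: dict[str, int] = {}
    for b in blocks:
        if b.chrom not in subgenome_map:
            raise ValueError(f"chromosome {b.chrom!r} missing from subgenome map")
        sg = subgenome_map[b.chrom]
        counts[sg] = counts.get(sg, 0) + 1
    for sg in set(subgenome_map.values()):
        counts.setdefault(sg, 0)
    total = sum(counts.values())
    return {sg: (n, _pct(n, total)) for sg, n in sorted(counts.items())}


def default_subgenome_map(chroms: list[str]) -> dict[str, str]:
    """A*/D* chromosome names -> At/Dt (allotetraploid cotton convention)."""
    out = {}
    for c in chroms:
        if c.startswith("A"):
            out[c] = "At"
        elif c.startswith("D"):
            out[c] = "Dt"
        else:
            raise ValueError(f"cannot infer subgenome for chromosome {c!r}")
    return out


def write_classifications(classifications: list[BlockClassification], path) -> None:
    from pathlib import Path

    lines = ["block_id\tcategory\tmatching_parents\tbreakpoints"]
    for c in classifications:
        bp = ",".join(map(str, c.breakpoints)) or "."
        mp = ",".join(c.matching_parents) or "."
        lines.append(f"{c.block_id}\t{c.category}\t{mp}\t{bp}")
    Path(path).write_text("\n".join(lines) + "\n")


def format_report(report: FamilyReport) -> str:
    def p(v):
        return "undefined" if v is None else f"{v:.2f}%"

    return "\n".join(
        [
            f"total_blocks\t{report.total_blocks}",
            f"family_shared\t{report.n_family_shared}\t{p(report.pct_family_shared)}",
            f"parentA_inherited\t{report.n_parentA_inherited}\t{p(report.pct_parentA_inherited)}",
            f"parentB_inherited\t{report.n_parentB_inherited}\t{p(report.pct_parentB_inherited)}",
            f"recombined\t{report.n_recombined}\t{p(report.pct_recombined)}",
            f"other\t{report.n_other}",
            f"parent_denominator\t{report.parent_denominator}",
        ]
    )
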