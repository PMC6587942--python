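"""Synthetic inbred-line panels with planted LD blocks, pedigree transmission
and a group-differentiated sweep region.

The generator emulates the study design the downstream analysis assumes: a
panel of ~20 haploid-coded near-homozygous lines comprising a two-parent ->
focal-cultivar -> progeny family plus unrelated lines split into a tolerant
and a sensitive trait group.

Statistical structure:

* Each chromosome carries non-overlapping "truth" blocks. A block has a pool
  of two complementary founder haplotypes; every line carries one of the two,
  so all intra-block SNP pairs are in complete LD (|D'| = 1). The pool
  frequency of haplotype 0 is drawn uniformly from ``hap_freq_range`` and the
  panel realizes that frequency exactly (carriers are assigned by balanced
  subset draws, not iid coin flips), keeping minor-haplotype counts inside
  the range where the Gabriel confidence-bound test has power at ~20 samples.
* The focal line is one recombinant gamete per chromosome from
  parentA x parentB (crossover count ~ Poisson(crossover_rate), positions
  uniform), instantly fixed to homozygosity; each progeny line is a
  recombinant gamete from focal x one unrelated panel line. By default
  crossovers are snapped to inter-block gaps so every truth block travels
  intact with a single founder origin.
* Inside the sweep region, sites are drawn independently per line with the
  alternate-allele frequency near fixation (``sweep_tolerant_fixation``) in
  the tolerant group and lower by ``sweep_freq_delta`` in the sensitive group
  (and in the family founders): differentiated and diversity-reduced in the
  tolerant group. With ``sweep_freq_delta = 0`` no sweep is planted and the
  region carries neutral sites with a per-site frequency ~ Uniform(0.2, 0.8)
  shared by both groups.

Identical seeds give identical output, down to the emitted VCF bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import (
    GeneAnnotation,
    GenotypeMatrix,
    GroupSpec,
    PedigreeSpec,
    write_gff,
    write_metadata,
    write_vcf,
)

CHROM_NAMES = [f"A{i:02d}" for i in range(1, 14)] + [f"D{i:02d}" for i in range(1, 14)]

_BLOCK_MARGIN = 200  # bp kept free on either side of a planted block within its slot


class SimConfigError(ValueError):
    """Raised for inconsistent simulation configurations."""


@dataclass
class SimConfig:
    """Parameters of the synthetic panel; defaults emulate the study design
    (26 allotetraploid chromosomes, 20 lines: 8 family + 12 grouped panel
    lines, ~25 blocks of 2-10 kb per chromosome, 2 crossovers/meiosis)."""

    n_chrom: int = 26
    chrom_len: int = 1_000_000
    n_blocks_per_chrom: int = 25
    block_len_range: tuple[int, int] = (2_000, 10_000)
    snps_per_block_range: tuple[int, int] = (4, 8)
    crossover_rate: float = 2.0
    n_progeny: int = 5
    n_panel_extra: int = 12
    sweep_region: tuple[str, int, int] | None = ("A01", 400_001, 500_000)
    sweep_freq_delta: float = 0.8
    sweep_site_spacing: int = 2_000
    sweep_tolerant_fixation: float = 0.98
    parent_share_prob: float = 0.4
    hap_freq_range: tuple[float, float] = (0.45, 0.55)
    snap_crossovers: bool = True
    gene_length: int = 3_000
    gene_spacing: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_chrom < 1 or self.chrom_len < 1 or self.n_blocks_per_chrom < 1:
            raise SimConfigError("counts must be positive")
        if self.n_progeny < 1 or self.n_panel_extra < 4:
            raise SimConfigError("need >= 1 progeny and >= 4 panel lines (two groups of >= 2)")
        if not 0.0 <= self.sweep_freq_delta <= 1.0:
            raise SimConfigError("sweep_freq_delta must be in [0, 1]")
        if self.block_len_range[0] < 10 or self.block_len_range[0] > self.block_len_range[1]:
            raise SimConfigError("bad block_len_range")
        if self.snps_per_block_range[0] < 2:
            raise SimConfigError("blocks need >= 2 SNPs")
        if self.crossover_rate < 0:
            raise SimConfigError("crossover_rate must be >= 0")
        need = self.n_blocks_per_chrom * (self.block_len_range[0] + 2 * _BLOCK_MARGIN)
        if need > self.chrom_len:
            raise SimConfigError("block intervals exceed chrom_len")
        if self.sweep_region is not None:
            c, s, e = self.sweep_region
            if s > e or e > self.chrom_len:
                raise SimConfigError("sweep region outside chromosome")
            if c not in self.chrom_names():
                raise SimConfigError(f"sweep chromosome {c!r} not among simulated chromosomes")
        if not (0 < self.sweep_tolerant_fixation < 1):
            raise SimConfigError("sweep_tolerant_fixation must be in (0, 1)")
        if self.sweep_tolerant_fixation - self.sweep_freq_delta <= 0:
            raise SimConfigError("sweep_freq_delta too large for sweep_tolerant_fixation")

    def chrom_names(self) -> list[str]:
        if self.n_chrom <= len(CHROM_NAMES):
            return CHROM_NAMES[: self.n_chrom]
        return CHROM_NAMES + [f"C{i:02d}" for i in range(1, self.n_chrom - len(CHROM_NAMES) + 1)]

    def sample_ids(self) -> list[str]:
        return (
            ["parentA", "parentB", "focal"]
            + [f"progeny{j + 1}" for j in range(self.n_progeny)]
            + [f"panel{k + 1:02d}" for k in range(self.n_panel_extra)]
        )


@dataclass
class TruthTable:
    """Ground truth of a simulated panel.

    blocks: one row per planted block (interval, SNP span, pool haplotypes).
    origins: block x sample pool-haplotype index (0/1; -1 = mixed within block).
    site_map: every SNP's block_id (-1 for inter-block / sweep-region sites).
    crossovers: every meiosis crossover (after optional snapping), with
    multiplicity; coincident snapped crossovers cancel pairwise.
    """

    blocks: pd.DataFrame
    origins: pd.DataFrame
    site_map: pd.DataFrame
    crossovers: pd.DataFrame
    sweep_region: tuple[str, int, int] | None
    progeny_other_parent: dict[str, str]

    def n_crossovers(self, meiosis: str) -> int:
        return int((self.crossovers["meiosis"] == meiosis).sum())


def _allocate(total: int, weights: list[int]) -> list[int]:
    """Largest-remainder split of ``total`` items proportional to weights."""
    w = np.asarray(weights, dtype=float)
    raw = total * w / w.sum()
    out = np.floor(raw).astype(int)
    rem = total - out.sum()
    order = np.argsort(-(raw - out))
    for i in order[:rem]:
        out[i] += 1
    return out.tolist()


def _side_at(pos: np.ndarray, crossovers: np.ndarray, start_side: int) -> np.ndarray:
    """0/1 parental side at each position for a gamete with given crossovers."""
    k = np.searchsorted(np.sort(crossovers), pos, side="left")
    return (start_side + k) % 2


def simulate_panel(
    config: SimConfig,
) -> tuple[GenotypeMatrix, PedigreeSpec, GroupSpec, list[GeneAnnotation], TruthTable]:
    """Generate the panel, pedigree/group metadata, gene tiling and ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    chroms = config.chrom_names()
    samples = config.sample_ids()
    n_total = len(samples)
    n_extra = config.n_panel_extra
    i_parentA, i_parentB, i_focal = 0, 1, 2
    prog_idx = [3 + j for j in range(config.n_progeny)]
    extra_idx = [3 + config.n_progeny + k for k in range(n_extra)]

    # minor-carrier floor: keep both pool haplotypes represented well enough
    # that the grid-likelihood lower bound can reach the Gabriel threshold
    lo_carriers = max(2, int(np.floor(0.35 * n_total)))

    # progeny matings: one unrelated panel parent per progeny, whole genome
    other_parent = rng.integers(0, n_extra, size=config.n_progeny)
    progeny_other = {samples[prog_idx[j]]: samples[extra_idx[other_parent[j]]] for j in range(config.n_progeny)}

    blk_rows, origin_rows, site_rows, xo_rows = [], [], [], []
    chrom_arrs, pos_arrs, allele_arrs = [], [], []
    block_counter = 0

    for chrom in chroms:
        L = config.chrom_len
        sweep_here = config.sweep_region is not None and config.sweep_region[0] == chrom
        spans = [(1, L)]
        if sweep_here:
            _, ss, se = config.sweep_region
            spans = [sp for sp in [(1, ss - 1), (se + 1, L)] if sp[1] - sp[0] + 1 > 0]

        span_lens = [b - a + 1 for a, b in spans]
        alloc = _allocate(config.n_blocks_per_chrom, span_lens)
        intervals: list[tuple[int, int]] = []
        for (a, b), k in zip(spans, alloc):
            if k == 0:
                continue
            slot = (b - a + 1) // k
            if slot < config.block_len_range[0] + 2 * _BLOCK_MARGIN:
                raise SimConfigError(f"blocks do not fit on {chrom}: slot {slot} bp")
            for i in range(k):
                s0 = a + i * slot
                bl = int(rng.integers(config.block_len_range[0], config.block_len_range[1] + 1))
                bl = min(bl, slot - 2 * _BLOCK_MARGIN)
                off = int(rng.integers(0, slot - bl - 2 * _BLOCK_MARGIN + 1))
                start = s0 + _BLOCK_MARGIN + off
                intervals.append((start, start + bl - 1))
        intervals.sort()

        # snap candidates: midpoints of inter-block gaps plus chromosome edges
        snap_points = [1.0]
        for (s1, e1), (s2, _) in zip(intervals, intervals[1:]):
            snap_points.append((e1 + s2) / 2.0)
        snap_points.append(float(L))
        snap_arr = np.asarray(snap_points)

        def _meiosis(label: str) -> tuple[np.ndarray, int]:
            k = rng.poisson(config.crossover_rate)
            raw = rng.uniform(1, L, size=k)
            if config.snap_crossovers and len(raw):
                pos = snap_arr[np.argmin(np.abs(raw[:, None] - snap_arr[None, :]), axis=1)]
            else:
                pos = raw
            for p in pos:
                xo_rows.append((label, chrom, float(p)))
            return pos, int(rng.integers(0, 2))

        focal_xo, focal_start = _meiosis("focal")
        prog_xo = [_meiosis(samples[prog_idx[j]]) for j in range(config.n_progeny)]

        # per-block founder pool and panel assignment
        chrom_sites: list[tuple[int, int]] = []  # (pos, block_id)
        founder_alleles: list[np.ndarray] = []  # per site: alleles for [A, B, extras...]
        for (bs, be) in intervals:
            m = int(rng.integers(config.snps_per_block_range[0], config.snps_per_block_range[1] + 1))
            pos = np.sort(rng.choice(np.arange(bs, be + 1), size=m, replace=False))
            hap0 = rng.integers(0, 2, size=m).astype(np.int8)
            hap1 = (1 - hap0).astype(np.int8)
            p1 = rng.uniform(*config.hap_freq_range)

            a_idx = 0 if rng.random() < p1 else 1
            b_idx = a_idx if rng.random() < config.parent_share_prob else 1 - a_idx
            f_side0 = _side_at(pos[:1], focal_xo, focal_start)[0]
            f_side1 = _side_at(pos[-1:], focal_xo, focal_start)[0]
            focal_mixed = f_side0 != f_side1 or (
                len(focal_xo) > 0 and np.any((focal_xo >= pos[0]) & (focal_xo <= pos[-1]))
            )
            f_idx = a_idx if f_side0 == 0 else b_idx

            # progeny block origin: focal side (0) or unrelated-parent side (1)
            p_origin = []
            for j, (xo, st) in enumerate(prog_xo):
                s0 = _side_at(pos[:1], xo, st)[0]
                mixed = _side_at(pos[-1:], xo, st)[0] != s0 or (
                    len(xo) > 0 and np.any((xo >= pos[0]) & (xo <= pos[-1]))
                )
                p_origin.append(("mixed" if mixed else ("focal" if s0 == 0 else "other")))

            # balance hap-0 carrier count toward the pool frequency
            base = int(a_idx == 0) + int(b_idx == 0) + (0 if focal_mixed else int(f_idx == 0))
            weights = np.ones(n_extra, dtype=int)
            for j, orig in enumerate(p_origin):
                if orig == "focal" and not focal_mixed and f_idx == 0:
                    base += 1
                elif orig == "other":
                    weights[other_parent[j]] += 1
            target = int(np.clip(round(n_total * p1), lo_carriers, n_total - lo_carriers))
            cap = n_total - lo_carriers
            carriers = np.zeros(n_extra, dtype=bool)
            tot = base
            for e in rng.permutation(n_extra):
                if tot >= target:
                    break
                if tot + weights[e] <= cap:
                    carriers[e] = True
                    tot += weights[e]
            if tot < lo_carriers:  # defensive; unreachable under default geometry
                for e in rng.permutation(n_extra):
                    if tot >= lo_carriers:
                        break
                    if not carriers[e]:
                        carriers[e] = True
                        tot += weights[e]

            extra_hidx = np.where(carriers, 0, 1)
            haps = (hap0, hap1)
            for si, p in enumerate(pos):
                row = np.empty(2 + n_extra, dtype=np.int8)
                row[0] = haps[a_idx][si]
                row[1] = haps[b_idx][si]
                row[2:] = [haps[h][si] for h in extra_hidx]
                founder_alleles.append(row)
                chrom_sites.append((int(p), block_counter))

            origins = {samples[i_parentA]: a_idx, samples[i_parentB]: b_idx}
            origins[samples[i_focal]] = -1 if focal_mixed else f_idx
            for j, orig in enumerate(p_origin):
                if orig == "mixed":
                    oi = -1
                elif orig == "focal":
                    oi = -1 if focal_mixed else f_idx
                else:
                    oi = extra_hidx[other_parent[j]]
                origins[samples[prog_idx[j]]] = oi
            for k in range(n_extra):
                origins[samples[extra_idx[k]]] = int(extra_hidx[k])

            blk_rows.append(
                dict(
                    block_id=block_counter,
                    chrom=chrom,
                    start=int(bs),
                    end=int(be),
                    first_snp_pos=int(pos[0]),
                    last_snp_pos=int(pos[-1]),
                    n_snps=m,
                    hap0="".join(map(str, hap0)),
                    hap1="".join(map(str, hap1)),
                )
            )
            origin_rows.append(origins)
            block_counter += 1

        # sweep / neutral independent sites inside the sweep span
        if sweep_here:
            _, ss, se = config.sweep_region
            spos = np.arange(ss + config.sweep_site_spacing // 2, se + 1, config.sweep_site_spacing)
            n_tol = n_extra // 2
            for p in spos:
                if config.sweep_freq_delta > 0:
                    f_tol = config.sweep_tolerant_fixation
                    f_sen = f_tol - config.sweep_freq_delta
                else:
                    f_tol = f_sen = rng.uniform(0.2, 0.8)
                row = np.empty(2 + n_extra, dtype=np.int8)
                row[0] = rng.random() < f_sen
                row[1] = rng.random() < f_sen
                row[2 : 2 + n_tol] = rng.random(n_tol) < f_tol
                row[2 + n_tol :] = rng.random(n_extra - n_tol) < f_sen
                founder_alleles.append(row)
                chrom_sites.append((int(p), -1))

        order = np.argsort([p for p, _ in chrom_sites], kind="stable")
        pos_arr = np.asarray([chrom_sites[i][0] for i in order], dtype=np.int64)
        blk_arr = [chrom_sites[i][1] for i in order]
        F = np.vstack([founder_alleles[i] for i in order])  # sites x (A, B, extras)

        focal_col = np.where(_side_at(pos_arr, focal_xo, focal_start) == 0, F[:, 0], F[:, 1]).astype(np.int8)
        prog_cols = []
        for j, (xo, st) in enumerate(prog_xo):
            other_col = F[:, 2 + other_parent[j]]
            prog_cols.append(np.where(_side_at(pos_arr, xo, st) == 0, focal_col, other_col).astype(np.int8))

        alle = np.column_stack([F[:, 0], F[:, 1], focal_col, *prog_cols, F[:, 2:]])
        chrom_arrs.append(np.full(len(pos_arr), chrom, dtype=object))
        pos_arrs.append(pos_arr)
        allele_arrs.append(alle)
        for p, b in zip(pos_arr, blk_arr):
            site_rows.append((chrom, int(p), int(b)))

    matrix = GenotypeMatrix(
        chrom=np.concatenate(chrom_arrs),
        pos=np.concatenate(pos_arrs),
        ref=np.full(sum(map(len, pos_arrs)), "A", dtype=object),
        alt=np.full(sum(map(len, pos_arrs)), "T", dtype=object),
        alleles=np.vstack(allele_arrs),
        sample_ids=samples,
    )
    matrix.validate()

    ped = PedigreeSpec(
        parentA=samples[i_parentA],
        parentB=samples[i_parentB],
        focal=samples[i_focal],
        progeny=[samples[i] for i in prog_idx],
    )
    n_tol = n_extra // 2
    group = GroupSpec(
        trait="stress",
        tolerant=[samples[i] for i in extra_idx[:n_tol]],
        sensitive=[samples[i] for i in extra_idx[n_tol:]],
    )
    genes = tile_genes(chroms, config.chrom_len, config.gene_length, config.gene_spacing)

    truth = TruthTable(
        blocks=pd.DataFrame(blk_rows),
        origins=pd.DataFrame(origin_rows, index=[r["block_id"] for r in blk_rows]),
        site_map=pd.DataFrame(site_rows, columns=["chrom", "pos", "block_id"]),
        crossovers=pd.DataFrame(xo_rows, columns=["meiosis", "chrom", "pos"]),
        sweep_region=config.sweep_region,
        progeny_other_parent=progeny_other,
    )
    return matrix, ped, group, genes, truth


def tile_genes(chroms: list[str], chrom_len: int, gene_length: int, gene_spacing: int) -> list[GeneAnnotation]:
    """Uniform gene tiling across chromosomes (ids Gh_<chrom>G<n>)."""
    genes = []
    for chrom in chroms:
        i = 0
        start = 1
        while start + gene_length - 1 <= chrom_len:
            i += 1
            genes.append(GeneAnnotation(f"Gh_{chrom}G{i:04d}", chrom, start, start + gene_length - 1))
            start += gene_spacing
    return genes


def planted_ld_matrix(
    n_blocks: int = 50,
    snps_per_block: int = 5,
    n_samples: int = 20,
    n_chrom: int = 2,
    block_spacing: int = 10_000,
    snp_spacing: int = 100,
) -> tuple[GenotypeMatrix, list[dict]]:
    """Deterministic planted matrix in which every intra-block SNP pair is in
    complete LD with balanced carriers, and neighbouring blocks' carrier sets
    overlap by exactly half so that no cross-block pair can satisfy the
    strong-LD criterion. Used as a clean recovery fixture for partitioning."""
    if n_samples % 4:
        raise ValueError("n_samples must be divisible by 4")
    h = n_samples // 2
    q = n_samples // 4
    set1 = np.zeros(n_samples, dtype=np.int8)
    set1[:h] = 1
    set2 = np.zeros(n_samples, dtype=np.int8)
    set2[:q] = 1
    set2[h : h + q] = 1
    chroms, poss, rows, truth = [], [], [], []
    per_chrom = int(np.ceil(n_blocks / n_chrom))
    b = 0
    for ci in range(n_chrom):
        chrom = CHROM_NAMES[ci]
        for k in range(per_chrom):
            if b >= n_blocks:
                break
            carriers = set1 if b % 2 == 0 else set2
            start = 1 + k * block_spacing
            pos = [start + j * snp_spacing for j in range(snps_per_block)]
            for p in pos:
                chroms.append(chrom)
                poss.append(p)
                rows.append(carriers.copy())
            truth.append(dict(block_id=b, chrom=chrom, first_snp_pos=pos[0], last_snp_pos=pos[-1], n_snps=snps_per_block))
            b += 1
    S = len(poss)
    m = GenotypeMatrix(
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        ref=np.full(S, "A", dtype=object),
        alt=np.full(S, "T", dtype=object),
        alleles=np.vstack(rows),
        sample_ids=[f"s{i + 1:02d}" for i in range(n_samples)],
    )
    m.validate()
    return m, truth


def write_panel(
    outdir: str | Path,
    matrix: GenotypeMatrix,
    pedigree: PedigreeSpec,
    group: GroupSpec,
    genes: list[GeneAnnotation],
    truth: TruthTable,
) -> dict[str, Path]:
    """Write VCF + GFF3 + metadata TSV + truth tables; returns the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "panel.vcf",
        "gff": out / "genes.gff3",
        "metadata": out / "metadata.tsv",
        "truth_blocks": out / "truth_blocks.tsv",
        "truth_origins": out / "truth_origins.tsv",
        "truth_sites": out / "truth_sites.tsv",
        "truth_crossovers": out / "truth_crossovers.tsv",
    }
    write_vcf(matrix, paths["vcf"])
    write_gff(genes, paths["gff"])
    panel_ids = [s for s in matrix.sample_ids if s not in pedigree.members()]
    write_metadata(paths["metadata"], pedigree, [group], panel_ids)
    truth.blocks.to_csv(paths["truth_blocks"], sep="\t", index=False)
    truth.origins.to_csv(paths["truth_origins"], sep="\t", index_label="block_id")
    truth.site_map.to_csv(paths["truth_sites"], sep="\t", index=False)
    truth.crossovers.to_csv(paths["truth_crossovers"], sep="\t", index=False)
    return paths
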