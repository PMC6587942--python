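"""Genotype, pedigree and annotation I/O.

The panel analysed here consists of near-homozygous inbred (or allohaploid)
lines, so each sample is treated as a single haplotype per locus: genotypes
are coded 0 (homozygous reference), 1 (homozygous alternate) or -1 (missing).
Residual heterozygous calls are recoded as missing rather than phased, on the
assumption that they are noise in highly selfed material.

Coordinates are kept 1-based inclusive throughout (VCF/GFF3 convention);
window arithmetic converts to half-open intervals at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from cyvcf2 import VCF
from gffutils.iterators import DataIterator

logger = logging.getLogger(__name__)

MISSING = -1


class VcfParseError(ValueError):
    """Raised when the input VCF cannot be parsed."""


class EmptyMatrixError(ValueError):
    """Raised when no site survives filtering (or an empty matrix is invalid)."""


class GffParseError(ValueError):
    """Raised for malformed GFF3 gene features."""


@dataclass
class GenotypeMatrix:
    """Biallelic SNP alleles for S sites x N samples.

    chrom, pos, ref, alt are per-site arrays; ``alleles`` is an (S, N) int8
    matrix with codes in {0, 1, -1}. Positions are strictly increasing within
    each chromosome and sample ids are unique.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    alleles: np.ndarray
    sample_ids: list[str]

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(str(c), None)
        return list(seen)

    def sites_on(self, chrom: str) -> np.ndarray:
        """Indices of sites on ``chrom``, in stored (sorted) order."""
        return np.flatnonzero(self.chrom == chrom)

    def validate(self) -> None:
        S, N = self.alleles.shape
        if not (len(self.chrom) == len(self.pos) == len(self.ref) == len(self.alt) == S):
            raise ValueError("per-site arrays disagree in length")
        if N != len(self.sample_ids):
            raise ValueError("allele matrix width != number of samples")
        if len(set(self.sample_ids)) != N:
            raise ValueError("sample ids are not unique")
        bad = ~np.isin(self.alleles, (0, 1, MISSING))
        if bad.any():
            raise ValueError("allele codes must be in {0, 1, -1}")
        for c in self.chromosomes():
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and np.array_equal(self.chrom, other.chrom)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.alleles, other.alleles)
        )


@dataclass
class PedigreeSpec:
    """Roles in a two-parent -> focal cultivar -> progeny pedigree."""

    parentA: str
    parentB: str
    focal: str
    progeny: list[str]

    def members(self) -> list[str]:
        return [self.parentA, self.parentB, self.focal, *self.progeny]

    def validate(self, sample_ids: Sequence[str] | None = None) -> None:
        ids = self.members()
        if len(set(ids)) != len(ids):
            raise ValueError("pedigree roles must be disjoint")
        if not self.progeny:
            raise ValueError("at least one progeny required")
        if sample_ids is not None:
            missing = [s for s in ids if s not in sample_ids]
            if missing:
                raise ValueError(f"pedigree samples absent from matrix: {missing}")


@dataclass
class GroupSpec:
    """Trait contrast: tolerant vs sensitive sample groups."""

    trait: str
    tolerant: list[str]
    sensitive: list[str]

    def validate(self, sample_ids: Sequence[str] | None = None) -> None:
        if set(self.tolerant) & set(self.sensitive):
            raise ValueError("tolerant and sensitive groups overlap")
        if len(self.tolerant) < 2 or len(self.sensitive) < 2:
            raise ValueError("each group needs >= 2 samples")
        if sample_ids is not None:
            missing = [s for s in self.tolerant + self.sensitive if s not in sample_ids]
            if missing:
                raise ValueError(f"group samples absent from matrix: {missing}")


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene model; 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


def read_vcf(path: str | Path, maf_min: float = 0.05, max_missing: float = 0.2) -> GenotypeMatrix:
    """Read a VCF of near-homozygous samples into a haploid-coded matrix.

    Heterozygous genotypes are recoded missing (logged per sample);
    multiallelic / non-SNP sites are skipped with a logged count. Sites must
    pass minor-allele frequency >= ``maf_min`` (among non-missing calls) and
    missingness <= ``max_missing``. Output is sorted by (chrom, pos).
    """
    path = str(path)
    try:
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    n = len(samples)
    if n == 0:
        raise VcfParseError(f"{path}: VCF has no sample columns")

    chroms, poss, refs, alts, rows = [], [], [], [], []
    n_multi = 0
    het_counts = np.zeros(n, dtype=np.int64)
    n_seen = 0
    try:
        for var in vcf:
            n_seen += 1
            if var.ALT is None or len(var.ALT) != 1:
                n_multi += 1
                continue
            if len(var.REF) != 1 or len(var.ALT[0]) != 1:
                n_multi += 1  # indel or MNP: not a biallelic SNP
                continue
            gt = var.gt_types  # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 missing
            codes = np.full(n, MISSING, dtype=np.int8)
            codes[gt == 0] = 0
            codes[gt == 2] = 1
            het_counts += gt == 1
            miss = codes == MISSING
            if miss.mean() > max_missing:
                continue
            called = ~miss
            if called.sum() == 0:
                continue
            f_alt = codes[called].mean()
            if min(f_alt, 1.0 - f_alt) < maf_min:
                continue
            chroms.append(var.CHROM)
            poss.append(var.POS)
            refs.append(var.REF)
            alts.append(var.ALT[0])
            rows.append(codes)
    except Exception as exc:
        raise VcfParseError(f"{path}: parse error at record {n_seen + 1}: {exc}") from exc

    if n_multi:
        logger.info("%s: skipped %d non-biallelic-SNP sites", path, n_multi)
    if het_counts.any():
        for s, h in zip(samples, het_counts):
            if h:
                logger.info("%s: sample %s het rate %.4f (recoded missing)", path, s, h / max(n_seen, 1))
    if not rows:
        raise EmptyMatrixError(f"{path}: no biallelic site passed filters (saw {n_seen} records)")

    m = GenotypeMatrix(
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
        alleles=np.vstack(rows),
        sample_ids=samples,
    )
    order = np.lexsort((m.pos, m.chrom.astype(str)))
    m = GenotypeMatrix(m.chrom[order], m.pos[order], m.ref[order], m.alt[order], m.alleles[order], m.sample_ids)
    m.validate()
    return m


_GT_STR = {0: "0/0", 1: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a VCF 4.2 with homozygous-style GT calls; re-readable by read_vcf."""
    matrix.validate()
    lines = ["##fileformat=VCFv4.2", "##source=hapblock"]
    for c in matrix.chromosomes():
        length = int(matrix.pos[matrix.chrom == c].max()) + 1
        lines.append(f"##contig=<ID={c},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(matrix.sample_ids))
    for i in range(matrix.n_sites):
        gts = "\t".join(_GT_STR[int(a)] for a in matrix.alleles[i])
        lines.append(
            f"{matrix.chrom[i]}\t{matrix.pos[i]}\t.\t{matrix.ref[i]}\t{matrix.alt[i]}\t.\tPASS\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff(path: str | Path) -> list[GeneAnnotation]:
    """Read gene features from a GFF3 file (1-based inclusive coordinates)."""
    genes: list[GeneAnnotation] = []
    seen: set[str] = set()
    for feat in DataIterator(str(path)):
        if feat.featuretype != "gene":
            continue
        ids = feat.attributes.get("ID")
        if not ids:
            raise GffParseError(f"gene feature at {feat.seqid}:{feat.start}-{feat.end} lacks ID attribute")
        gid = ids[0]
        if gid in seen:
            raise GffParseError(f"duplicate gene ID {gid!r}")
        seen.add(gid)
        genes.append(GeneAnnotation(gid, feat.seqid, int(feat.start), int(feat.end), feat.strand or "+"))
    if not genes:
        logger.warning("%s: no gene features found", path)
    return genes


def write_gff(genes: Sequence[GeneAnnotation], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        lines.append(
            f"{g.chrom}\thapblock\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_metadata(
    path: str | Path,
    pedigree: PedigreeSpec | None,
    groups: Sequence[GroupSpec] = (),
    panel: Sequence[str] = (),
) -> None:
    """Write the sample metadata TSV (columns: sample_id, role, trait, group)."""
    role: dict[str, str] = {s: "panel" for s in panel}
    if pedigree is not None:
        role[pedigree.parentA] = "parentA"
        role[pedigree.parentB] = "parentB"
        role[pedigree.focal] = "focal"
        for p in pedigree.progeny:
            role[p] = "progeny"
    membership: dict[str, list[tuple[str, str]]] = {}
    for g in groups:
        for s in g.tolerant:
            membership.setdefault(s, []).append((g.trait, "tolerant"))
        for s in g.sensitive:
            membership.setdefault(s, []).append((g.trait, "sensitive"))
    lines = ["sample_id\trole\ttrait\tgroup"]
    for s, r in role.items():
        entries = membership.get(s) or [(".", ".")]
        for trait, grp in entries:
            lines.append(f"{s}\t{r}\t{trait}\t{grp}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_metadata(path: str | Path) -> tuple[PedigreeSpec | None, dict[str, GroupSpec]]:
    """Read sample metadata; returns the pedigree (if roles present) and per-trait groups."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "role", "trait", "group"}
    if not required.issubset(df.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    roles = df.drop_duplicates("sample_id").set_index("sample_id")["role"]
    ped = None
    if "focal" in set(roles):
        def _one(r):
            hits = roles[roles == r].index.tolist()
            if len(hits) != 1:
                raise ValueError(f"expected exactly one sample with role {r!r}, got {hits}")
            return hits[0]

        ped = PedigreeSpec(
            parentA=_one("parentA"),
            parentB=_one("parentB"),
            focal=_one("focal"),
            progeny=roles[roles == "progeny"].index.tolist(),
        )
        ped.validate()
    groups: dict[str, GroupSpec] = {}
    for trait, sub in df[df["trait"] != "."].groupby("trait"):
        g = GroupSpec(
            trait=str(trait),
            tolerant=sub.loc[sub["group"] == "tolerant", "sample_id"].tolist(),
            sensitive=sub.loc[sub["group"] == "sensitive", "sample_id"].tolist(),
        )
        g.validate()
        groups[str(trait)] = g
    return ped, groups
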