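"""Sliding-window nucleotide diversity, Fst and log diversity-ratio scan
between a tolerant and a sensitive trait group.

Per window (default 100 kb, 10 kb step), theta-pi is the sum over window SNPs
of the mean number of pairwise allele differences among the group's
haplotypes, divided by the window span in bp. Differentiation is

    Fst = (pi_between - pi_within) / pi_between

with pi_between the mean pairwise difference across groups and pi_within the
unweighted mean of the two group diversities (symmetric Hudson-style
estimator). Selection candidates are windows simultaneously in the top
``tail`` fraction of Fst and the bottom ``tail`` fraction of
ln(pi_tolerant/pi_sensitive) — i.e. diversity reduced in the tolerant group —
with ties at either cutoff included; selected windows are merged into
contiguous sweep regions.

Undefined statistics (no SNPs, zero diversity denominators) are NaN and the
window is excluded from ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix, GroupSpec


@dataclass
class SweepRegion:
    """Contiguous run of selected windows."""

    chrom: str
    start: int
    end: int
    window_ids: list[int]
    peak_fst: float
    peak_ln_ratio: float


def fst(pi_between: float, pi_within: float) -> float:
    """(pi_between - pi_within)/pi_between; NaN when pi_between is 0."""
    if pi_between <= 0:
        return math.nan
    return (pi_between - pi_within) / pi_between

def ln_ratio(pi_r: float, pi_s: float) -> float:
    """ln(pi_R/pi_S) when both are positive, else NaN (undefined flag)."""
    if pi_r > 0 and pi_s > 0:
        return math.log(pi_r / pi_s)
    return math.nan


def _site_pi_within(alleles: np.ndarray) -> np.ndarray:
    """Per-site mean pairwise difference among a group's haplotypes
    (pairwise-complete; 0 where < 2 informative haplotypes)."""
    valid = alleles != MISSING
    n = valid.sum(axis=1)
    c = ((alleles == 1) & valid).sum(axis=1)
    out = np.zeros(alleles.shape[0])
    ok = n >= 2
    out[ok] = 2.0 * c[ok] * (n[ok] - c[ok]) / (n[ok] * (n[ok] - 1.0))
    return out


def _site_pi_between(a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
    """Per-site mean pairwise difference for cross-group haplotype pairs."""
    v1, v2 = a1 != MISSING, a2 != MISSING
    n1, n2 = v1.sum(axis=1), v2.sum(axis=1)
    c1 = ((a1 == 1) & v1).sum(axis=1)
    c2 = ((a2 == 1) & v2).sum(axis=1)
    out = np.zeros(a1.shape[0])
    ok = (n1 >= 1) & (n2 >= 1)
    out[ok] = (c1[ok] * (n2[ok] - c2[ok]) + (n1[ok] - c1[ok]) * c2[ok]) / (n1[ok] * n2[ok])
    return out


def window_pi(
    matrix: GenotypeMatrix,
    samples: list[str],
    chrom: str,
    win_start: int,
    win_size: int,
) -> float:
    """Per-bp diversity of ``samples`` in [win_start, win_start + win_size)."""
    cols = [matrix.sample_index(s) for s in samples]
    idx = matrix.sites_on(chrom)
    pos = matrix.pos[idx]
    inside = idx[(pos >= win_start) & (pos < win_start + win_size)]
    if len(inside) == 0:
        return 0.0
    return float(_site_pi_within(matrix.alleles[np.ix_(inside, cols)]).sum() / win_size)


def window_starts(chrom_len: int, win_size: int, step: int) -> np.ndarray:
    """1-based window start positions tiling a chromosome. Only full windows
    are started; a chromosome shorter than one window yields a single
    truncated window covering it entirely."""
    if chrom_len < win_size:
        return np.array([1], dtype=np.int64)
    return np.arange(1, chrom_len - win_size + 2, step, dtype=np.int64)


def scan(
    matrix: GenotypeMatrix,
    groups: GroupSpec,
    win_size: int = 100_000,
    step: int = 10_000,
    chrom_len: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Window statistics for every chromosome in the matrix.

    Returns a DataFrame with one row per window: chrom, win_start, win_end,
    n_snps, pi_r, pi_s, pi_between, fst, ln_ratio. Chromosome lengths default
    to the last SNP position.
    """
    groups.validate(matrix.sample_ids)
    cols_r = [matrix.sample_index(s) for s in groups.tolerant]
    cols_s = [matrix.sample_index(s) for s in groups.sensitive]
    rows = []
    for chrom in matrix.chromosomes():
        idx = matrix.sites_on(chrom)
        pos = matrix.pos[idx]
        L = (chrom_len or {}).get(chrom, int(pos.max()))
        a_r = matrix.alleles[np.ix_(idx, cols_r)]
        a_s = matrix.alleles[np.ix_(idx, cols_s)]
        site_r = _site_pi_within(a_r)
        site_s = _site_pi_within(a_s)
        site_b = _site_pi_between(a_r, a_s)
        cum_r = np.concatenate([[0.0], np.cumsum(site_r)])
        cum_s = np.concatenate([[0.0], np.cumsum(site_s)])
        cum_b = np.concatenate([[0.0], np.cumsum(site_b)])
        for ws in window_starts(L, win_size, step):
            we = int(min(ws + win_size - 1, L))
            span = we - ws + 1
            lo = np.searchsorted(pos, ws, side="left")
            hi = np.searchsorted(pos, we, side="right")
            n_snps = int(hi - lo)
            pi_r = (cum_r[hi] - cum_r[lo]) / span
            pi_s = (cum_s[hi] - cum_s[lo]) / span
            pi_b = (cum_b[hi] - cum_b[lo]) / span
            pi_w = 0.5 * (pi_r + pi_s)
            rows.append(
                dict(
                    chrom=chrom,
                    win_start=int(ws),
                    win_end=we,
                    n_snps=n_snps,
                    pi_r=pi_r,
                    pi_s=pi_s,
                    pi_between=pi_b,
                    fst=fst(pi_b, pi_w) if n_snps else math.nan,
                    ln_ratio=ln_ratio(pi_r, pi_s) if n_snps else math.nan,
                )
            )
    return pd.DataFrame(rows)


def select_candidates(stats: pd.DataFrame, tail: float = 0.01) -> list[SweepRegion]:
    """Windows jointly in the Fst top tail and the ln-ratio bottom tail,
    ties at either cutoff included, merged into contiguous sweep regions."""
    if not 0 < tail <= 1:
        raise ValueError("tail must be in (0, 1]")
    defined = stats[np.isfinite(stats["fst"]) & np.isfinite(stats["ln_ratio"])]
    if defined.empty:
        import logging

        logging.getLogger(__name__).warning("no window with defined fst and ln_ratio")
        return []
    k = max(1, math.ceil(tail * len(defined)))
    fst_cut = np.sort(defined["fst"].to_numpy())[::-1][k - 1]
    lr_cut = np.sort(defined["ln_ratio"].to_numpy())[k - 1]
    sel = defined[(defined["fst"] >= fst_cut) & (defined["ln_ratio"] <= lr_cut)]
    regions: list[SweepRegion] = []
    for chrom, sub in sel.groupby("chrom", sort=False):
        sub = sub.sort_values("win_start")
        cur: list[int] = []
        cur_start = cur_end = None
        for wid, row in sub.iterrows():
            if cur and row["win_start"] <= cur_end + 1:
                cur.append(wid)
                cur_end = max(cur_end, int(row["win_end"]))
            else:
                if cur:
                    regions.append(_region(stats, chrom, cur_start, cur_end, cur))
                cur = [wid]
                cur_start, cur_end = int(row["win_start"]), int(row["win_end"])
        if cur:
            regions.append(_region(stats, chrom, cur_start, cur_end, cur))
    return regions


def _region(stats, chrom, start, end, ids) -> SweepRegion:
    sub = stats.loc[ids]
    return SweepRegion(
        chrom=str(chrom),
        start=start,
        end=end,
        window_ids=list(ids),
        peak_fst=float(sub["fst"].max()),
        peak_ln_ratio=float(sub["ln_ratio"].min()),
    )


def write_scan(stats: pd.DataFrame, regions: list[SweepRegion], stats_path, bed_path) -> None:
    from pathlib import Path

    stats.to_csv(stats_path, sep="\t", index=False, float_format="%.6g")
    lines = ["#chrom\tstart\tend\tpeak_fst\tpeak_ln_ratio\tn_windows"]
    for r in regions:
        lines.append(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.peak_fst:.6g}\t{r.peak_ln_ratio:.6g}\t{len(r.window_ids)}")
    Path(bed_path).write_text("\n".join(lines) + "\n")
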