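"""Window diversity/Fst statistics against all-pairs oracles; candidate
selection semantics."""

import math

import numpy as np
import pandas as pd
import pytest

from hapblock.genotype_io import GroupSpec
from hapblock.sweep_scan import (
    fst,
    ln_ratio,
    scan,
    select_candidates,
    window_pi,
    window_starts,
)

from conftest import matrix_from_sites


def oracle_pi(columns):
    """Mean pairwise Hamming distance over all haplotype pairs (complete data)."""
    n = columns.shape[1]
    tot = 0
    for i in range(n):
        for j in range(i + 1, n):
            tot += np.sum(columns[:, i] != columns[:, j])
    return tot / (n * (n - 1) / 2)


def test_window_pi_single_difference():
    m = matrix_from_sites([("A01", 10, "01")])
    assert window_pi(m, ["s01", "s02"], "A01", 1, 100) == pytest.approx(0.01)


def test_window_pi_identical_haplotypes_zero():
    m = matrix_from_sites([("A01", 10, "11"), ("A01", 20, "00")])
    assert window_pi(m, ["s01", "s02"], "A01", 1, 100) == 0.0


def test_window_pi_matches_all_pairs_oracle():
    rng = np.random.default_rng(7)
    cols = rng.integers(0, 2, size=(3, 4))
    sites = [("A01", 10 + i, cols[i]) for i in range(3)]
    m = matrix_from_sites(sites)
    got = window_pi(m, m.sample_ids, "A01", 1, 50)
    assert got == pytest.approx(oracle_pi(cols) / 50)


def test_fst_equation():
    assert fst(0.2, 0.1) == pytest.approx(0.5)  # (piB - piW)/piB
    assert fst(0.3, 0.3) == 0.0
    assert math.isnan(fst(0.0, 0.0))


def test_fst_is_one_for_oppositely_fixed_groups():
    # group 1 fixed alt, group 2 fixed ref: pi_within = 0 by direct pair counting
    m = matrix_from_sites([("A01", 10, "111000"), ("A01", 20, "111000")])
    g = GroupSpec("t", ["s01", "s02", "s03"], ["s04", "s05", "s06"])
    stats = scan(m, g, win_size=100, step=100)
    assert stats["fst"].iloc[0] == pytest.approx(1.0)


def test_ln_ratio_values():
    assert ln_ratio(0.01, 0.01) == 0.0
    assert ln_ratio(0.01, 0.02) == pytest.approx(math.log(0.5))
    assert math.isnan(ln_ratio(0.01, 0.0))


def test_window_tiling_arithmetic():
    starts = window_starts(1_000_000, 100_000, 10_000)
    assert len(starts) == 91
    assert starts[0] == 1 and starts[1] == 10_001 and starts[-1] == 900_001
    assert window_starts(50_000, 100_000, 10_000).tolist() == [1]


def test_identical_groups_show_no_differentiation(small_panel):
    """Duplicating the same samples into both groups gives ln_ratio 0 and the
    exact duplicate-pair Fst artifact -1/(n-1) of the mean-pairwise-difference
    estimators (within over distinct pairs, between over all cross pairs);
    differentiation is never positive."""
    matrix = small_panel[0]
    from hapblock.genotype_io import GenotypeMatrix

    n = 4
    m2 = GenotypeMatrix(
        chrom=matrix.chrom,
        pos=matrix.pos,
        ref=matrix.ref,
        alt=matrix.alt,
        alleles=np.hstack([matrix.alleles[:, :n], matrix.alleles[:, :n]]),
        sample_ids=[f"x{i}" for i in range(n)] + [f"y{i}" for i in range(n)],
    )
    g = GroupSpec("t", [f"x{i}" for i in range(n)], [f"y{i}" for i in range(n)])
    stats = scan(m2, g)
    defined = stats[np.isfinite(stats["fst"])]
    assert np.allclose(defined["fst"], -1 / (n - 1))
    assert np.allclose(defined["ln_ratio"].fillna(0.0), 0.0)


def test_scan_invariant_to_sample_order(small_panel):
    matrix, _, group, _, _ = small_panel
    shuffled = GroupSpec(group.trait, group.tolerant[::-1], group.sensitive[::-1])
    pd.testing.assert_frame_equal(scan(matrix, group), scan(matrix, shuffled))


def test_permuted_labels_give_near_zero_mean_fst(small_panel):
    """Fst has mean ~0 over random group-label permutations."""
    matrix, _, group, _, _ = small_panel
    ids = group.tolerant + group.sensitive
    rng = np.random.default_rng(123)
    means = []
    for _ in range(200):
        perm = list(rng.permutation(ids))
        g = GroupSpec("t", perm[:6], perm[6:])
        stats = scan(matrix, g, win_size=100_000, step=100_000)
        means.append(np.nanmean(stats["fst"]))
    assert abs(np.mean(means)) <= 0.02


def _stats_frame(fsts, lrs):
    return pd.DataFrame(
        dict(
            chrom="A01",
            win_start=np.arange(len(fsts)) * 100 + 1,
            win_end=np.arange(len(fsts)) * 100 + 100,
            n_snps=1,
            pi_r=0.1,
            pi_s=0.1,
            pi_between=0.2,
            fst=fsts,
            ln_ratio=lrs,
        )
    )


def test_select_candidates_joint_tails():
    rng = np.random.default_rng(5)
    fsts = rng.normal(0, 0.01, 1000)
    lrs = rng.normal(0, 0.01, 1000)
    fsts[500], lrs[500] = 0.9, -3.0  # one clear sweep window
    regions = select_candidates(_stats_frame(fsts, lrs), tail=0.01)
    sel = {w for r in regions for w in r.window_ids}
    assert 500 in sel
    assert len(sel) <= 10  # at most tail fraction from each tail jointly


def test_select_candidates_all_tied_selects_all():
    stats = _stats_frame(np.full(20, 0.5), np.full(20, -1.0))
    regions = select_candidates(stats, tail=0.05)
    assert sum(len(r.window_ids) for r in regions) == 20


def test_select_candidates_monotone_in_tail():
    rng = np.random.default_rng(9)
    stats = _stats_frame(rng.normal(size=300), rng.normal(size=300))
    prev = set()
    for tail in (0.01, 0.02, 0.05, 0.1):
        sel = {w for r in select_candidates(stats, tail=tail) for w in r.window_ids}
        assert prev <= sel
        prev = sel


def test_select_candidates_merges_contiguous_windows():
    fsts = np.zeros(50)
    lrs = np.zeros(50)
    fsts[10:13], lrs[10:13] = 0.9, -2.0
    regions = select_candidates(_stats_frame(fsts, lrs), tail=0.06)
    assert len(regions) == 1
    assert (regions[0].start, regions[0].end) == (1001, 1300)
    assert regions[0].peak_fst == pytest.approx(0.9)


def test_sweep_simulation_fst_exceeds_background(small_panel):
    matrix, _, group, _, truth = small_panel
    stats = scan(matrix, group)
    c, s, e = truth.sweep_region
    inside = stats[(stats.chrom == c) & (stats.win_start <= e) & (stats.win_end >= s)]
    assert np.nanmedian(inside["fst"]) > np.nanmedian(stats["fst"])


def test_scan_rejects_unknown_group(small_panel):
    matrix = small_panel[0]
    g = GroupSpec("t", ["nope1", "nope2"], matrix.sample_ids[:2])
    with pytest.raises(ValueError):
        scan(matrix, g)
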