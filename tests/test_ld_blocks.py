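"""LD statistics against brute-force oracles, and block partitioning on
planted structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hapblock.ld_blocks import (
    DPRIME_GRID,
    LDUndefinedError,
    dprime_bounds,
    haplotype_counts,
    ld_from_counts,
    pairwise_ld,
    partition_blocks,
)
from hapblock.sim_pedigree import planted_ld_matrix

from conftest import matrix_from_sites


def oracle_ld(nAB, nAb, naB, nab):
    """Direct evaluation of D, |D'|, r2 from the 2x2 table."""
    n = nAB + nAb + naB + nab
    pA, pB, pAB = (nAB + nAb) / n, (nAB + naB) / n, nAB / n
    D = pAB - pA * pB
    dmax = min(pA * (1 - pB), (1 - pA) * pB) if D >= 0 else min(pA * pB, (1 - pA) * (1 - pB))
    return D, abs(D) / dmax, D * D / (pA * (1 - pA) * pB * (1 - pB))


def oracle_bounds(nAB, nAb, naB, nab):
    """Grid-likelihood normalization computed with scipy's multinomial pmf."""
    from scipy.stats import multinomial

    n = nAB + nAb + naB + nab
    pA, pB = (nAB + nAb) / n, (nAB + naB) / n
    D = nAB / n - pA * pB
    dmax = min(pA * (1 - pB), (1 - pA) * pB) if D >= 0 else min(pA * pB, (1 - pA) * (1 - pB))
    sign = 1.0 if D >= 0 else -1.0
    lik = []
    for d in DPRIME_GRID:
        pAB = pA * pB + sign * d * dmax
        probs = np.clip([pAB, pA - pAB, pB - pAB, 1 - pA - pB + pAB], 1e-12, None)
        lik.append(multinomial.pmf([nAB, nAb, naB, nab], n, probs / probs.sum()))
    lik = np.asarray(lik)
    cdf = np.cumsum(lik) / lik.sum()
    return float(DPRIME_GRID[np.searchsorted(cdf, 0.05)]), float(DPRIME_GRID[np.searchsorted(cdf, 0.95)])


@pytest.mark.parametrize(
    "counts,dprime,r2",
    [
        ((4, 0, 0, 4), 1.0, 1.0),  # complete LD
        ((3, 3, 3, 3), 0.0, 0.0),  # independence
        ((5, 1, 1, 5), 2 / 3, None),  # D/Dmax with pA=pB=0.5, pAB=5/12
    ],
)
def test_dprime_worked_examples(counts, dprime, r2):
    D, dp, rr, n = ld_from_counts(counts)
    assert dp == pytest.approx(dprime, abs=1e-12)
    if r2 is not None:
        assert rr == pytest.approx(r2, abs=1e-12)


@given(
    st.tuples(
        st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30)
    ).filter(lambda c: (c[0] + c[1]) * (c[2] + c[3]) > 0 and (c[0] + c[2]) * (c[1] + c[3]) > 0)
)
@settings(max_examples=200, derandomize=True)
def test_ld_matches_bruteforce_oracle(counts):
    D, dp, rr, _ = ld_from_counts(counts)
    eD, edp, err = oracle_ld(*counts)
    assert D == pytest.approx(eD, abs=1e-12)
    assert dp == pytest.approx(min(edp, 1.0), abs=1e-12)
    assert rr == pytest.approx(min(err, 1.0), abs=1e-12)


def test_pairwise_ld_from_raw_alleles_pairwise_complete():
    a = np.array([1, 1, 0, 0, -1, 1, 0])
    b = np.array([1, 0, 0, 1, 1, -1, 0])
    assert haplotype_counts(a, b) == (1, 1, 1, 2)
    stats = pairwise_ld(a, b)
    assert stats.n == 5
    eD, edp, err = oracle_ld(1, 1, 1, 2)
    assert stats.Dprime == pytest.approx(edp, abs=1e-12)


def test_allele_label_swap_leaves_dprime_and_r2_invariant():
    rng = np.random.default_rng(42)
    for _ in range(50):
        a = rng.integers(0, 2, 20)
        b = rng.integers(0, 2, 20)
        if len(set(a)) < 2 or len(set(b)) < 2:
            continue
        s = pairwise_ld(a, b)
        s_swap = pairwise_ld(1 - a, b)
        assert s_swap.Dprime == pytest.approx(s.Dprime, abs=1e-12)
        assert s_swap.r2 == pytest.approx(s.r2, abs=1e-12)


@pytest.mark.parametrize(
    "counts",
    [(50, 0, 0, 50), (25, 25, 25, 25), (1, 0, 0, 1), (8, 0, 0, 12), (9, 1, 1, 9), (3, 2, 7, 8)],
)
def test_bounds_match_grid_likelihood_oracle(counts):
    CL, CU = dprime_bounds(counts)
    eCL, eCU = oracle_bounds(*counts)
    assert CL == pytest.approx(eCL, abs=1e-9)
    assert CU == pytest.approx(eCU, abs=1e-9)


def test_bounds_strong_ld_criteria_cases():
    # no discordant haplotypes, deep data: strong LD criteria met
    CL, CU = dprime_bounds((50, 0, 0, 50))
    assert CL >= 0.7 and CU >= 0.98
    # perfect independence at depth: upper bound far below 0.98
    CL, CU = dprime_bounds((25, 25, 25, 25))
    assert CU < 0.98
    # two haplotypes only: too little data for strong LD
    CL, CU = dprime_bounds((1, 0, 0, 1))
    assert CL < 0.7


def test_monomorphic_pair_is_undefined():
    with pytest.raises(LDUndefinedError):
        pairwise_ld(np.zeros(10, dtype=int), np.array([0, 1] * 5))
    with pytest.raises(LDUndefinedError):
        dprime_bounds((10, 0, 10, 0))
    with pytest.raises(LDUndefinedError):
        pairwise_ld(np.array([1, -1]), np.array([1, -1]))


def test_partition_complete_ld_single_block():
    carriers = "1" * 10 + "0" * 10
    m = matrix_from_sites([("A01", 100 + 50 * i, carriers) for i in range(5)])
    blocks = partition_blocks(m)
    assert len(blocks) == 1
    b = blocks[0]
    assert (b.start, b.end, b.n_snps) == (100, 300, 5)
    assert b.haplotypes["s01"] == "11111" and b.haplotypes["s11"] == "00000"


def test_partition_planted_break_between_blocks():
    """SNPs 1-3 in complete LD, SNPs 4-6 in complete LD, independent across
    the boundary: exactly two blocks."""
    set1 = "1" * 10 + "0" * 10
    set2 = ("10" * 10)  # half-overlap with set1: cross pairs ~independent
    sites = [("A01", 100 + i, set1) for i in range(3)]
    sites += [("A01", 200 + i, set2) for i in range(3)]
    blocks = partition_blocks(matrix_from_sites(sites))
    assert [(b.start, b.end) for b in blocks] == [(100, 102), (200, 202)]


def test_partition_monomorphic_chromosome_yields_no_blocks():
    m = matrix_from_sites([("A01", 100, "0" * 20), ("A01", 200, "0" * 20)])
    assert partition_blocks(m) == []


def test_blocks_do_not_span_chromosomes_or_overlap(small_panel):
    matrix = small_panel[0]
    blocks = partition_blocks(matrix)
    seen = set()
    for b in blocks:
        assert len(set(matrix.chrom[b.snp_indices])) == 1
        assert b.n_snps >= 2
        for i in b.snp_indices:
            assert i not in seen
            seen.add(i)


def test_partition_recovers_planted_blocks(small_panel):
    """>= 90% of planted block boundaries recovered exactly on simulated
    panels with crossovers snapped to gaps."""
    matrix, _, _, _, truth = small_panel
    detected = {(b.chrom, b.start, b.end) for b in partition_blocks(matrix)}
    hits = sum(
        (r.chrom, r.first_snp_pos, r.last_snp_pos) in detected for _, r in truth.blocks.iterrows()
    )
    assert hits / len(truth.blocks) >= 0.9


def test_missing_alleles_give_null_haplotype():
    sites = [
        ("A01", 100, [1] * 10 + [0] * 9 + [-1]),
        ("A01", 101, [1] * 10 + [0] * 10),
    ]
    m = matrix_from_sites(sites)
    blocks = partition_blocks(m)
    assert len(blocks) == 1
    assert blocks[0].haplotypes["s20"] is None
    assert blocks[0].haplotypes["s01"] == "11"
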