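"""Diversity summaries, Hardy–Weinberg exact tests, LD and F_IS."""

from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as sps

import msatpop as m
from msatpop.diversity import (
    bonferroni_threshold,
    fis_weir_cockerham,
    global_hwe,
    hwe_exact_enumeration,
    hwe_exact_mc,
    ld_genotypic_test,
    locus_summary,
    unbiased_he,
)
from msatpop.simulate import SimulationConfig, simulate_dataset

from conftest import build_dataset


# ----------------------------------------------------------------------
# Summaries


def test_unbiased_he_closed_form():
    # 10 typed individuals, two alleles at 0.5 → (20/19)·0.5
    assert unbiased_he({1: 0.5, 2: 0.5}, 10) == pytest.approx(10 / 19)


def test_locus_summary_all_homozygotes_and_monomorphic():
    ds = build_dataset({"A": [[(1, 1), (5, 5)], [(2, 2), (5, 5)]]})
    summary = locus_summary(ds, seed=0)
    row1 = summary[summary.locus == "L1"].iloc[0]
    assert row1.Ho == 0.0 and row1.NA == 2
    row2 = summary[summary.locus == "L2"].iloc[0]
    assert row2.NA == 1 and row2.He == 0.0 and row2.hwe_p == 1.0


def test_locus_summary_skips_blank_cells():
    ds = build_dataset({"A": [[None], [None]]})
    assert locus_summary(ds, seed=0).empty


# ----------------------------------------------------------------------
# HWE exact tests


def test_enumeration_two_homozygotes():
    # margins A:2, a:2 admit two tables with probabilities 1/3 and 2/3
    assert hwe_exact_enumeration({(1, 1): 1, (2, 2): 1}, as_fraction=True) == Fraction(1, 3)


def test_enumeration_two_heterozygotes():
    assert hwe_exact_enumeration({(1, 2): 2}, as_fraction=True) == Fraction(1)


def test_enumeration_monomorphic_convention():
    assert hwe_exact_enumeration({(1, 1): 5}) == 1.0


def test_mc_matches_enumeration_three_alleles():
    counts = {(1, 1): 2, (1, 2): 1, (2, 3): 2, (3, 3): 1}
    exact = hwe_exact_enumeration(counts)
    steps = 40000
    p = hwe_exact_mc(counts, steps=steps, dememorization=2000, seed=5)
    se = np.sqrt(exact * (1 - exact) / steps)
    assert abs(p - exact) < max(5 * se, 0.02)


def test_mc_deterministic_under_seed():
    counts = {(1, 1): 4, (1, 2): 3, (2, 2): 3}
    a = hwe_exact_mc(counts, 2000, 500, seed=42)
    b = hwe_exact_mc(counts, 2000, 500, seed=42)
    assert a == b


def test_mc_monomorphic_and_degenerate():
    assert hwe_exact_mc({(1, 1): 6}, 100, 10, seed=0) == 1.0
    assert hwe_exact_mc({(1, 2): 1}, 100, 10, seed=0) == 1.0


def test_global_hwe_fisher_combination():
    ds = build_dataset(
        {
            "A": [[(1, 1)], [(1, 2)], [(2, 2)], [(1, 2)]],
            "B": [[(1, 1)], [(1, 2)], [(2, 2)], [(1, 2)]],
        }
    )
    summary = locus_summary(ds, seed=0)
    out = global_hwe(summary)
    assert len(out) == 1 and 0 < out.global_p.iloc[0] <= 1


# ----------------------------------------------------------------------
# Linkage disequilibrium


def test_ld_duplicate_locus_detected():
    rng = np.random.default_rng(1)
    genos = [tuple(sorted(rng.integers(1, 5, size=2))) for _ in range(20)]
    ds = build_dataset({"A": [[g, g] for g in genos]})
    p = ld_genotypic_test(ds, "L1", "L2", "A", iterations=999, seed=2)
    assert p <= 0.05


def test_ld_monomorphic_locus_gives_one():
    ds = build_dataset({"A": [[(1, 1), (1, 2)], [(1, 1), (2, 2)]]})
    assert ld_genotypic_test(ds, "L1", "L2", "A", 99, seed=0) == 1.0


def test_ld_type_one_error_calibrated():
    """Under independence the LD permutation p-values are valid: never
    anti-conservative (one-sided KS at α=0.01) and with a rejection rate
    at the 5% level inside its binomial band.  The discrete table
    statistic makes the distribution super-uniform (ties are counted in
    the tail), so exact uniformity is not expected."""
    ps = []
    for rep in range(200):
        cfg = SimulationConfig(
            pop_sizes=[25], n_loci=2, alleles_per_locus=4, seed=30000 + rep
        )
        ds, _ = simulate_dataset(cfg)
        ps.append(ld_genotypic_test(ds, "L01", "L02", "POP1", 199, seed=rep))
    assert sps.kstest(ps, "uniform", alternative="greater").pvalue > 0.01
    lo, hi = sps.binom.interval(0.99, 200, 0.05)
    assert (np.array(ps) <= 0.05).sum() <= hi


def test_ld_requires_two_individuals():
    ds = build_dataset({"A": [[(1, 2), (1, 2)]]})
    with pytest.raises(ValueError):
        ld_genotypic_test(ds, "L1", "L2", "A", 99, seed=0)


# ----------------------------------------------------------------------
# Bonferroni


@pytest.mark.parametrize(
    "alpha,k,expected",
    [(0.05, 28, 0.00179), (0.05, 1, 0.05), (0.05, 36, 0.00139)],
)
def test_bonferroni_threshold(alpha, k, expected):
    got = bonferroni_threshold(alpha, k)
    # agreement to 3 significant figures
    assert float(f"{got:.3g}") == expected


def test_bonferroni_properties():
    assert bonferroni_threshold(0.05, 7) * 7 == 0.05
    ks = [1, 2, 5, 10, 100]
    vals = [bonferroni_threshold(0.05, k) for k in ks]
    assert vals == sorted(vals, reverse=True)
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0)


# ----------------------------------------------------------------------
# F_IS


def test_fis_forced_homozygosity_gives_one():
    ds = build_dataset({"A": [[(1, 1)], [(2, 2)], [(1, 1)], [(2, 2)]]})
    out = fis_weir_cockerham(ds)
    assert out.overall == pytest.approx(1.0)
    assert out.per_locus["L1"] == pytest.approx(1.0)


def test_fis_monomorphic_locus_not_evaluated():
    ds = build_dataset({"A": [[(1, 1), (1, 2)], [(1, 1), (2, 2)], [(1, 1), (1, 2)]]})
    out = fis_weir_cockerham(ds)
    assert out.per_locus["L1"] is None
    assert out.per_locus["L2"] is not None


def test_fis_random_mating_near_zero():
    cfg = SimulationConfig(pop_sizes=[400], n_loci=15, alleles_per_locus=8, seed=21)
    ds, _ = simulate_dataset(cfg)
    out = fis_weir_cockerham(ds)
    assert abs(out.overall) < 0.04


def test_fis_inbreeding_recovery_with_ci_and_p():
    cfg = SimulationConfig(
        pop_sizes=[300], n_loci=12, alleles_per_locus=8, inbreeding_f=0.25, seed=22
    )
    ds, _ = simulate_dataset(cfg)
    out = fis_weir_cockerham(ds, randomizations=99, seed=1)
    assert abs(out.overall - 0.25) < 0.06
    lo, hi = out.ci
    assert lo < out.overall < hi
    assert out.p == pytest.approx(1 / 100)  # homozygote excess never matched


def test_fis_overall_is_ratio_of_sums_not_mean():
    # one very informative locus and one noisy one: overall must weight
    # by components, not average per-locus values
    ds = build_dataset(
        {
            "A": [
                [(1, 1), (1, 2)],
                [(1, 1), (1, 2)],
                [(2, 2), (1, 2)],
                [(2, 2), (1, 2)],
                [(1, 2), (1, 2)],
                [(1, 2), (1, 2)],
            ]
        }
    )
    out = fis_weir_cockerham(ds)
    per_locus_mean = np.mean([v for v in out.per_locus.values() if v is not None])
    assert out.overall != pytest.approx(per_locus_mean)
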