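"""ML dyadic relatedness: likelihoods, classification, r estimation."""

from fractions import Fraction
from itertools import combinations_with_replacement, product

import numpy as np
import pytest

import msatpop as m
from msatpop.data import allele_frequencies
from msatpop.nulls import NULL_ALLELE
from msatpop.relatedness import (
    CATEGORY_K,
    KVector,
    classify_dyads,
    dyad_frequency_table,
    dyad_locus_likelihood,
    estimate_r_bulk,
    ml_relationship,
)
from msatpop.simulate import SimulationConfig, simulate_dataset

from conftest import build_dataset
from oracles import dyad_joint_probability


# ----------------------------------------------------------------------
# KVector and canonical points


def test_kvector_validation():
    with pytest.raises(ValueError):
        KVector(0.5, 0.6, 0.2)
    with pytest.raises(ValueError):
        KVector(-0.1, 0.6, 0.5)


def test_canonical_relatedness_values():
    assert CATEGORY_K["UR"].r == 0.0
    assert CATEGORY_K["HS"].r == 0.25
    assert CATEGORY_K["FS"].r == 0.5
    assert CATEGORY_K["PO"].r == 0.5


# ----------------------------------------------------------------------
# Locus likelihoods


def test_shared_homozygote_likelihoods_two_allele_half_frequencies():
    freqs = {1: 0.5, 2: 0.5}
    g = (1, 1)
    assert dyad_locus_likelihood(g, g, freqs, CATEGORY_K["UR"]) == pytest.approx(0.0625)
    assert dyad_locus_likelihood(g, g, freqs, CATEGORY_K["HS"]) == pytest.approx(0.09375)
    assert dyad_locus_likelihood(g, g, freqs, CATEGORY_K["FS"]) == pytest.approx(0.140625)


def test_ur_likelihood_is_product_of_genotype_probabilities():
    freqs = {1: 0.2, 2: 0.3, 3: 0.5}
    for g1 in [(1, 1), (1, 2), (2, 3)]:
        for g2 in [(3, 3), (1, 3)]:
            expected = (
                (freqs[g1[0]] ** 2 if g1[0] == g1[1] else 2 * freqs[g1[0]] * freqs[g1[1]])
                * (freqs[g2[0]] ** 2 if g2[0] == g2[1] else 2 * freqs[g2[0]] * freqs[g2[1]])
            )
            assert dyad_locus_likelihood(g1, g2, freqs, CATEGORY_K["UR"]) == pytest.approx(expected)


def test_likelihoods_sum_to_one_over_genotype_pairs():
    """Conservation: Σ over unordered genotype pairs of P(g1,g2|k) = 1,
    exactly, for any k on the simplex (rational arithmetic)."""
    freqs = {1: Fraction(1, 6), 2: Fraction(1, 3), 3: Fraction(1, 2)}
    genos = list(combinations_with_replacement(sorted(freqs), 2))
    for k in (CATEGORY_K["UR"], CATEGORY_K["HS"], CATEGORY_K["FS"], CATEGORY_K["PO"],
              KVector(0.2, 0.5, 0.3)):
        total = sum(
            dyad_locus_likelihood(g1, g2, freqs, k) for g1, g2 in product(genos, genos)
        )
        assert abs(float(total) - 1.0) < 1e-12


EXACT_K = {
    "UR": KVector(Fraction(1), Fraction(0), Fraction(0)),
    "HS": KVector(Fraction(1, 2), Fraction(1, 2), Fraction(0)),
    "FS": KVector(Fraction(1, 4), Fraction(1, 2), Fraction(1, 4)),
    "PO": KVector(Fraction(0), Fraction(1), Fraction(0)),
}


@pytest.mark.parametrize("relationship", ["UR", "HS", "FS", "PO"])
def test_likelihood_matches_pedigree_enumeration(relationship):
    """The k-coefficient likelihood equals brute-force enumeration over
    parental genotypes and gamete transmissions, exactly."""
    freqs = {1: Fraction(1, 4), 2: Fraction(1, 4), 3: Fraction(1, 2)}
    genos = list(combinations_with_replacement(sorted(freqs), 2))
    k = EXACT_K[relationship]
    for g1 in genos:
        for g2 in genos:
            expected = dyad_joint_probability(relationship, g1, g2, freqs)
            got = dyad_locus_likelihood(g1, g2, freqs, k)
            assert got == expected


def test_null_accommodation_reduces_when_null_frequency_zero():
    freqs = {1: 0.4, 2: 0.6, NULL_ALLELE: 0.0}
    plain = {1: 0.4, 2: 0.6}
    for g1, g2 in [((1, 1), (1, 2)), ((2, 2), (2, 2))]:
        for cat in CATEGORY_K.values():
            assert dyad_locus_likelihood(g1, g2, freqs, cat, with_nulls=True) == pytest.approx(
                dyad_locus_likelihood(g1, g2, plain, cat)
            )


def test_unknown_allele_raises():
    with pytest.raises(KeyError):
        dyad_locus_likelihood((1, 9), (1, 1), {1: 0.5, 2: 0.5}, CATEGORY_K["UR"])


# ----------------------------------------------------------------------
# Classification


def test_monomorphic_loci_tie_classified_unrelated():
    ds = build_dataset({"A": [[(1, 1)], [(1, 1)]]})
    freqs = allele_frequencies(ds)
    d = ml_relationship((ds.individuals[0], ds.individuals[1]), ds, freqs)
    assert d.ml_category == "UR"
    lls = list(d.loglik.values())
    assert max(lls) - min(lls) < 1e-12


def test_uninformative_locus_never_changes_ranking():
    cfg = SimulationConfig(pop_sizes=[30], n_loci=5, alleles_per_locus=6,
                           family_plan=[[("FS", 2)] * 10], seed=11)
    ds, _ = simulate_dataset(cfg)
    freqs = allele_frequencies(ds)
    base = classify_dyads(ds, freqs)
    # append a monomorphic locus
    calls = dict(ds.calls)
    for i in ds.individuals:
        calls[(i, "MONO")] = (42, 42)
    ds2 = m.GenotypeDataset(ds.individuals, ds.populations, ds.loci + ["MONO"], calls)
    aug = classify_dyads(ds2, allele_frequencies(ds2))
    for d1, d2 in zip(base, aug):
        assert d1.ml_category == d2.ml_category


def test_zero_shared_loci_unclassifiable():
    ds = build_dataset({"A": [[(1, 2), None], [None, (1, 2)]]})
    freqs = allele_frequencies(ds)
    d = ml_relationship((ds.individuals[0], ds.individuals[1]), ds, freqs)
    assert d.ml_category is None and d.r is None


def test_fs_dyads_recovered():
    cfg = SimulationConfig(pop_sizes=[600], n_loci=12, alleles_per_locus=8,
                           family_plan=[[("FS", 2)] * 150], seed=12)
    ds, truth = simulate_dataset(cfg)
    freqs = allele_frequencies(ds)
    inds = ds.individuals
    pairs = [(inds[2 * i], inds[2 * i + 1]) for i in range(150)]
    r = estimate_r_bulk(ds, freqs, pairs)
    assert abs(np.nanmean(r) - 0.5) < 0.05
    cats = [
        ml_relationship(p, ds, freqs, estimate_r=False).ml_category for p in pairs
    ]
    assert sum(c == "FS" for c in cats) >= 0.7 * len(pairs)


def test_ur_dyads_have_low_mean_r():
    cfg = SimulationConfig(pop_sizes=[200], n_loci=12, alleles_per_locus=8, seed=13)
    ds, _ = simulate_dataset(cfg)
    freqs = allele_frequencies(ds)
    inds = ds.individuals
    pairs = [(inds[2 * i], inds[2 * i + 1]) for i in range(100)]
    r = estimate_r_bulk(ds, freqs, pairs)
    assert np.nanmean(r) <= 0.05


def test_r_threshold_on_informative_loci():
    ds = build_dataset({"A": [[(1, 2), (1, 1)], [(1, 2), (1, 1)]]})
    freqs = allele_frequencies(ds)
    d = ml_relationship(
        (ds.individuals[0], ds.individuals[1]), ds, freqs, min_informative_loci=5
    )
    assert d.r is None  # too few informative loci for a stable k estimate


# ----------------------------------------------------------------------
# Dyad frequency table


def test_dyad_frequency_table_ratio():
    # 10 clones of one multilocus genotype would all classify as related;
    # instead construct a mixed sample and check the denominator logic
    cfg = SimulationConfig(pop_sizes=[10], n_loci=10, alleles_per_locus=8,
                           family_plan=[[("FS", 3)]], seed=14)
    ds, _ = simulate_dataset(cfg)
    table = dyad_frequency_table(ds, allele_frequencies(ds))
    row = table.iloc[0]
    n_hs = round(row.HS_NNA * 45)
    n_fs = round(row.FS_NNA * 45)
    dyads = classify_dyads(ds, allele_frequencies(ds))
    assert n_hs == sum(d.ml_category == "HS" for d in dyads)
    assert n_fs == sum(d.ml_category == "FS" for d in dyads)


def test_dyad_frequency_table_deterministic():
    ds, _ = simulate_dataset(
        SimulationConfig(pop_sizes=[15, 15], n_loci=6, alleles_per_locus=6, seed=15)
    )
    freqs = allele_frequencies(ds)
    t1 = dyad_frequency_table(ds, freqs)
    t2 = dyad_frequency_table(ds, freqs)
    assert t1.equals(t2)
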