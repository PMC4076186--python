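"""Synthetic-data generator: distributional oracles and bookkeeping."""

from fractions import Fraction

import numpy as np
import pytest

import msatpop as m
from msatpop.data import allele_frequencies
from msatpop.io import write_genepop
from msatpop.simulate import (
    SimulationConfig,
    apply_null_alleles,
    derive_population_frequencies,
    generate_study_like_dataset,
    sample_base_frequencies,
    simulate_dataset,
)


def test_same_seed_same_dataset():
    a, _ = generate_study_like_dataset(7)
    b, _ = generate_study_like_dataset(7)
    assert write_genepop(a) == write_genepop(b)


def test_study_like_shape():
    ds, truth = generate_study_like_dataset(1)
    assert len(ds.individuals) == 259
    assert len(ds.loci) == 9
    assert len(ds.pop_order) == 8
    assert [ds.sample_size(p) for p in ds.pop_order] == [52, 43, 36, 24, 13, 53, 14, 24]


def test_base_frequencies_single_allele():
    cfg = SimulationConfig(pop_sizes=[10], n_loci=1, alleles_per_locus=1, seed=0)
    table = sample_base_frequencies(cfg)
    assert table.freqs[("BASE", "L01")] == {1: 1.0}


def test_base_frequencies_deterministic():
    cfg = SimulationConfig(pop_sizes=[10], n_loci=3, alleles_per_locus=5, seed=9)
    assert sample_base_frequencies(cfg).freqs == sample_base_frequencies(cfg).freqs


def test_high_concentration_near_uniform():
    cfg = SimulationConfig(
        pop_sizes=[10], n_loci=1, alleles_per_locus=4,
        base_freq_concentration=1e6, seed=0,
    )
    freqs = sample_base_frequencies(cfg).freqs[("BASE", "L01")]
    assert all(abs(f - 0.25) < 0.01 for f in freqs.values())


def test_balding_nichols_zero_fst_returns_base():
    cfg = SimulationConfig(pop_sizes=[10, 10], n_loci=2, alleles_per_locus=4, seed=1)
    base = sample_base_frequencies(cfg)
    pops = derive_population_frequencies(base, 0.0, 1, ["P1", "P2"])
    for pop in ("P1", "P2"):
        for locus in ("L01", "L02"):
            assert pops.freqs[(pop, locus)] == base.freqs[("BASE", locus)]


def test_balding_nichols_variance_matches_closed_form(rng):
    """Two alleles at p=0.5, F=0.2: Var(p) across populations = F·p(1−p) = 0.05."""
    base = m.AlleleFrequencyTable()
    base.freqs[("BASE", "L1")] = {1: 0.5, 2: 0.5}
    drawn = derive_population_frequencies(
        base, 0.2, 123, [f"P{i}" for i in range(10000)]
    )
    ps = np.array([drawn.freqs[(f"P{i}", "L1")][1] for i in range(10000)])
    assert abs(ps.mean() - 0.5) < 0.01
    assert abs(ps.var() - 0.05) < 0.003


def test_balding_nichols_high_f_concentrates():
    base = m.AlleleFrequencyTable()
    base.freqs[("BASE", "L1")] = {1: 0.5, 2: 0.5}
    drawn = derive_population_frequencies(
        base, 0.98, 5, [f"P{i}" for i in range(500)]
    )
    ps = np.array([drawn.freqs[(f"P{i}", "L1")][1] for i in range(500)])
    assert ((ps < 0.05) | (ps > 0.95)).mean() > 0.8


def test_full_inbreeding_forces_homozygosity():
    cfg = SimulationConfig(
        pop_sizes=[50], n_loci=5, alleles_per_locus=6, inbreeding_f=1.0, seed=2
    )
    ds, _ = simulate_dataset(cfg)
    for ind in ds.individuals:
        for locus in ds.loci:
            a, b = ds.calls[(ind, locus)]
            assert a == b


def test_heterozygosity_recovery_under_inbreeding():
    """Observed heterozygosity ≈ (1−F)·He at F=0.3 (5% relative tolerance)."""
    F = 0.3
    cfg = SimulationConfig(
        pop_sizes=[800], n_loci=10, alleles_per_locus=8, inbreeding_f=F, seed=3
    )
    ds, _ = simulate_dataset(cfg)
    table = allele_frequencies(ds)
    ho_all, he_all = [], []
    for locus in ds.loci:
        typed = ds.typed_genotypes_at("POP1", locus)
        ho_all.append(sum(a != b for a, b in typed) / len(typed))
        p = table.freqs[("POP1", locus)]
        he_all.append(1 - sum(v * v for v in p.values()))
    ratio = np.mean(ho_all) / np.mean(he_all)
    assert abs(ratio - (1 - F)) < 0.05 * (1 - F)


def test_pedigree_truth_consistent_with_categories():
    ds, truth = generate_study_like_dataset(5)
    cats = truth.true_dyad_categories(ds)
    for (a, b), cat in cats.items():
        shared = len(set(truth.pedigree[a]) & set(truth.pedigree[b]))
        assert cat == {0: "UR", 1: "HS", 2: "FS"}[shared]


def test_no_families_means_all_unrelated():
    cfg = SimulationConfig(pop_sizes=[20], n_loci=2, alleles_per_locus=4, seed=4)
    ds, truth = simulate_dataset(cfg)
    assert set(truth.true_dyad_categories(ds).values()) == {"UR"}


def test_plan_exceeding_pop_size_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(
            pop_sizes=[5], n_loci=1, alleles_per_locus=2,
            family_plan=[[("FS", 6)]], seed=0,
        )


def test_fs_offspring_match_exhaustive_enumeration():
    """FS dyad genotype distribution at a 2-allele locus matches brute-force
    enumeration over parental genotypes and gamete transmissions."""
    p = Fraction(1, 2)
    freqs = {1: p, 2: 1 - p}

    def geno_prob(g):
        a, b = g
        return freqs[a] * freqs[b] * (1 if a == b else 2)

    genotypes = [(1, 1), (1, 2), (2, 2)]
    expected = {}
    for gm in genotypes:
        for gf in genotypes:
            w = geno_prob(gm) * geno_prob(gf)
            for a1 in gm:
                for b1 in gf:
                    for a2 in gm:
                        for b2 in gf:
                            c1 = tuple(sorted((a1, b1)))
                            c2 = tuple(sorted((a2, b2)))
                            key = (c1, c2)
                            expected[key] = expected.get(key, 0) + w * Fraction(1, 16)
    assert sum(expected.values()) == 1

    # simulate many independent FS families of size 2
    plan = [("FS", 2)] * 4000
    cfg = SimulationConfig(
        pop_sizes=[8000], n_loci=1, alleles_per_locus=2,
        base_freq_concentration=1e9,  # forces p ≈ 1/2
        family_plan=[plan], seed=6,
    )
    ds, _ = simulate_dataset(cfg)
    counts = {}
    inds = ds.individuals
    for i in range(4000):
        g1 = ds.calls[(inds[2 * i], "L01")]
        g2 = ds.calls[(inds[2 * i + 1], "L01")]
        counts[(g1, g2)] = counts.get((g1, g2), 0) + 1
    for key, prob in expected.items():
        emp = counts.get(key, 0) / 4000
        assert abs(emp - float(prob)) < 0.03


def test_null_alleles_observation_model():
    ds = m.GenotypeDataset(
        ["i1", "i2"], {"i1": "A", "i2": "A"}, ["L1"],
        {("i1", "L1"): (1, 2), ("i2", "L1"): (1, 2)},
    )
    # rate ~1 ⇒ everything blanks
    out = apply_null_alleles(ds, 0.999, 0)
    # with r=0.999 almost surely both gametes null
    assert out.calls[("i1", "L1")] is None or out.calls[("i1", "L1")][0] == out.calls[("i1", "L1")][1]


def test_null_blank_fraction_matches_r_squared():
    n, r = 4000, 0.3
    cfg = SimulationConfig(pop_sizes=[n], n_loci=1, alleles_per_locus=6, seed=8)
    ds, _ = simulate_dataset(cfg)
    out = apply_null_alleles(ds, r, 99)
    blanks = sum(out.calls[(i, "L01")] is None for i in out.individuals)
    assert abs(blanks / n - r * r) < 0.02


def test_homozygote_excess_monotone_in_null_rate():
    cfg = SimulationConfig(pop_sizes=[3000], n_loci=1, alleles_per_locus=6, seed=9)
    ds, _ = simulate_dataset(cfg)

    def hom_frac(d):
        typed = d.typed_genotypes_at("POP1", "L01")
        return sum(a == b for a, b in typed) / len(typed)

    fractions = [hom_frac(apply_null_alleles(ds, r, 11)) for r in (0.0, 0.15, 0.35)]
    assert fractions[0] < fractions[1] < fractions[2]


def test_truth_bundle_serialises():
    import json

    _, truth = generate_study_like_dataset(2)
    payload = json.loads(truth.to_json())
    assert payload["seed"] == 2
    assert set(payload["true_null_freqs"]) == {f"L{i + 1:02d}" for i in range(9)}
    assert payload["null_freqs_by_pop"]["NAD06"]["L01"] >= 0.0


def test_study_like_true_dyad_frequencies_in_reported_range():
    """Planted family plans give true within-sample HS/FS dyad frequencies
    in the 0–0.05 band reported for the emulated survey."""
    ds, truth = generate_study_like_dataset(3)
    cats = truth.true_dyad_categories(ds)
    for pop in ds.pop_order:
        inds = set(ds.individuals_in(pop))
        n = len(inds)
        kin = sum(
            1 for (a, b), c in cats.items()
            if c in ("HS", "FS") and a in inds
        )
        freq = kin / (n * (n - 1) / 2)
        assert freq <= 0.05
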