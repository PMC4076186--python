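"""Null-allele estimators (moment + EM) and the genotype correction."""

import numpy as np
import pytest

import msatpop as m
from msatpop.data import BLANK
from msatpop.diversity import genotype_counts, hwe_test
from msatpop.nulls import (
    NULL_ALLELE,
    adjust_genotypes,
    estimate_null_em,
    estimate_null_moment,
    estimate_nulls,
    expected_blank_count,
)
from msatpop.simulate import SimulationConfig, simulate_dataset



# ----------------------------------------------------------------------
# Moment estimators


def test_moment_estimator_closed_forms():
    assert estimate_null_moment(0.4, 0.8, "brookfield1") == pytest.approx(0.4 / 1.8)
    assert estimate_null_moment(0.4, 0.8, "chakraborty") == pytest.approx(0.4 / 1.2)


def test_moment_estimator_edge_cases():
    assert estimate_null_moment(0.5, 0.5) == 0.0          # no excess
    assert estimate_null_moment(0.6, 0.5) == 0.0          # negative → clamp
    assert estimate_null_moment(0.0, 0.0) == 0.0          # monomorphic
    with pytest.raises(ValueError):
        estimate_null_moment(1.5, 0.5)


# ----------------------------------------------------------------------
# EM estimator


def test_em_no_signal_converges_to_zero():
    # perfect Hardy–Weinberg counts, no blanks
    counts = {(1, 1): 25, (1, 2): 50, (2, 2): 25}
    _, r, trace = estimate_null_em(counts)
    assert r < 1e-4
    assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))


def test_em_all_blank_boundary():
    _, r, _ = estimate_null_em({}, n_blank=10)
    assert r == 1.0


def test_em_loglik_monotone_on_noisy_data():
    cfg = SimulationConfig(
        pop_sizes=[200], n_loci=1, alleles_per_locus=6, null_freqs=[0.15], seed=1
    )
    ds, _ = simulate_dataset(cfg)
    counts = genotype_counts(ds, "POP1", "L01")
    _, _, trace = estimate_null_em(counts, n_blank=200 - sum(counts.values()))
    assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))


def test_em_recovers_planted_null_frequency():
    cfg = SimulationConfig(
        pop_sizes=[500], n_loci=1, alleles_per_locus=8, null_freqs=[0.2], seed=3
    )
    ds, _ = simulate_dataset(cfg)
    counts = genotype_counts(ds, "POP1", "L01")
    _, r, _ = estimate_null_em(counts, n_blank=500 - sum(counts.values()))
    assert abs(r - 0.2) < 0.05


def test_em_bias_shrinks_with_sample_size():
    errs = []
    for n in (50, 200, 800):
        reps = []
        for rep in range(8):
            cfg = SimulationConfig(
                pop_sizes=[n], n_loci=1, alleles_per_locus=8,
                null_freqs=[0.15], seed=100 * n + rep,
            )
            ds, _ = simulate_dataset(cfg)
            counts = genotype_counts(ds, "POP1", "L01")
            _, r, _ = estimate_null_em(counts, n_blank=n - sum(counts.values()))
            reps.append(r - 0.15)
        errs.append(abs(np.mean(reps)))
    assert errs[-1] < 0.05
    assert errs[-1] <= errs[0] + 0.02


def test_em_exclude_blanks_mode_close_to_include():
    cfg = SimulationConfig(
        pop_sizes=[600], n_loci=1, alleles_per_locus=8, null_freqs=[0.2], seed=4
    )
    ds, _ = simulate_dataset(cfg)
    counts = genotype_counts(ds, "POP1", "L01")
    nb = 600 - sum(counts.values())
    _, r_in, _ = estimate_null_em(counts, n_blank=nb, include_blanks=True)
    _, r_ex, _ = estimate_null_em(counts, n_blank=nb, include_blanks=False)
    assert abs(r_in - r_ex) < 0.06


def test_moment_and_em_agree_on_large_samples():
    cfg = SimulationConfig(
        pop_sizes=[1500], n_loci=1, alleles_per_locus=8, null_freqs=[0.15], seed=5
    )
    ds, _ = simulate_dataset(cfg)
    est = estimate_nulls(ds, seed=0)
    key = ("POP1", "L01")
    assert abs(est.r_em[key] - est.r_chakraborty[key]) < 0.05
    assert abs(est.r_em[key] - est.r_brookfield1[key]) < 0.05


# ----------------------------------------------------------------------
# Genotype adjustment


def test_adjust_identity_when_no_nulls():
    cfg = SimulationConfig(pop_sizes=[100], n_loci=3, alleles_per_locus=6, seed=6)
    ds, _ = simulate_dataset(cfg)
    est = estimate_nulls(ds, seed=0)
    out = adjust_genotypes(ds, est)
    # unflagged or zero-estimate cells pass through
    changed = [k for k in ds.calls if out.calls[k] != ds.calls[k]]
    for ind, locus in changed:
        assert est.flagged[(ds.populations[ind], locus)]


def test_adjust_only_relabels_homozygotes_and_conserves_counts():
    cfg = SimulationConfig(
        pop_sizes=[200], n_loci=2, alleles_per_locus=6, null_freqs=[0.25, 0.25], seed=7
    )
    ds, _ = simulate_dataset(cfg)
    est = estimate_nulls(ds, seed=0)
    out = adjust_genotypes(ds, est)
    assert out.individuals == ds.individuals
    n_changed = 0
    for key in ds.calls:
        before, after = ds.calls[key], out.calls[key]
        if before == after:
            continue
        n_changed += 1
        # every change is hom (a,a) → (a, NULL)
        assert before is not BLANK and before[0] == before[1]
        assert after == tuple(sorted((before[0], NULL_ALLELE)))
    assert n_changed > 0


def test_adjust_relabel_counts_match_em_expectation():
    cfg = SimulationConfig(
        pop_sizes=[500], n_loci=1, alleles_per_locus=6, null_freqs=[0.25], seed=8
    )
    ds, _ = simulate_dataset(cfg)
    est = estimate_nulls(ds, seed=0)
    out = adjust_genotypes(ds, est)
    key = ("POP1", "L01")
    r = est.r_em[key]
    vis = est.em_visible[key]
    for allele, q in vis.items():
        n_hom = sum(
            1 for i in ds.individuals
            if ds.calls[(i, "L01")] == (allele, allele)
        )
        expected = n_hom * 2 * r / (q + 2 * r)
        got = sum(
            1 for i in ds.individuals
            if out.calls[(i, "L01")] == tuple(sorted((allele, NULL_ALLELE)))
        )
        assert abs(got - expected) <= 1.0


def test_adjustment_relieves_hardy_weinberg_disequilibrium():
    """Correcting a truly null-affected locus raises the HWE p-value in
    ≥90% of seeded replicates."""
    relieved = 0
    reps = 100
    for rep in range(reps):
        cfg = SimulationConfig(
            pop_sizes=[120], n_loci=1, alleles_per_locus=8,
            null_freqs=[0.25], seed=40000 + rep,
        )
        ds, _ = simulate_dataset(cfg)
        est = estimate_nulls(ds, seed=rep)
        out = adjust_genotypes(ds, est)
        p0 = hwe_test(ds, "POP1", "L01", 1500, 1500, seed=1)
        p1 = hwe_test(out, "POP1", "L01", 1500, 1500, seed=1)
        relieved += p1 > p0
    assert relieved >= 0.9 * reps


# ----------------------------------------------------------------------
# Expected blanks


def test_expected_blank_count_closed_form():
    assert expected_blank_count(0.139, 259) == pytest.approx(5.004, abs=0.01)
    assert expected_blank_count(0.0, 100) == 0.0
    assert expected_blank_count(1.0, 100) == 100.0
    with pytest.raises(ValueError):
        expected_blank_count(1.5, 10)
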