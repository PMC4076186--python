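"""Per-locus diversity summaries, exact Hardy–Weinberg tests, genotypic
linkage-disequilibrium tests, Bonferroni control and Weir–Cockerham F_IS.

The Hardy–Weinberg exact test comes in two flavours: full enumeration of
all genotype tables compatible with the observed allele counts (exact,
rational arithmetic, feasible for small samples) and a seeded Markov
chain over tables for realistic sample sizes.  Both use the Fisher
criterion: the p-value is the total probability of tables no more
probable than the observed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import _wc
from .data import GenotypeDataset

__all__ = [
    "locus_summary",
    "unbiased_he",
    "genotype_counts",
    "hwe_exact_enumeration",
    "hwe_exact_mc",
    "hwe_test",
    "global_hwe",
    "ld_genotypic_test",
    "bonferroni_threshold",
    "fis_weir_cockerham",
    "FisCoefficient",
]

GenotypeCounts = dict[tuple[int, int], int]


# ----------------------------------------------------------------------
# Summaries


def unbiased_he(freqs: dict[int, float], n_typed: int) -> float:
    """Unbiased expected heterozygosity (2n/(2n−1))·(1 − Σp²)."""
    if n_typed < 1:
        raise ValueError("need at least one typed genotype")
    plug_in = 1.0 - sum(p * p for p in freqs.values())
    return (2 * n_typed / (2 * n_typed - 1)) * plug_in


def genotype_counts(ds: GenotypeDataset, pop: str, locus: str) -> GenotypeCounts:
    """Observed genotype table (unordered pairs) for one population × locus."""
    counts: GenotypeCounts = {}
    for g in ds.typed_genotypes_at(pop, locus):
        counts[g] = counts.get(g, 0) + 1
    return counts


def locus_summary(
    ds: GenotypeDataset,
    hwe_steps: int = 1000,
    hwe_dememorization: int = 10000,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """N_A, Ho, unbiased He and exact-HWE p per (population, locus).

    Cells with no typed genotype are omitted.  The HWE p-value uses the
    Markov-chain exact test with the given chain settings.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for pop in ds.pop_order:
        for locus in ds.loci:
            typed = ds.typed_genotypes_at(pop, locus)
            if not typed:
                continue
            n = len(typed)
            alleles: dict[int, int] = {}
            het = 0
            for a, b in typed:
                alleles[a] = alleles.get(a, 0) + 1
                alleles[b] = alleles.get(b, 0) + 1
                het += a != b
            freqs = {al: c / (2 * n) for al, c in alleles.items()}
            counts = genotype_counts(ds, pop, locus)
            p = hwe_exact_mc(
                counts, hwe_steps, hwe_dememorization,
                np.random.default_rng(ss.spawn(1)[0]),
            )
            rows.append(
                {
                    "population": pop,
                    "locus": locus,
                    "n_typed": n,
                    "NA": len(alleles),
                    "Ho": het / n,
                    "He": unbiased_he(freqs, n),
                    "hwe_p": p,
                }
            )
    return pd.DataFrame(rows)


def global_hwe(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-locus Fisher combination of the per-population HWE p-values."""
    rows = []
    for locus, grp in summary.groupby("locus", sort=False):
        ps = grp["hwe_p"].clip(lower=1e-300)
        stat, p = sps.combine_pvalues(ps, method="fisher")
        rows.append({"locus": locus, "k": len(ps), "fisher_chi2": stat, "global_p": p})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Hardy–Weinberg exact tests


def _margins(counts: GenotypeCounts) -> dict[int, int]:
    m: dict[int, int] = {}
    for (a, b), c in counts.items():
        m[a] = m.get(a, 0) + c
        m[b] = m.get(b, 0) + c
    return m


def _table_prob(counts: GenotypeCounts, margins: dict[int, int]) -> Fraction:
    """Exact probability of a genotype table given its allele counts:
    n!·2^h·Πm_a! / ((2n)!·Πn_gg!)."""
    n = sum(counts.values())
    h = sum(c for (a, b), c in counts.items() if a != b)
    num = Fraction(math.factorial(n) * 2 ** h)
    for m in margins.values():
        num *= math.factorial(m)
    den = Fraction(math.factorial(2 * n))
    for c in counts.values():
        den *= math.factorial(c)
    return num / den


def _enumerate_tables(alleles: Sequence[int], remaining: dict[int, int]):
    """Yield all genotype tables (dicts) with the given allele-count margins."""
    if not alleles:
        yield {}
        return
    a, rest = alleles[0], alleles[1:]
    m = remaining[a]
    # choose homozygote count and a composition of the rest over pairs (a, b)
    def compositions(total, bs):
        if not bs:
            if total == 0:
                yield {}
            return
        b, tail = bs[0], bs[1:]
        for x in range(0, min(total, remaining[b]) + 1):
            for comp in compositions(total - x, tail):
                out = dict(comp)
                if x:
                    out[b] = x
                yield out

    for n_aa in range(m // 2, -1, -1):
        leftover = m - 2 * n_aa
        for comp in compositions(leftover, rest):
            sub_remaining = {b: remaining[b] - comp.get(b, 0) for b in rest}
            for subtable in _enumerate_tables(rest, sub_remaining):
                table = dict(subtable)
                if n_aa:
                    table[(a, a)] = n_aa
                for b, x in comp.items():
                    table[(a, b) if a <= b else (b, a)] = x
                yield table


def hwe_exact_enumeration(
    counts: GenotypeCounts, as_fraction: bool = False
) -> Union[float, Fraction]:
    """Exact HWE p-value by full enumeration (rational arithmetic).

    p = Σ P(T) over tables T with the observed allele counts and
    P(T) ≤ P(observed).  Monomorphic data → 1 by convention.
    """
    margins = _margins(counts)
    if len(margins) <= 1:
        return Fraction(1) if as_fraction else 1.0
    p_obs = _table_prob(counts, margins)
    alleles = sorted(margins)
    total = Fraction(0)
    p_value = Fraction(0)
    for table in _enumerate_tables(alleles, dict(margins)):
        p_t = _table_prob(table, margins)
        total += p_t
        if p_t <= p_obs:
            p_value += p_t
    assert total == 1, "table probabilities must sum to 1"
    return p_value if as_fraction else float(p_value)


def hwe_exact_mc(
    counts: GenotypeCounts,
    steps: int = 1000,
    dememorization: int = 10000,
    seed: Union[int, np.random.Generator, None] = None,
) -> float:
    """Markov-chain exact HWE test.

    The chain state is the set of ``n`` genotypes viewed as labelled
    gamete pairings; a step swaps one allele between two randomly chosen
    genotypes.  The proposal is symmetric and every labelled pairing is
    equally likely under the null, so the chain needs no accept/reject
    weighting and its marginal table distribution is the exact-test null.
    The p-value is the fraction of post-dememorization states whose table
    probability does not exceed the observed one.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    margins = _margins(counts)
    if len(margins) <= 1:
        return 1.0
    n = sum(counts.values())
    if n < 2:
        return 1.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    genotypes = [[g[0], g[1]] for g, c in sorted(counts.items()) for _ in range(c)]
    table: dict[tuple[int, int], int] = dict(counts)

    # log P(table) up to constants: h·log2 − Σ log(n_gg!)
    def log_w(tab):
        h = sum(c for (a, b), c in tab.items() if a != b)
        return h * math.log(2) - sum(math.lgamma(c + 1) for c in tab.values())

    logw = log_w(table)
    obs_logw = logw

    def key(pair):
        a, b = pair
        return (a, b) if a <= b else (b, a)

    hits = 0
    total_steps = dememorization + steps
    idx = rng.integers(0, n, size=2 * total_steps)
    slots = rng.integers(0, 2, size=2 * total_steps)
    log2 = math.log(2)
    for t in range(total_steps):
        i, j = idx[2 * t], idx[2 * t + 1]
        if i != j:
            gi, gj = genotypes[i], genotypes[j]
            si, sj = slots[2 * t], slots[2 * t + 1]
            old_i, old_j = key(gi), key(gj)
            gi[si], gj[sj] = gj[sj], gi[si]
            new_i, new_j = key(gi), key(gj)
            if new_i != old_i or new_j != old_j:
                for old in (old_i, old_j):
                    c = table[old]
                    logw += math.lgamma(c + 1) - math.lgamma(c)
                    if old[0] != old[1]:
                        logw -= log2
                    if c == 1:
                        del table[old]
                    else:
                        table[old] = c - 1
                for new in (new_i, new_j):
                    c = table.get(new, 0)
                    logw += math.lgamma(c + 1) - math.lgamma(c + 2)
                    if new[0] != new[1]:
                        logw += log2
                    table[new] = c + 1
        if t >= dememorization and logw <= obs_logw + 1e-9:
            hits += 1
    return hits / steps


def hwe_test(
    ds: GenotypeDataset,
    pop: str,
    locus: str,
    steps: int = 1000,
    dememorization: int = 10000,
    seed: Union[int, np.random.Generator, None] = None,
) -> float:
    """Convenience wrapper: Markov-chain exact HWE p for one cell."""
    return hwe_exact_mc(genotype_counts(ds, pop, locus), steps, dememorization, seed)


# ----------------------------------------------------------------------
# Linkage disequilibrium


def _contingency_logprob(table: np.ndarray) -> float:
    """Log-probability of a contingency table under fixed margins
    (Fisher criterion): log(Π r_i! Π c_j! / (N! Π n_ij!))."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()
    lp = (
        sum(math.lgamma(x + 1) for x in rows)
        + sum(math.lgamma(x + 1) for x in cols)
        - math.lgamma(n + 1)
        - sum(math.lgamma(x + 1) for x in table.ravel())
    )
    return lp


def ld_genotypic_test(
    ds: GenotypeDataset,
    locus_a: str,
    locus_b: str,
    population: str,
    iterations: int = 999,
    seed: Union[int, np.random.Generator, None] = None,
) -> float:
    """Permutation exact-style test of genotypic association between two loci.

    The statistic is the log-probability of the two-locus genotype
    contingency table; the null is realised by permuting one locus's
    genotypes among the individuals of the population.  The p-value uses
    the add-one correction.  A locus monomorphic in the population gives
    p = 1.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pairs = [
        (ds.calls[(i, locus_a)], ds.calls[(i, locus_b)])
        for i in ds.individuals_in(population)
    ]
    pairs = [(ga, gb) for ga, gb in pairs if ga is not None and gb is not None]
    if len(pairs) < 2:
        raise ValueError("need at least 2 individuals typed at both loci")
    ga_list = [g for g, _ in pairs]
    gb_list = [g for _, g in pairs]
    cats_a = sorted(set(ga_list))
    cats_b = sorted(set(gb_list))
    if len({a for g in ga_list for a in g}) <= 1 or len({a for g in gb_list for a in g}) <= 1:
        return 1.0
    ia = np.array([cats_a.index(g) for g in ga_list])
    ib = np.array([cats_b.index(g) for g in gb_list])

    def logprob(perm_b):
        table = np.zeros((len(cats_a), len(cats_b)), dtype=int)
        np.add.at(table, (ia, perm_b), 1)
        return _contingency_logprob(table)

    obs = logprob(ib)
    hits = 0
    for _ in range(iterations):
        if logprob(rng.permutation(ib)) <= obs + 1e-9:
            hits += 1
    return (hits + 1) / (iterations + 1)


def bonferroni_threshold(alpha: float, k: int) -> float:
    """Family-wise significance threshold alpha/k."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    return alpha / k


# ----------------------------------------------------------------------
# F_IS


@dataclass
class FisCoefficient:
    """Weir–Cockerham inbreeding estimates with bootstrap CI and
    randomization significance."""

    per_locus: dict[str, Optional[float]] = field(default_factory=dict)
    overall: float = float("nan")
    ci: Optional[tuple[float, float]] = None
    p: Optional[float] = None
    randomizations: int = 0
    seed: Optional[int] = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"locus": loc, "fis": f if f is not None else float("nan"),
             "evaluated": f is not None}
            for loc, f in self.per_locus.items()
        ]
        rows.append({"locus": "TOTAL", "fis": self.overall, "evaluated": True})
        return pd.DataFrame(rows)


def fis_weir_cockerham(
    ds: GenotypeDataset,
    pops: Optional[Sequence[str]] = None,
    randomizations: int = 0,
    seed: Optional[int] = None,
    bootstrap_ci: int = 1000,
) -> FisCoefficient:
    """Per-locus and overall f (F_IS) from Weir–Cockerham variance components.

    Overall f is the ratio of summed components over loci (never the mean
    of per-locus values).  Significance comes from randomizing alleles
    among individuals within samples (one-tailed, homozygote excess);
    the 95% CI on the overall value is a percentile bootstrap over loci.
    A locus with no within-population variation is flagged not evaluated
    (``None``).
    """
    if pops is None:
        pops = ds.pop_order
    comps = _wc.locus_components(ds, pops)
    per_locus: dict[str, Optional[float]] = {}
    usable = []
    for locus, (a, b, c) in comps.items():
        if b + c == 0.0:
            per_locus[locus] = None
        else:
            per_locus[locus] = 1.0 - c / (b + c)
            usable.append((a, b, c))
    overall = _wc.fis_from_components(usable) if usable else float("nan")

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    ci = None
    if bootstrap_ci and len(usable) >= 2:
        arr = np.array(usable)
        idx = rng.integers(0, len(usable), size=(bootstrap_ci, len(usable)))
        C = arr[:, 2][idx].sum(axis=1)
        BC = (arr[:, 1] + arr[:, 2])[idx].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            boots = 1.0 - C / BC
        boots = boots[np.isfinite(boots)]
        if boots.size:
            ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))

    p = None
    if randomizations:
        rng_p = np.random.default_rng(ss.spawn(1)[0])
        hits = 0
        for _ in range(randomizations):
            perm = _randomize_alleles_within_samples(ds, pops, rng_p)
            comps_p = _wc.locus_components(perm, pops)
            f_p = _wc.fis_from_components(
                [v for v in comps_p.values() if v[1] + v[2] != 0.0]
            )
            if f_p >= overall:
                hits += 1
        p = (hits + 1) / (randomizations + 1)
    return FisCoefficient(per_locus, overall, ci, p, randomizations, seed)


def _randomize_alleles_within_samples(
    ds: GenotypeDataset, pops: Sequence[str], rng: np.random.Generator
) -> GenotypeDataset:
    """Re-pair alleles at random among typed individuals within each sample."""
    new_calls = {}
    for pop in pops:
        inds = ds.individuals_in(pop)
        for locus in ds.loci:
            typed_inds = [i for i in inds if ds.calls[(i, locus)] is not None]
            if len(typed_inds) < 2:
                continue
            pool = []
            for i in typed_inds:
                pool.extend(ds.calls[(i, locus)])
            pool = np.array(pool)
            rng.shuffle(pool)
            for j, i in enumerate(typed_inds):
                a, b = int(pool[2 * j]), int(pool[2 * j + 1])
                new_calls[(i, locus)] = (a, b) if a <= b else (b, a)
    return ds.with_calls(new_calls)
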