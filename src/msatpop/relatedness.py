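"""Maximum-likelihood dyadic relatedness and relationship classification.

For a pair of non-inbred diploid individuals the IBD-sharing vector
k = (k0, k1, k2) gives the probabilities that the dyad shares 0, 1 or 2
alleles identical by descent; relatedness is r = k2 + k1/2.  The
canonical relationship categories sit at fixed points of the simplex:

    UR = (1, 0, 0)     HS = (1/2, 1/2, 0)
    FS = (1/4, 1/2, 1/4)   PO = (0, 1, 0)

The likelihood of an observed genotype pair at one locus is linear in k,

    P(g1, g2 | k) = k0·P(g1)P(g2) + k1·P(g1)·T1(g2|g1) + k2·P(g1)·T2(g2|g1),

with T1/T2 the one-/two-gene IBD transition probabilities.  Multiplying
over loci gives the dyad likelihood; a dyad is classified to the
category with the highest likelihood, and k (hence r) can be estimated
by maximising over the whole simplex.

Null alleles are accommodated by treating the null as an extra allele
and summing the likelihood over the true genotypes compatible with each
observation: an observed homozygote (i,i) may be (i,i) or (i,null), a
blank is (null,null).

All arithmetic in the scalar path is exact under ``fractions.Fraction``
inputs, which the test-suite's pedigree-enumeration oracle exploits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .data import BLANK, AlleleFrequencyTable, GenotypeDataset, pair_count
from .nulls import NULL_ALLELE

__all__ = [
    "KVector",
    "DyadRelationship",
    "CATEGORY_K",
    "dyad_locus_likelihood",
    "dyad_locus_components",
    "ml_relationship",
    "classify_dyads",
    "estimate_r_bulk",
    "dyad_frequency_table",
    "frequency_lookup",
]


@dataclass(frozen=True)
class KVector:
    """IBD-sharing probabilities (k0, k1, k2); must lie on the simplex."""

    k0: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        if min(self.k0, self.k1, self.k2) < -1e-12:
            raise ValueError("k coefficients must be non-negative")
        if abs(self.k0 + self.k1 + self.k2 - 1.0) > 1e-9:
            raise ValueError("k coefficients must sum to 1")

    @property
    def r(self) -> float:
        return self.k2 + self.k1 / 2.0


#: Canonical k-points, in tie-break priority order (least related first).
CATEGORY_K = {
    "UR": KVector(1.0, 0.0, 0.0),
    "HS": KVector(0.5, 0.5, 0.0),
    "FS": KVector(0.25, 0.5, 0.25),
    "PO": KVector(0.0, 1.0, 0.0),
}

DEFAULT_CATEGORIES = ("UR", "HS", "FS")


@dataclass
class DyadRelationship:
    """Classified pair of individuals."""

    pair: tuple[str, str]
    population: Optional[str]
    loglik: dict[str, float]
    ml_category: Optional[str]
    confidence: float
    r: Optional[float]
    n_loci_used: int
    ml_k: Optional[KVector] = None


# ----------------------------------------------------------------------
# Scalar likelihood (Fraction-safe)


def genotype_prob(g: tuple, freqs: dict):
    """Hardy–Weinberg probability of an unordered genotype."""
    a, b = g
    if a == b:
        return freqs[a] * freqs[a]
    return 2 * freqs[a] * freqs[b]


def transition_one(g1: tuple, g2: tuple, freqs: dict):
    """T1(g2 | g1): one gene IBD.  The shared gene is a uniformly chosen
    allele of g1; the other gene of g2 is an independent population draw."""
    a, b = g1
    c, d = g2
    total = 0
    for src in (a, b):
        if c == d:
            if src == c:
                total = total + freqs[c]
        else:
            if src == c:
                total = total + freqs[d]
            if src == d:
                total = total + freqs[c]
    if total == 0:
        return 0  # exact zero, keeps Fraction arithmetic exact
    return total / 2


def transition_two(g1: tuple, g2: tuple):
    """T2(g2 | g1): both genes IBD, so the genotypes must coincide."""
    return 1 if tuple(sorted(g1)) == tuple(sorted(g2)) else 0


def _expand_observed(g, null_allele=NULL_ALLELE):
    """True genotypes compatible with an observation under the null model."""
    if g is BLANK:
        return [(null_allele, null_allele)]
    a, b = g
    if a == b:
        return [(a, a), (a, null_allele)]
    return [(a, b)]


def dyad_locus_components(g1, g2, freqs: dict, with_nulls: bool = False):
    """(L0, L1, L2) such that P(g1,g2|k) = k0·L0 + k1·L1 + k2·L2.

    With ``with_nulls`` (frequencies must then include the null allele's
    frequency under the ``NULL_ALLELE`` key) the components are summed
    over all compatible true genotype pairs.
    """
    if with_nulls:
        pairs = [
            (t1, t2)
            for t1 in _expand_observed(g1)
            for t2 in _expand_observed(g2)
        ]
    else:
        if g1 is BLANK or g2 is BLANK:
            raise ValueError("blank genotype without null accommodation")
        pairs = [(g1, g2)]
    L0 = L1 = L2 = 0
    for t1, t2 in pairs:
        p1 = genotype_prob(t1, freqs)
        L0 = L0 + p1 * genotype_prob(t2, freqs)
        L1 = L1 + p1 * transition_one(t1, t2, freqs)
        L2 = L2 + p1 * transition_two(t1, t2)
    return L0, L1, L2


def dyad_locus_likelihood(g1, g2, freqs: dict, k: KVector, with_nulls: bool = False):
    """P(g1, g2 | k) at one locus.  Unknown alleles raise ``KeyError``."""
    L0, L1, L2 = dyad_locus_components(g1, g2, freqs, with_nulls)
    return k.k0 * L0 + k.k1 * L1 + k.k2 * L2


# ----------------------------------------------------------------------
# Frequencies plumbing


def frequency_lookup(
    freq_table: AlleleFrequencyTable, pop: str, locus: str
) -> Optional[tuple[dict, bool]]:
    """(frequency dict incl. null if present, with_nulls flag) for one cell."""
    if not freq_table.has(pop, locus):
        return None
    freqs = dict(freq_table.freqs[(pop, locus)])
    nf = freq_table.get_null(pop, locus)
    if nf > 0.0:
        freqs[NULL_ALLELE] = nf
        return freqs, True
    return freqs, False


# ----------------------------------------------------------------------
# Classification


def _category_logliks(components, categories):
    lls = {}
    for cat in categories:
        k = CATEGORY_K[cat]
        ll = 0.0
        for L0, L1, L2 in components:
            v = k.k0 * L0 + k.k1 * L1 + k.k2 * L2
            ll += math.log(v) if v > 0 else -math.inf
        lls[cat] = ll
    return lls


def _classify(lls: dict[str, float]):
    """Argmax with ties (within 1e-9) resolved toward the least related
    category, in CATEGORY_K priority order."""
    best = max(lls.values())
    for cat in CATEGORY_K:
        if cat in lls and lls[cat] >= best - 1e-9:
            winner = cat
            break
    finite = [v for v in lls.values() if v > -math.inf]
    if not finite:
        return winner, 0.0
    conf = float(math.exp(lls[winner] - logsumexp(list(lls.values()))))
    return winner, conf


def _pair_components(
    ds: GenotypeDataset,
    freq_table: AlleleFrequencyTable,
    a: str,
    b: str,
    freq_pop: str,
    cache: Optional[dict] = None,
):
    """Per-locus (L0, L1, L2) for a dyad; skips loci without usable data."""
    comps = []
    n_used = 0
    for locus in ds.loci:
        cell = frequency_lookup(freq_table, freq_pop, locus)
        if cell is None:
            continue
        freqs, with_nulls = cell
        g1 = ds.calls[(a, locus)]
        g2 = ds.calls[(b, locus)]
        if not with_nulls and (g1 is BLANK or g2 is BLANK):
            continue
        ckey = (freq_pop, locus, g1, g2)
        if cache is not None and ckey in cache:
            c = cache[ckey]
        else:
            c = dyad_locus_components(g1, g2, freqs, with_nulls)
            if cache is not None:
                cache[ckey] = c
        comps.append(c)
        if g1 is not BLANK and g2 is not BLANK and len(freqs) > 1:
            n_used += 1
    return comps, n_used


def ml_relationship(
    pair: tuple[str, str],
    ds: GenotypeDataset,
    freq_table: AlleleFrequencyTable,
    categories: Sequence[str] = DEFAULT_CATEGORIES,
    freq_pop: Optional[str] = None,
    min_informative_loci: int = 5,
    estimate_r: bool = True,
) -> DyadRelationship:
    """Classify one dyad and (optionally) estimate its ML k-vector and r.

    Frequencies default to the population sample containing the dyad
    (both members must then share a population).  r is estimated by a
    grid search over the k-simplex refined to ~1e-3 followed by a local
    polish, and is only reported when at least ``min_informative_loci``
    polymorphic loci are typed in both individuals.
    """
    a, b = pair
    if freq_pop is None:
        pa, pb = ds.populations[a], ds.populations[b]
        if pa != pb:
            raise ValueError(
                "dyad spans two populations; pass freq_pop explicitly"
            )
        freq_pop = pa
    comps, n_used = _pair_components(ds, freq_table, a, b, freq_pop)
    if not comps:
        return DyadRelationship((a, b), freq_pop, {}, None, 0.0, None, 0)
    lls = _category_logliks(comps, categories)
    winner, conf = _classify(lls)
    r = None
    ml_k = None
    if estimate_r and n_used >= min_informative_loci:
        arr = np.array(comps, dtype=float)[None, :, :]
        k1, k2 = _maximize_k(arr)
        k1, k2 = float(k1[0]), float(k2[0])
        k1, k2 = _polish_k(np.array(comps, dtype=float), k1, k2)
        ml_k = KVector(max(1.0 - k1 - k2, 0.0), k1, k2)
        r = ml_k.r
    return DyadRelationship((a, b), freq_pop, lls, winner, conf, r, n_used, ml_k)


def classify_dyads(
    ds: GenotypeDataset,
    freq_table: AlleleFrequencyTable,
    categories: Sequence[str] = DEFAULT_CATEGORIES,
    pops: Optional[Sequence[str]] = None,
) -> list[DyadRelationship]:
    """Classify every within-population dyad (no r estimation)."""
    out = []
    cache: dict = {}
    if pops is None:
        pops = ds.pop_order
    for pop in pops:
        inds = ds.individuals_in(pop)
        for i in range(len(inds)):
            for j in range(i + 1, len(inds)):
                a, b = inds[i], inds[j]
                comps, n_used = _pair_components(ds, freq_table, a, b, pop, cache)
                if not comps:
                    out.append(
                        DyadRelationship((a, b), pop, {}, None, 0.0, None, 0)
                    )
                    continue
                lls = _category_logliks(comps, categories)
                winner, conf = _classify(lls)
                out.append(
                    DyadRelationship((a, b), pop, lls, winner, conf, None, n_used)
                )
    return out


# ----------------------------------------------------------------------
# Bulk r estimation (vectorized grid refinement over the simplex)


def _triangle_grid(step: float) -> np.ndarray:
    m = int(round(1.0 / step))
    pts = [
        (i * step, j * step)
        for i in range(m + 1)
        for j in range(m + 1 - i)
    ]
    return np.array(pts)


def _loglik_at(X0, X1, X2, k1, k2):
    v = X0 * (1.0 - k1 - k2) + X1 * k1 + X2 * k2
    return np.log(np.clip(v, 1e-300, None)).sum(axis=-1)


def _maximize_k(components: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized grid refinement of (k1, k2) per dyad.

    ``components`` has shape (n_dyads, n_loci, 3); loci a dyad cannot use
    should hold (1, 1, 1) so they contribute nothing.  Returns per-dyad
    (k1, k2) to ~1e-3 resolution.
    """
    X0, X1, X2 = components[..., 0], components[..., 1], components[..., 2]
    P = components.shape[0]
    coarse = _triangle_grid(0.1)
    best_ll = np.full(P, -np.inf)
    best = np.zeros((P, 2))
    for k1, k2 in coarse:
        ll = _loglik_at(X0, X1, X2, k1, k2)
        better = ll > best_ll
        best_ll = np.where(better, ll, best_ll)
        best[better] = (k1, k2)
    step = 0.05
    offsets = np.array([(i, j) for i in range(-2, 3) for j in range(-2, 3)])
    while step > 5e-4:
        for oi, oj in offsets:
            k1 = best[:, 0] + oi * step
            k2 = best[:, 1] + oj * step
            valid = (k1 >= -1e-12) & (k2 >= -1e-12) & (k1 + k2 <= 1.0 + 1e-12)
            k1c = np.clip(k1, 0.0, 1.0)
            k2c = np.clip(k2, 0.0, 1.0)
            ll = _loglik_at(X0, X1, X2, k1c[:, None], k2c[:, None])
            ll = np.where(valid, ll, -np.inf)
            better = ll > best_ll + 1e-12
            best_ll = np.where(better, ll, best_ll)
            best[better, 0] = k1c[better]
            best[better, 1] = k2c[better]
        step /= 2.0
    return best[:, 0], best[:, 1]


def _polish_k(components: np.ndarray, k1: float, k2: float) -> tuple[float, float]:
    """Local constrained polish of a single dyad's (k1, k2)."""
    X0, X1, X2 = components[:, 0], components[:, 1], components[:, 2]

    def nll(x):
        return -_loglik_at(X0, X1, X2, x[0], x[1])

    res = minimize(
        nll,
        [k1, k2],
        method="SLSQP",
        bounds=[(0.0, 1.0), (0.0, 1.0)],
        constraints=[{"type": "ineq", "fun": lambda x: 1.0 - x[0] - x[1]}],
        options={"ftol": 1e-12, "maxiter": 200},
    )
    if res.success and -res.fun >= _loglik_at(X0, X1, X2, k1, k2) - 1e-9:
        return float(res.x[0]), float(res.x[1])
    return k1, k2


def estimate_r_bulk(
    ds: GenotypeDataset,
    freq_table: AlleleFrequencyTable,
    pairs: Sequence[tuple[str, str]],
    freq_pop: Union[str, None] = None,
    min_informative_loci: int = 5,
    chunk: int = 4096,
) -> np.ndarray:
    """ML relatedness r for many dyads at once (NaN where unclassifiable).

    ``freq_pop`` fixes one frequency column for every pair (e.g. a pooled
    sample); if ``None``, each pair uses its own population's frequencies
    and must be within-population.
    """
    n_loci = len(ds.loci)
    r_out = np.full(len(pairs), np.nan)
    cache: dict = {}
    for start in range(0, len(pairs), chunk):
        block = pairs[start : start + chunk]
        comp = np.ones((len(block), n_loci, 3))
        usable = np.zeros(len(block), dtype=int)
        for bi, (a, b) in enumerate(block):
            pop = freq_pop
            if pop is None:
                pa, pb = ds.populations[a], ds.populations[b]
                if pa != pb:
                    raise ValueError("cross-population pair needs freq_pop")
                pop = pa
            for li, locus in enumerate(ds.loci):
                cell = frequency_lookup(freq_table, pop, locus)
                if cell is None:
                    continue
                freqs, with_nulls = cell
                g1 = ds.calls[(a, locus)]
                g2 = ds.calls[(b, locus)]
                if not with_nulls and (g1 is BLANK or g2 is BLANK):
                    continue
                ckey = (pop, locus, g1, g2)
                c = cache.get(ckey)
                if c is None:
                    c = dyad_locus_components(g1, g2, freqs, with_nulls)
                    cache[ckey] = c
                comp[bi, li] = c
                if g1 is not BLANK and g2 is not BLANK and len(freqs) > 1:
                    usable[bi] += 1
        k1, k2 = _maximize_k(comp)
        r = k2 + k1 / 2.0
        r[usable < min_informative_loci] = np.nan
        r_out[start : start + len(block)] = r
    return r_out


# ----------------------------------------------------------------------
# Dyad frequency summaries


def dyad_frequency_table(
    ds: GenotypeDataset,
    freq_table_nna: AlleleFrequencyTable,
    freq_table_na: Optional[AlleleFrequencyTable] = None,
    categories: Sequence[str] = DEFAULT_CATEGORIES,
) -> pd.DataFrame:
    """Per-population frequencies of HS and FS dyads.

    Frequencies divide classified-dyad counts by n(n−1)/2.  When a
    second, null-aware frequency table is given the table carries the
    four columns HS_NNA / HS_NA / FS_NNA / FS_NA (no-null-accounting vs
    null-accounting), mirroring the usual with/without comparison.
    """
    def freq_block(freq_table):
        dyads = classify_dyads(ds, freq_table, categories)
        counts: dict[str, dict[str, int]] = {
            pop: {"HS": 0, "FS": 0} for pop in ds.pop_order
        }
        for d in dyads:
            if d.ml_category in ("HS", "FS"):
                counts[d.population][d.ml_category] += 1
        return counts

    nna = freq_block(freq_table_nna)
    na = freq_block(freq_table_na) if freq_table_na is not None else None
    rows = []
    for pop in ds.pop_order:
        n = ds.sample_size(pop)
        denom = pair_count(n) if n >= 2 else 1
        row = {
            "population": pop,
            "n": n,
            "HS_NNA": nna[pop]["HS"] / denom,
            "FS_NNA": nna[pop]["FS"] / denom,
        }
        if na is not None:
            row["HS_NA"] = na[pop]["HS"] / denom
            row["FS_NA"] = na[pop]["FS"] / denom
        rows.append(row)
    return pd.DataFrame(rows)
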