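"""Null-allele frequency estimation and genotype adjustment.

A null allele fails to amplify: a visible/null heterozygote is scored as
a visible homozygote and a null/null genotype as a blank, inflating
observed homozygosity.  This module provides the two classical moment
estimators (Chakraborty; Brookfield 1), an EM estimator that treats the
null as an extra allele (observed homozygotes are fractionally
reassigned between true homozygote and visible×null heterozygote, blanks
to null/null), and a deterministic correction that re-labels the
expected excess homozygotes as visible×null heterozygotes to produce the
"corrected" dataset used by the with/without-correction comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .data import BLANK, AlleleFrequencyTable, GenotypeDataset
from .diversity import genotype_counts, hwe_exact_mc, unbiased_he

__all__ = [
    "NULL_ALLELE",
    "NullEstimate",
    "estimate_null_moment",
    "estimate_null_em",
    "estimate_nulls",
    "adjust_genotypes",
    "expected_blank_count",
]

#: Reserved allele label for a null allele in adjusted datasets.  0 is the
#: missing-data code in GenePop, so the sentinel is a dedicated out-of-range
#: positive label that downstream likelihood code recognises.
NULL_ALLELE = 999


@dataclass
class NullEstimate:
    """Per (population, locus) null-allele frequency estimates."""

    r_chakraborty: dict[tuple[str, str], float] = field(default_factory=dict)
    r_brookfield1: dict[tuple[str, str], float] = field(default_factory=dict)
    r_em: dict[tuple[str, str], float] = field(default_factory=dict)
    em_visible: dict[tuple[str, str], dict[int, float]] = field(default_factory=dict)
    raw_visible: dict[tuple[str, str], dict[int, float]] = field(default_factory=dict)
    expected_blanks: dict[tuple[str, str], float] = field(default_factory=dict)
    flagged: dict[tuple[str, str], bool] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key in sorted(self.r_em):
            pop, locus = key
            rows.append(
                {
                    "population": pop,
                    "locus": locus,
                    "r_chakraborty": self.r_chakraborty.get(key, float("nan")),
                    "r_brookfield1": self.r_brookfield1.get(key, float("nan")),
                    "r_em": self.r_em[key],
                    "expected_blanks": self.expected_blanks.get(key, float("nan")),
                    "flagged": self.flagged.get(key, False),
                }
            )
        return pd.DataFrame(rows)

    def em_table(self, only_flagged: bool = True) -> AlleleFrequencyTable:
        """EM frequencies as an :class:`AlleleFrequencyTable` (visible + null).

        With ``only_flagged`` the null frequency is zeroed (and visible
        frequencies renormalised) for cells not flagged as null-affected,
        mirroring the practice of accommodating nulls only where detected.
        """
        out = AlleleFrequencyTable()
        for key, vis in self.em_visible.items():
            r = self.r_em[key]
            if only_flagged and not self.flagged.get(key, False):
                # fall back to plain counting frequencies so downstream
                # with/without comparisons are exact on unaffected cells
                if key in self.raw_visible:
                    out.freqs[key] = dict(self.raw_visible[key])
                else:
                    total = sum(vis.values())
                    out.freqs[key] = {a: v / total for a, v in vis.items()}
                out.null_freq[key] = 0.0
            else:
                out.freqs[key] = dict(vis)
                out.null_freq[key] = r
        return out


def estimate_null_moment(ho: float, he: float, method: str = "chakraborty") -> float:
    """Moment estimators of the null frequency from the heterozygote deficit.

    chakraborty: (He−Ho)/(He+Ho);  brookfield1: (He−Ho)/(1+He).
    Negative estimates clamp to 0; He = 0 (monomorphic) returns 0.
    """
    if not 0.0 <= ho <= 1.0 or not 0.0 <= he <= 1.0:
        raise ValueError("Ho and He must be in [0, 1]")
    if he == 0.0:
        return 0.0
    if method == "chakraborty":
        r = (he - ho) / (he + ho)
    elif method == "brookfield1":
        r = (he - ho) / (1.0 + he)
    else:
        raise ValueError(f"unknown method {method!r}")
    return max(r, 0.0)


def estimate_null_em(
    counts: dict[tuple[int, int], int],
    n_blank: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-10,
    include_blanks: bool = True,
) -> tuple[dict[int, float], float, list[float]]:
    """EM estimate of (visible frequencies, null frequency) at one locus.

    The null is an extra allele under Hardy–Weinberg.  E-step: each
    observed homozygote (i,i) splits between true (i,i) and (i,null) in
    ratio p_i : 2·p_null; blanks are (null,null).  M-step re-normalises
    gamete counts.  Returns the visible-frequency dict (summing to
    1 − r̂), the null frequency and the log-likelihood trace (guaranteed
    non-decreasing).

    With ``include_blanks=False`` the blank count is ignored and the EM
    maximises the likelihood conditional on amplification, via the
    standard truncated-data augmentation.
    """
    n_obs = sum(counts.values())
    if n_obs < 1:
        if n_blank > 0 and include_blanks:
            # boundary: nothing amplifies, the null is fixed
            return {}, 1.0, [0.0]
        raise ValueError("need at least one non-blank genotype")
    alleles = sorted({a for g in counts for a in g})
    k = len(alleles)
    idx = {a: i for i, a in enumerate(alleles)}

    hom = np.zeros(k)
    het_gametes = np.zeros(k)
    het_ia, het_ib, het_n = [], [], []
    for (a, b), c in counts.items():
        if a == b:
            hom[idx[a]] += c
        else:
            het_gametes[idx[a]] += c
            het_gametes[idx[b]] += c
            het_ia.append(idx[a])
            het_ib.append(idx[b])
            het_n.append(c)
    het_ia = np.array(het_ia, dtype=int)
    het_ib = np.array(het_ib, dtype=int)
    het_n = np.array(het_n, dtype=float)

    # init: counting frequencies with a small null mass
    p = np.full(k + 1, 0.0)
    p[:k] = 2 * hom + het_gametes
    p[:k] /= p[:k].sum()
    p[:k] *= 0.95
    p[k] = 0.05

    use_blanks = include_blanks
    trace: list[float] = []
    for _ in range(max_iter):
        pv, pn = p[:k], p[k]
        # E-step
        w_hom = np.where(pv + 2 * pn > 0, pv / np.where(pv + 2 * pn > 0, pv + 2 * pn, 1.0), 1.0)
        exp_true_hom = hom * w_hom            # stays (i,i)
        exp_null_het = hom * (1.0 - w_hom)    # becomes (i,null)
        if use_blanks:
            blanks = float(n_blank)
            n_eff = n_obs + n_blank
        else:
            # truncated-data augmentation: impute the unobserved nn class
            blanks = n_obs * pn ** 2 / max(1.0 - pn ** 2, 1e-12)
            n_eff = n_obs + blanks
        # M-step: gamete counting
        gam = 2 * exp_true_hom + exp_null_het + het_gametes
        gam_null = exp_null_het.sum() + 2 * blanks
        total = gam.sum() + gam_null
        p_new = np.append(gam, gam_null) / total

        # observed-data log-likelihood
        trace.append(_obs_loglik(p_new[:k], p_new[k], hom, het_ia, het_ib, het_n,
                                 n_blank if use_blanks else 0, n_obs, use_blanks))
        delta = np.abs(p_new - p).max()
        p = p_new
        if delta < tol:
            break

    def _obs_ll(pv_vec, pn_val):
        return _obs_loglik(pv_vec, pn_val, hom, het_ia, het_ib, het_n,
                           n_blank if use_blanks else 0, n_obs, use_blanks)

    # EM approaches the r = 0 boundary sublinearly; snap to the boundary
    # when the null-free solution is at least as likely.
    if (not n_blank or not use_blanks) and p[k] < 0.05:
        p0 = np.append(p[:k] / p[:k].sum(), 0.0)
        if _obs_ll(p0[:k], 0.0) >= _obs_ll(p[:k], p[k]) - 1e-9:
            p = p0
            trace.append(_obs_ll(p0[:k], 0.0))
    visible = {a: float(p[idx[a]]) for a in alleles}
    return visible, float(p[k]), trace


def _obs_loglik(pv, pn, hom, het_ia, het_ib, het_n, n_blank, n_obs, use_blanks):
    """Observed-data log-likelihood of the null-allele model."""
    with np.errstate(divide="ignore"):
        ll = float((hom * np.log(np.maximum(pv ** 2 + 2 * pv * pn, 1e-300))).sum())
        if het_n.size:
            ll += float(
                (het_n * np.log(np.maximum(2 * pv[het_ia] * pv[het_ib], 1e-300))).sum()
            )
    if use_blanks and n_blank:
        ll += n_blank * float(np.log(max(pn ** 2, 1e-300)))
    if not use_blanks:
        ll -= n_obs * float(np.log(max(1.0 - pn ** 2, 1e-300)))
    return ll


def estimate_nulls(
    ds: GenotypeDataset,
    flag_alpha: Optional[float] = 0.05,
    include_blanks: bool = True,
    hwe_steps: int = 2000,
    hwe_dememorization: int = 2000,
    seed: Optional[int] = None,
) -> NullEstimate:
    """All three estimators for every (population, locus) cell.

    A cell is flagged as potentially null-affected when its one-sided
    homozygote-excess signal is significant: exact-HWE p < ``flag_alpha``
    together with Ho < He (detection through strong deviation from HWE).
    ``expected_blanks`` is n·r̂_EM² over the whole sample (typed + blank).
    """
    ss = np.random.SeedSequence(seed)
    out = NullEstimate()
    for pop in ds.pop_order:
        n_pop = ds.sample_size(pop)
        for locus in ds.loci:
            typed = ds.typed_genotypes_at(pop, locus)
            if not typed:
                continue
            key = (pop, locus)
            n = len(typed)
            counts = genotype_counts(ds, pop, locus)
            allele_counts: dict[int, int] = {}
            het = 0
            for a, b in typed:
                allele_counts[a] = allele_counts.get(a, 0) + 1
                allele_counts[b] = allele_counts.get(b, 0) + 1
                het += a != b
            freqs = {al: c / (2 * n) for al, c in allele_counts.items()}
            ho = het / n
            he = unbiased_he(freqs, n)
            out.r_chakraborty[key] = estimate_null_moment(ho, min(he, 1.0), "chakraborty")
            out.r_brookfield1[key] = estimate_null_moment(ho, min(he, 1.0), "brookfield1")
            visible, r_em, _ = estimate_null_em(
                counts, n_blank=n_pop - n, include_blanks=include_blanks
            )
            out.r_em[key] = r_em
            out.em_visible[key] = visible
            out.raw_visible[key] = freqs
            out.expected_blanks[key] = expected_blank_count(r_em, n_pop)
            if flag_alpha is None or len(allele_counts) <= 1 or ho >= he:
                out.flagged[key] = False
            else:
                p = hwe_exact_mc(
                    counts, hwe_steps, hwe_dememorization,
                    np.random.default_rng(ss.spawn(1)[0]),
                )
                out.flagged[key] = p < flag_alpha
    return out


def adjust_genotypes(ds: GenotypeDataset, estimates: NullEstimate) -> GenotypeDataset:
    """Deterministic null-allele correction of flagged cells.

    For each allele class ``i`` at a flagged (population, locus) cell,
    the EM expectation says a fraction ``2·p_null/(p_i + 2·p_null)`` of
    the observed (i,i) homozygotes are really (i,null) heterozygotes.
    That many homozygotes (rounded) are re-labelled (i, NULL_ALLELE),
    largest residual first, ties by allele order, individuals in dataset
    order.  Unflagged cells pass through unchanged; the total genotype
    count is conserved and no new visible allele ever appears.
    """
    new_calls = {}
    for (pop, locus), flagged in estimates.flagged.items():
        if not flagged:
            continue
        vis = estimates.em_visible[(pop, locus)]
        r = estimates.r_em[(pop, locus)]
        if r <= 0.0:
            continue
        inds = ds.individuals_in(pop)
        hom_carriers: dict[int, list[str]] = {}
        for ind in inds:
            g = ds.calls[(ind, locus)]
            if g is not BLANK and g[0] == g[1]:
                hom_carriers.setdefault(g[0], []).append(ind)
        expected: list[tuple[int, float]] = []
        for allele in sorted(hom_carriers):
            p_i = vis.get(allele, 0.0)
            frac = 2 * r / (p_i + 2 * r) if (p_i + 2 * r) > 0 else 0.0
            expected.append((allele, len(hom_carriers[allele]) * frac))
        # integer allocation: floors, then extra units to largest residuals
        # (ties by allele order), capped at the homozygotes actually present
        target = int(round(sum(e for _, e in expected)))
        floors = {al: int(np.floor(e)) for al, e in expected}
        residuals = sorted(
            ((e - floors[al], al) for al, e in expected),
            key=lambda t: (-t[0], t[1]),
        )
        extra = max(target - sum(floors.values()), 0)
        alloc = dict(floors)
        for _, al in residuals[:extra]:
            alloc[al] += 1
        for allele, n_relabel in alloc.items():
            carriers = hom_carriers[allele]
            for ind in carriers[: min(n_relabel, len(carriers))]:
                new_calls[(ind, locus)] = (allele, NULL_ALLELE)
    return ds.with_calls(new_calls) if new_calls else ds


def expected_blank_count(null_freq: float, n: int) -> float:
    """Expected null/null blanks among n individuals: n·r²."""
    if not 0.0 <= null_freq <= 1.0:
        raise ValueError("null_freq must be in [0, 1]")
    return n * null_freq ** 2
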