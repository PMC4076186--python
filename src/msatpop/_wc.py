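"""Weir–Cockerham (1984) variance components, shared by F_IS and F_ST code.

For each locus and allele the classic components are
``a`` (among populations), ``b`` (among individuals within populations)
and ``c`` (within individuals).  Multilocus estimators are ratios of
sums:  θ = Σa / Σ(a+b+c)  and  f (F_IS) = 1 − Σc / Σ(b+c).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .data import GenotypeDataset


def pop_locus_stats(ds: GenotypeDataset, pops: Sequence[str], locus: str):
    """Per population: typed count, allele frequencies, per-allele heterozygote
    frequencies (fraction of typed individuals heterozygous *and* carrying the
    allele).  Populations with no typed genotype are dropped."""
    stats = []
    for pop in pops:
        typed = ds.typed_genotypes_at(pop, locus)
        if not typed:
            continue
        n = len(typed)
        counts: dict[int, int] = {}
        hets: dict[int, int] = {}
        for a, b in typed:
            counts[a] = counts.get(a, 0) + 1
            counts[b] = counts.get(b, 0) + 1
            if a != b:
                hets[a] = hets.get(a, 0) + 1
                hets[b] = hets.get(b, 0) + 1
        p = {al: c / (2 * n) for al, c in counts.items()}
        h = {al: hets.get(al, 0) / n for al in counts}
        stats.append((n, p, h))
    return stats


def components_from_stats(stats) -> tuple[float, float, float]:
    """Summed-over-alleles (a, b, c) for one locus.

    ``stats`` is a list of ``(n_i, p_i, h_i)`` per population as returned
    by :func:`pop_locus_stats`.  With a single population the among-
    population component is identically 0.
    """
    r = len(stats)
    if r == 0:
        return (0.0, 0.0, 0.0)
    n = np.array([s[0] for s in stats], dtype=float)
    nbar = n.mean()
    if nbar <= 1.0:
        return (0.0, 0.0, 0.0)
    alleles = sorted({al for _, p, _ in stats for al in p})
    if r > 1:
        n_c = (r * nbar - (n ** 2).sum() / (r * nbar)) / (r - 1)
    else:
        n_c = nbar
    A = B = C = 0.0
    for al in alleles:
        p_i = np.array([p.get(al, 0.0) for _, p, _ in stats])
        h_i = np.array([h.get(al, 0.0) for _, _, h in stats])
        pbar = (n * p_i).sum() / (r * nbar)
        hbar = (n * h_i).sum() / (r * nbar)
        if pbar <= 0.0 or pbar >= 1.0:
            continue
        if r > 1:
            s2 = (n * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            a = (nbar / n_c) * (
                s2
                - (1.0 / (nbar - 1))
                * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
            )
        else:
            s2 = 0.0
            a = 0.0
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2.0
        A += a
        B += b
        C += c
    return (A, B, C)


def locus_components(
    ds: GenotypeDataset, pops: Optional[Sequence[str]] = None
) -> dict[str, tuple[float, float, float]]:
    """Per-locus (a, b, c) sums over alleles for the given populations."""
    if pops is None:
        pops = ds.pop_order
    return {
        locus: components_from_stats(pop_locus_stats(ds, pops, locus))
        for locus in ds.loci
    }


def theta_from_components(comps) -> float:
    """Multilocus θ = Σa / Σ(a+b+c) (ratio of sums, never mean of ratios)."""
    A = sum(a for a, _, _ in comps)
    T = sum(a + b + c for a, b, c in comps)
    return A / T if T != 0 else float("nan")


def fis_from_components(comps) -> float:
    """Multilocus f = 1 − Σc / Σ(b+c)."""
    C = sum(c for _, _, c in comps)
    BC = sum(b + c for _, b, c in comps)
    return 1.0 - C / BC if BC != 0 else float("nan")
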