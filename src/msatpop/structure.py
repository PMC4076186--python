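"""Weir–Cockerham F_ST with permutation significance, locus-bootstrap
confidence intervals, and the ENA null-allele correction.

θ is the ratio-of-sums estimator over variance components a (among
populations), b (among individuals within populations) and c (within
individuals), summed over alleles and loci.  Negative values are
reported as computed (they are part of the estimator's sampling
distribution around 0); a display option floors them at 0.

The ENA ("excluding null alleles") correction recomputes each
population × locus cell's allele frequencies and per-allele heterozygote
frequencies as their EM expectations under the null-allele model —
observed homozygotes are fractionally reassigned to visible×null
heterozygotes and blanks to null/null — and the null class itself is
excluded from the per-allele sums.  When every EM null estimate is 0
the corrected θ equals the raw one exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import _wc
from .data import GenotypeDataset
from .nulls import NullEstimate

__all__ = [
    "wc_theta",
    "per_locus_theta",
    "fst_permutation_p",
    "global_fst_permutation_p",
    "fst_bootstrap_ci",
    "ena_corrected_theta",
    "pairwise_fst",
    "FstMatrix",
]


def wc_theta(
    ds: GenotypeDataset,
    pops: Optional[Sequence[str]] = None,
    return_components: bool = False,
):
    """Multilocus Weir–Cockerham θ (and optionally per-locus components)."""
    if pops is None:
        pops = ds.pop_order
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    comps = _wc.locus_components(ds, pops)
    theta = _wc.theta_from_components(list(comps.values()))
    if return_components:
        return theta, comps
    return theta


def per_locus_theta(ds: GenotypeDataset, pops: Optional[Sequence[str]] = None) -> pd.Series:
    """θ per locus (NaN where undefined)."""
    if pops is None:
        pops = ds.pop_order
    comps = _wc.locus_components(ds, pops)
    out = {}
    for locus, (a, b, c) in comps.items():
        tot = a + b + c
        out[locus] = a / tot if tot != 0 else float("nan")
    return pd.Series(out)


# ----------------------------------------------------------------------
# Fast two-population permutation


def _encode(ds: GenotypeDataset, inds: Sequence[str]):
    """Per locus: allele-index matrix (n, 2) with -1 for blanks."""
    enc = []
    for locus in ds.loci:
        alleles = sorted(
            {a for i in inds for a in (ds.calls[(i, locus)] or ())}
        )
        idx = {a: k for k, a in enumerate(alleles)}
        mat = np.full((len(inds), 2), -1, dtype=int)
        for row, i in enumerate(inds):
            g = ds.calls[(i, locus)]
            if g is not None:
                mat[row, 0] = idx[g[0]]
                mat[row, 1] = idx[g[1]]
        enc.append((mat, len(alleles)))
    return enc


def _components_encoded(mat: np.ndarray, n_alleles: int, groups: np.ndarray, n_groups: int):
    """(a, b, c) sums over alleles for one locus from an encoded matrix."""
    typed = mat[:, 0] >= 0
    if n_alleles < 1 or not typed.any():
        return (0.0, 0.0, 0.0)
    g = groups[typed]
    m = mat[typed]
    n_i = np.bincount(g, minlength=n_groups).astype(float)
    present = n_i > 0
    r = int(present.sum())
    if r < 1:
        return (0.0, 0.0, 0.0)
    counts = np.zeros((n_groups, n_alleles))
    np.add.at(counts, (g, m[:, 0]), 1.0)
    np.add.at(counts, (g, m[:, 1]), 1.0)
    het = np.zeros((n_groups, n_alleles))
    hmask = m[:, 0] != m[:, 1]
    np.add.at(het, (g[hmask], m[hmask, 0]), 1.0)
    np.add.at(het, (g[hmask], m[hmask, 1]), 1.0)
    n_i = n_i[present]
    counts = counts[present]
    het = het[present]
    nbar = n_i.mean()
    if nbar <= 1.0:
        return (0.0, 0.0, 0.0)
    p = counts / (2 * n_i[:, None])
    h = het / n_i[:, None]
    pbar = (n_i[:, None] * p).sum(axis=0) / (r * nbar)
    hbar = (n_i[:, None] * h).sum(axis=0) / (r * nbar)
    keep = (pbar > 0) & (pbar < 1)
    if not keep.any():
        return (0.0, 0.0, 0.0)
    p, h, pbar, hbar = p[:, keep], h[:, keep], pbar[keep], hbar[keep]
    if r > 1:
        n_c = (r * nbar - (n_i ** 2).sum() / (r * nbar)) / (r - 1)
        s2 = (n_i[:, None] * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        a = (nbar / n_c) * (
            s2
            - (1.0 / (nbar - 1))
            * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4.0)
        )
    else:
        s2 = np.zeros_like(pbar)
        a = np.zeros_like(pbar)
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2.0
    return (float(a.sum()), float(b.sum()), float(c.sum()))


def _theta_encoded(enc, groups, n_groups) -> float:
    A = T = 0.0
    for mat, k in enc:
        a, b, c = _components_encoded(mat, k, groups, n_groups)
        A += a
        T += a + b + c
    return A / T if T != 0 else float("nan")


def fst_permutation_p(
    ds: GenotypeDataset,
    pop_a: str,
    pop_b: str,
    iterations: int = 999,
    seed: Union[int, np.random.Generator, None] = None,
) -> float:
    """One-tailed permutation p for pairwise θ.

    Individuals (whole genotype rows) are permuted between the two
    samples, sizes preserved; p uses the add-one correction.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    inds = ds.individuals_in(pop_a) + ds.individuals_in(pop_b)
    n_a = ds.sample_size(pop_a)
    enc = _encode(ds, inds)
    groups = np.array([0] * n_a + [1] * (len(inds) - n_a))
    observed = _theta_encoded(enc, groups, 2)
    hits = 0
    for _ in range(iterations):
        perm = rng.permutation(groups)
        if _theta_encoded(enc, perm, 2) >= observed - 1e-15:
            hits += 1
    return (hits + 1) / (iterations + 1)


def global_fst_permutation_p(
    ds: GenotypeDataset,
    iterations: int = 999,
    seed: Union[int, np.random.Generator, None] = None,
) -> float:
    """Permutation p for the global θ (individuals shuffled among all samples)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pops = ds.pop_order
    inds = [i for p in pops for i in ds.individuals_in(p)]
    enc = _encode(ds, inds)
    groups = np.array([pops.index(ds.populations[i]) for i in inds])
    observed = _theta_encoded(enc, groups, len(pops))
    hits = 0
    for _ in range(iterations):
        perm = rng.permutation(groups)
        if _theta_encoded(enc, perm, len(pops)) >= observed - 1e-15:
            hits += 1
    return (hits + 1) / (iterations + 1)


def fst_bootstrap_ci(
    ds: GenotypeDataset,
    pops: Optional[Sequence[str]] = None,
    iterations: int = 50000,
    seed: Optional[int] = None,
    components: Optional[dict] = None,
) -> tuple[float, float]:
    """Percentile 95% CI for multilocus θ by bootstrapping loci."""
    if pops is None:
        pops = ds.pop_order
    if components is None:
        _, components = wc_theta(ds, pops, return_components=True)
    arr = np.array(list(components.values()))  # (L, 3)
    if arr.shape[0] < 2:
        raise ValueError("bootstrap CI undefined with a single locus")
    rng = np.random.default_rng(seed)
    L = arr.shape[0]
    idx = rng.integers(0, L, size=(iterations, L))
    A = arr[:, 0][idx].sum(axis=1)
    T = arr.sum(axis=1)[idx].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        thetas = A / T
    thetas = thetas[np.isfinite(thetas)]
    return (float(np.percentile(thetas, 2.5)), float(np.percentile(thetas, 97.5)))


# ----------------------------------------------------------------------
# ENA correction


def _ena_stats(
    ds: GenotypeDataset, estimates: NullEstimate, pop: str, locus: str
):
    """(n, p, h) for one cell with EM-expected null reassignment.

    ``p`` are the EM visible-allele frequencies on the absolute scale
    (they sum to 1 − r̂; the null class is simply excluded from the
    per-allele sums).  ``h`` counts, per visible allele, the observed
    heterozygotes plus the EM-expected visible×null heterozygotes hiding
    among the observed homozygotes; blanks enter the sample size as
    null/null individuals.  With r̂ = 0 this returns exactly the raw
    typed-only statistics, so the corrected θ reduces to the
    uncorrected one.
    """
    typed = ds.typed_genotypes_at(pop, locus)
    if not typed:
        return None
    key = (pop, locus)
    r = estimates.r_em.get(key, 0.0)
    if r >= 1.0:
        return None  # locus dropped (nothing visible under the model)
    counts: dict[int, float] = {}
    hets: dict[int, float] = {}
    for a, b in typed:
        counts[a] = counts.get(a, 0.0) + 1.0
        counts[b] = counts.get(b, 0.0) + 1.0
        if a != b:
            hets[a] = hets.get(a, 0.0) + 1.0
            hets[b] = hets.get(b, 0.0) + 1.0
    if r <= 0.0:
        n = float(len(typed))
        p = {al: c / (2 * n) for al, c in counts.items()}
        h = {al: hets.get(al, 0.0) / n for al in counts}
        return (n, p, h)
    vis = estimates.em_visible.get(key, {})
    for a, b in typed:
        if a == b:
            q = vis.get(a, 0.0)
            w = q / (q + 2 * r) if (q + 2 * r) > 0 else 1.0
            hets[a] = hets.get(a, 0.0) + (1.0 - w)
    n = float(ds.sample_size(pop))
    p = {al: vis.get(al, 0.0) for al in counts}
    h = {al: hets.get(al, 0.0) / n for al in counts}
    return (n, p, h)


def ena_corrected_theta(
    ds: GenotypeDataset,
    estimates: NullEstimate,
    pops: Optional[Sequence[str]] = None,
    return_components: bool = False,
):
    """Multilocus θ with the ENA null-allele correction.

    Uses EM-expected visible-allele frequencies and heterozygote
    frequencies per cell; the null class is excluded from the per-allele
    sums.  Cells with r̂ = 1 are dropped with the locus flagged.
    """
    if pops is None:
        pops = ds.pop_order
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    comps = {}
    for locus in ds.loci:
        stats = []
        for pop in pops:
            cell = _ena_stats(ds, estimates, pop, locus)
            if cell is not None:
                stats.append(cell)
        comps[locus] = _wc.components_from_stats(stats)
    theta = _wc.theta_from_components(list(comps.values()))
    if return_components:
        return theta, comps
    return theta


# ----------------------------------------------------------------------
# Pairwise matrix


@dataclass
class FstMatrix:
    """Pairwise θ (below-diagonal values), permutation p-values, and the
    global estimate with its locus-bootstrap CI."""

    theta: pd.DataFrame
    p: pd.DataFrame
    global_theta: float
    global_ci: Optional[tuple[float, float]]
    global_p: Optional[float]
    ena_corrected: bool = False

    def display(self, floor_zero: bool = True) -> pd.DataFrame:
        """θ below the diagonal, p above (report layout)."""
        pops = list(self.theta.index)
        out = pd.DataFrame("", index=pops, columns=pops)
        for i, a in enumerate(pops):
            for j, b in enumerate(pops):
                if i > j:
                    v = self.theta.loc[a, b]
                    if floor_zero:
                        v = max(v, 0.0)
                    out.loc[a, b] = f"{v:.4f}"
                elif i < j:
                    out.loc[a, b] = f"{self.p.loc[a, b]:.4f}"
        return out


def pairwise_fst(
    ds: GenotypeDataset,
    iterations: int = 999,
    seed: Optional[int] = None,
    bootstrap_iterations: int = 50000,
    global_p_iterations: Optional[int] = None,
) -> FstMatrix:
    """Pairwise θ matrix with permutation p-values plus the global θ,
    its 95% locus-bootstrap CI and a global permutation p."""
    pops = ds.pop_order
    ss = np.random.SeedSequence(seed)
    theta = pd.DataFrame(np.nan, index=pops, columns=pops)
    pmat = pd.DataFrame(np.nan, index=pops, columns=pops)
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            sub_pops = [pops[i], pops[j]]
            t = wc_theta(ds, sub_pops)
            p = fst_permutation_p(
                ds, pops[i], pops[j], iterations,
                np.random.default_rng(ss.spawn(1)[0]),
            )
            theta.iloc[i, j] = theta.iloc[j, i] = t
            pmat.iloc[i, j] = pmat.iloc[j, i] = p
    g_theta, comps = wc_theta(ds, pops, return_components=True)
    ci = None
    if len(ds.loci) >= 2 and bootstrap_iterations:
        ci = fst_bootstrap_ci(
            ds, pops, bootstrap_iterations,
            int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31)),
            components=comps,
        )
    gp = None
    if global_p_iterations:
        gp = global_fst_permutation_p(
            ds, global_p_iterations, np.random.default_rng(ss.spawn(1)[0])
        )
    return FstMatrix(theta, pmat, g_theta, ci, gp)
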