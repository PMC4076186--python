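"""Inference on relatedness patterns: mean intra/inter-population r,
permutation tests of kin aggregation, and paired t-tests for the
with/without-null-correction comparisons.

The permutation test asks whether the mean pairwise relatedness within
(or between) population samples is higher than expected by chance: dyad
r values are computed once over the pooled dataset, then individuals'
population labels are permuted globally (sample sizes preserved) and
each cell's mean is recomputed by re-indexing — the genotypes, and hence
the multiset of dyad r values, never change.  p-values are one-tailed
upper with the add-one correction, so never exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data import GenotypeDataset
from .relatedness import estimate_r_bulk
from .data import allele_frequencies

__all__ = [
    "mean_pairwise_r",
    "pairwise_r_matrix",
    "RelatednessMatrix",
    "PermutationResult",
    "relatedness_permutation_test",
    "paired_t_test",
]


def mean_pairwise_r(
    dyads,
    populations: dict[str, str],
    pop_a: str,
    pop_b: str,
) -> float:
    """Arithmetic mean r over dyads spanning (pop_a, pop_b).

    ``dyads`` is any iterable of objects with ``pair`` and ``r``
    attributes (e.g. :class:`~msatpop.relatedness.DyadRelationship`).
    Intra-population means (pop_a == pop_b) use all within pairs.  Dyads
    with missing r are skipped; no valid dyad raises ``ValueError``.
    """
    vals = []
    for d in dyads:
        if d.r is None or (isinstance(d.r, float) and np.isnan(d.r)):
            continue
        pa, pb = populations[d.pair[0]], populations[d.pair[1]]
        if {pa, pb} == {pop_a, pop_b}:
            vals.append(d.r)
    if not vals:
        raise ValueError(f"no valid dyad across ({pop_a}, {pop_b})")
    return float(np.mean(vals))


def pairwise_r_matrix(
    ds: GenotypeDataset,
    freq_table=None,
    min_informative_loci: int = 5,
) -> np.ndarray:
    """Symmetric N×N matrix of ML relatedness over *all* individual pairs.

    Frequencies come from the pooled dataset (one frequency vector per
    locus), matching a single whole-dataset likelihood run; pass a
    prepared table (e.g. EM frequencies with nulls) to override.
    """
    inds = ds.individuals
    if freq_table is None:
        pooled = GenotypeDataset(
            inds, {i: "ALL" for i in inds}, ds.loci, ds.calls
        )
        freq_table = allele_frequencies(pooled)
        freq_pop = "ALL"
    else:
        pops = {p for (p, _) in freq_table.freqs}
        if len(pops) != 1:
            raise ValueError("pooled frequency table must have a single label")
        freq_pop = next(iter(pops))
    pairs = [
        (inds[i], inds[j])
        for i in range(len(inds))
        for j in range(i + 1, len(inds))
    ]
    r = estimate_r_bulk(ds, freq_table, pairs, freq_pop, min_informative_loci)
    mat = np.zeros((len(inds), len(inds)))
    k = 0
    for i in range(len(inds)):
        for j in range(i + 1, len(inds)):
            mat[i, j] = mat[j, i] = r[k]
            k += 1
    return mat


@dataclass
class RelatednessMatrix:
    """Mean pairwise r per population pair (intra on the diagonal)."""

    means: pd.DataFrame
    counts: pd.DataFrame


@dataclass
class PermutationResult:
    """Observed cell means and one-tailed permutation p-values."""

    observed: pd.DataFrame
    p: pd.DataFrame
    n_permutations: int
    seed: Optional[int]


def _cell_means(R: np.ndarray, Z: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """Mean pairwise r per population pair from indicator matrix Z (N×P)."""
    S = Z.T @ R @ Z
    out = np.full(S.shape, np.nan)
    P = S.shape[0]
    for a in range(P):
        for b in range(P):
            if a == b:
                n = sizes[a]
                if n >= 2:
                    out[a, a] = S[a, a] / (n * (n - 1))
            else:
                out[a, b] = S[a, b] / (sizes[a] * sizes[b])
    return out


def relatedness_permutation_test(
    ds: GenotypeDataset,
    n_permutations: int = 1000,
    seed: Optional[int] = None,
    freq_table=None,
    r_matrix: Optional[np.ndarray] = None,
    min_informative_loci: int = 5,
) -> PermutationResult:
    """Monte-Carlo test that intra/inter-sample mean r exceeds chance.

    Population labels are permuted globally across all individuals each
    iteration; dyad r values are fixed and only re-indexed.  Cells for
    populations of size 1 are flagged absent (NaN).
    """
    pops = ds.pop_order
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    rng = np.random.default_rng(seed)
    if r_matrix is None:
        r_matrix = pairwise_r_matrix(ds, freq_table, min_informative_loci)
    R = np.nan_to_num(r_matrix, nan=0.0)
    np.fill_diagonal(R, 0.0)
    labels = np.array([pops.index(ds.populations[i]) for i in ds.individuals])
    sizes = np.bincount(labels, minlength=len(pops))
    N = len(ds.individuals)
    Z = np.zeros((N, len(pops)))
    Z[np.arange(N), labels] = 1.0
    observed = _cell_means(R, Z, sizes)
    exceed = np.zeros_like(observed)
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        Zp = np.zeros_like(Z)
        Zp[np.arange(N), perm] = 1.0
        means = _cell_means(R, Zp, sizes)
        exceed += (means >= observed - 1e-15).astype(float)
    pvals = (exceed + 1.0) / (n_permutations + 1.0)
    pvals[np.isnan(observed)] = np.nan
    idx = list(pops)
    return PermutationResult(
        pd.DataFrame(observed, index=idx, columns=idx),
        pd.DataFrame(pvals, index=idx, columns=idx),
        n_permutations,
        seed,
    )


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Classic paired two-tailed t-test on per-sample differences.

    Returns (t, df, p) with df = n−1.  All-zero differences give
    (0, df, 1) by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 paired observations")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return 0.0, n - 1, 1.0
        # constant nonzero difference: t is infinite, p -> 0
        return float(np.inf) * np.sign(d.mean()), n - 1, 0.0
    res = sps.ttest_rel(x, y)
    return float(res.statistic), n - 1, float(res.pvalue)
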