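"""Shared fixtures and tiny dataset builders."""

import numpy as np
import pytest

from msatpop.data import GenotypeDataset


def build_dataset(pop_genotypes, loci=None):
    """Construct a dataset from {pop: [genotype-tuple-per-locus, ...]}.

    ``pop_genotypes`` maps population label → list of individuals, each a
    list with one genotype (pair or None) per locus.
    """
    first = next(iter(pop_genotypes.values()))
    n_loci = len(first[0])
    loci = loci or [f"L{i+1}" for i in range(n_loci)]
    individuals, populations, calls = [], {}, {}
    k = 0
    for pop, inds in pop_genotypes.items():
        for genos in inds:
            k += 1
            name = f"{pop}_{k:03d}"
            individuals.append(name)
            populations[name] = pop
            for locus, g in zip(loci, genos):
                calls[(name, locus)] = g
    return GenotypeDataset(individuals, populations, loci, calls)


@pytest.fixture
def two_pop_ds():
    """Two small populations at one locus."""
    return build_dataset(
        {
            "A": [[(1, 1)], [(1, 2)], [(2, 2)], [(1, 2)]],
            "B": [[(1, 1)], [(1, 1)], [(1, 2)], [(2, 2)]],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
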