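"""Core data structures for co-dominant microsatellite genotypes.

A :class:`GenotypeDataset` holds diploid genotypes (unordered pairs of
positive integer allele labels, typically fragment sizes in base pairs)
for a set of individuals grouped into population samples.  A missing
genotype — complete amplification failure at a locus — is a *blank*,
represented by ``None``.  Half-called genotypes do not occur in this
data model and are rejected on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

#: Missing genotype (complete amplification failure).
BLANK = None

Genotype = Optional[tuple[int, int]]


class ValidationError(ValueError):
    """A dataset violates a structural invariant."""


@dataclass
class LocusMeta:
    """Descriptive marker information (motif, size range in bp)."""

    name: str
    repeat_motif: Optional[str] = None
    size_range: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.size_range is not None and self.size_range[0] > self.size_range[1]:
            raise ValidationError(
                f"locus {self.name}: size_range min {self.size_range[0]} "
                f"> max {self.size_range[1]}"
            )


def _normalize_call(call: Genotype) -> Genotype:
    if call is BLANK:
        return BLANK
    a, b = call
    a, b = int(a), int(b)
    if a <= 0 or b <= 0:
        raise ValidationError(f"allele labels must be positive integers, got {call}")
    return (a, b) if a <= b else (b, a)


class GenotypeDataset:
    """Individuals × loci genotype matrix with population labels.

    Parameters
    ----------
    individuals : ordered identifiers (unique).
    populations : mapping individual → population label.
    loci : ordered locus names.
    calls : mapping ``(individual, locus)`` → allele pair or ``BLANK``.
        Missing keys are treated as ``BLANK``.

    Individual and population order is preserved exactly as given so that
    seeded permutation procedures downstream are reproducible.
    """

    def __init__(
        self,
        individuals: Sequence[str],
        populations: Mapping[str, str],
        loci: Sequence[str],
        calls: Mapping[tuple[str, str], Genotype],
    ) -> None:
        self.individuals = list(individuals)
        if len(set(self.individuals)) != len(self.individuals):
            dup = [i for i in self.individuals if self.individuals.count(i) > 1]
            raise ValidationError(f"duplicate individual ids: {sorted(set(dup))}")
        self.populations = dict(populations)
        missing = [i for i in self.individuals if i not in self.populations]
        if missing:
            raise ValidationError(f"individuals without population label: {missing}")
        self.loci = list(loci)
        if len(set(self.loci)) != len(self.loci):
            raise ValidationError("duplicate locus names")
        self.calls: dict[tuple[str, str], Genotype] = {}
        for ind in self.individuals:
            for loc in self.loci:
                self.calls[(ind, loc)] = _normalize_call(calls.get((ind, loc), BLANK))

    # ------------------------------------------------------------------
    @property
    def pop_order(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(self.populations[ind], None)
        return list(seen)

    def individuals_in(self, pop: str) -> list[str]:
        return [i for i in self.individuals if self.populations[i] == pop]

    def sample_size(self, pop: str) -> int:
        return len(self.individuals_in(pop))

    def genotype(self, individual: str, locus: str) -> Genotype:
        return self.calls[(individual, locus)]

    def genotypes_at(self, pop: str, locus: str) -> list[Genotype]:
        return [self.calls[(i, locus)] for i in self.individuals_in(pop)]

    def typed_genotypes_at(self, pop: str, locus: str) -> list[tuple[int, int]]:
        return [g for g in self.genotypes_at(pop, locus) if g is not BLANK]

    def subset(self, pops: Iterable[str]) -> "GenotypeDataset":
        keep = set(pops)
        inds = [i for i in self.individuals if self.populations[i] in keep]
        return GenotypeDataset(
            inds,
            {i: self.populations[i] for i in inds},
            self.loci,
            {(i, l): self.calls[(i, l)] for i in inds for l in self.loci},
        )

    def with_calls(self, new_calls: Mapping[tuple[str, str], Genotype]) -> "GenotypeDataset":
        """Copy of the dataset with some genotypes replaced."""
        calls = dict(self.calls)
        calls.update(new_calls)
        return GenotypeDataset(self.individuals, self.populations, self.loci, calls)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.populations == other.populations
            and self.loci == other.loci
            and self.calls == other.calls
        )

    def __repr__(self) -> str:
        return (
            f"<GenotypeDataset {len(self.individuals)} individuals, "
            f"{len(self.loci)} loci, {len(self.pop_order)} populations>"
        )

    def summary_frame(self) -> pd.DataFrame:
        """Per (population, locus) sample size and typed counts, as a table."""
        rows = []
        for pop in self.pop_order:
            n = self.sample_size(pop)
            for loc in self.loci:
                typed = len(self.typed_genotypes_at(pop, loc))
                rows.append(
                    {"population": pop, "locus": loc, "n": n, "n_typed": typed,
                     "n_blank": n - typed}
                )
        return pd.DataFrame(rows)


@dataclass
class AlleleFrequencyTable:
    """Per (population, locus) visible-allele frequencies.

    ``freqs[(pop, locus)]`` maps allele label → frequency.  Together with
    the optional null-allele frequency the entries sum to 1.  Cells where
    every genotype is blank are *absent* (no key).
    """

    freqs: dict[tuple[str, str], dict[int, float]] = field(default_factory=dict)
    null_freq: dict[tuple[str, str], float] = field(default_factory=dict)
    n_typed: dict[tuple[str, str], int] = field(default_factory=dict)

    def has(self, pop: str, locus: str) -> bool:
        return (pop, locus) in self.freqs

    def alleles(self, pop: str, locus: str) -> list[int]:
        return sorted(self.freqs[(pop, locus)])

    def get_null(self, pop: str, locus: str) -> float:
        return self.null_freq.get((pop, locus), 0.0)

    def validate(self, tol: float = 1e-9) -> None:
        for key, table in self.freqs.items():
            total = sum(table.values()) + self.null_freq.get(key, 0.0)
            if abs(total - 1.0) > tol:
                raise ValidationError(f"frequencies at {key} sum to {total!r}, not 1")
            if any(v < -tol for v in table.values()):
                raise ValidationError(f"negative frequency at {key}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (pop, locus), table in self.freqs.items():
            for allele, f in sorted(table.items()):
                rows.append({"population": pop, "locus": locus,
                             "allele": allele, "frequency": f})
            nf = self.null_freq.get((pop, locus), 0.0)
            if nf:
                rows.append({"population": pop, "locus": locus,
                             "allele": "null", "frequency": nf})
        return pd.DataFrame(rows)


def allele_frequencies(ds: GenotypeDataset) -> AlleleFrequencyTable:
    """Count visible-allele frequencies per (population, locus).

    Blank genotypes are ignored; a cell with no typed genotype is flagged
    absent (no entry).  Null frequencies are initialised to 0.
    """
    out = AlleleFrequencyTable()
    for pop in ds.pop_order:
        for locus in ds.loci:
            typed = ds.typed_genotypes_at(pop, locus)
            if not typed:
                continue
            counts: dict[int, int] = {}
            for a, b in typed:
                counts[a] = counts.get(a, 0) + 1
                counts[b] = counts.get(b, 0) + 1
            total = 2 * len(typed)
            out.freqs[(pop, locus)] = {a: c / total for a, c in sorted(counts.items())}
            out.null_freq[(pop, locus)] = 0.0
            out.n_typed[(pop, locus)] = len(typed)
    return out


def pair_count(n: int) -> int:
    """Number of unordered pairs among ``n`` individuals: n(n−1)/2."""
    if n < 1:
        raise ValueError(f"need n >= 1, got {n}")
    return n * (n - 1) // 2
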