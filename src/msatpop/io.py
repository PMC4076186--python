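"""Readers and writers: GenePop and a long-form CSV dialect.

GenePop files are the lingua franca of microsatellite studies: a title
line, one locus name per line (or comma-separated), then one ``POP``
block per population sample with lines ``id ,  g1 g2 ...`` where each
genotype is ``2*allele_digits`` characters and the all-zero code means
a blank (missing) genotype.

The CSV dialect is long form with columns
``individual,population,locus,allele1,allele2``; empty allele fields
mean blank.
"""

from __future__ import annotations

import io as _io
import os
from typing import Union

import pandas as pd

from .data import BLANK, GenotypeDataset, ValidationError

__all__ = ["read_genepop", "write_genepop", "read_csv", "write_csv", "ParseError"]


class ParseError(ValueError):
    """Malformed input file."""


def _as_text(path_or_text: Union[str, os.PathLike]) -> str:
    s = str(path_or_text)
    if "\n" in s or not os.path.exists(s):
        if "\n" not in s and not os.path.exists(s):
            raise ParseError(f"no such file and not inline text: {s!r}")
        return s
    with open(s, "r", encoding="utf-8") as fh:
        return fh.read()


def read_genepop(path_or_text: Union[str, os.PathLike], allele_digits: int = 3) -> GenotypeDataset:
    """Parse a GenePop file (2- or 3-digit diploid coding).

    Populations are labelled ``POP1``, ``POP2``, ... in file order; the
    all-zero code decodes to a blank.  Half-missing codes (exactly one
    allele zero) are rejected: the pipeline this format serves has no
    half-called genotypes.
    """
    if allele_digits not in (2, 3):
        raise ValueError("allele_digits must be 2 or 3")
    text = _as_text(path_or_text)
    lines = [ln.rstrip("\r\n") for ln in text.splitlines()]
    lines = [ln for ln in lines if ln.strip() != ""]
    if len(lines) < 2:
        raise ParseError("GenePop file too short (need title, loci, POP blocks)")

    # Title, then locus names until the first POP marker.
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        for name in lines[i].split(","):
            name = name.strip()
            if name:
                loci.append(name)
        i += 1
    if i == len(lines):
        raise ParseError("GenePop file has zero POP blocks")
    if not loci:
        raise ParseError("GenePop file lists no loci")

    width = 2 * allele_digits
    individuals: list[str] = []
    populations: dict[str, str] = {}
    calls: dict[tuple[str, str], tuple[int, int] | None] = {}
    pop_idx = 0
    while i < len(lines):
        if lines[i].strip().upper() == "POP":
            pop_idx += 1
            i += 1
            continue
        line = lines[i]
        if "," not in line:
            raise ParseError(f"line {i + 1}: expected 'id , genotypes', got {line!r}")
        ind, geno_part = line.split(",", 1)
        ind = ind.strip()
        codes = geno_part.split()
        if len(codes) != len(loci):
            raise ParseError(
                f"line {i + 1}: {len(codes)} genotypes for {len(loci)} loci"
            )
        if ind in populations:
            raise ValidationError(f"duplicate individual id {ind!r} (line {i + 1})")
        individuals.append(ind)
        populations[ind] = f"POP{pop_idx}"
        for locus, code in zip(loci, codes):
            if len(code) != width or not code.isdigit():
                raise ParseError(
                    f"line {i + 1}: genotype code {code!r} is not {width} digits"
                )
            a = int(code[:allele_digits])
            b = int(code[allele_digits:])
            if a == 0 and b == 0:
                calls[(ind, locus)] = BLANK
            elif a == 0 or b == 0:
                raise ParseError(
                    f"line {i + 1}: half-missing genotype {code!r} at locus {locus}"
                )
            else:
                calls[(ind, locus)] = (a, b)
        i += 1
    if not individuals:
        raise ParseError("GenePop file has POP blocks but no individuals")
    return GenotypeDataset(individuals, populations, loci, calls)


def write_genepop(ds: GenotypeDataset, allele_digits: int = 3, title: str = "msatpop export") -> str:
    """Serialise a dataset to GenePop text; inverse of :func:`read_genepop`."""
    if allele_digits not in (2, 3):
        raise ValueError("allele_digits must be 2 or 3")
    limit = 10 ** allele_digits
    buf = _io.StringIO()
    buf.write(title + "\n")
    for locus in ds.loci:
        buf.write(locus + "\n")
    for pop in ds.pop_order:
        buf.write("POP\n")
        for ind in ds.individuals_in(pop):
            codes = []
            for locus in ds.loci:
                g = ds.calls[(ind, locus)]
                if g is BLANK:
                    a = b = 0
                else:
                    a, b = g
                    if a >= limit or b >= limit:
                        raise ValueError(
                            f"allele label {max(a, b)} at locus {locus} does not fit "
                            f"in {allele_digits} digits"
                        )
                codes.append(f"{a:0{allele_digits}d}{b:0{allele_digits}d}")
            buf.write(f"{ind} ,  " + " ".join(codes) + "\n")
    return buf.getvalue()


def read_csv(path_or_text: Union[str, os.PathLike]) -> GenotypeDataset:
    """Read the long-form CSV dialect (individual,population,locus,allele1,allele2)."""
    text = _as_text(path_or_text)
    df = pd.read_csv(_io.StringIO(text), dtype={"individual": str, "population": str, "locus": str})
    required = {"individual", "population", "locus", "allele1", "allele2"}
    if not required.issubset(df.columns):
        raise ParseError(f"CSV must have columns {sorted(required)}")
    individuals: list[str] = []
    populations: dict[str, str] = {}
    loci: list[str] = []
    calls: dict[tuple[str, str], tuple[int, int] | None] = {}
    for row in df.itertuples(index=False):
        ind, pop, locus = row.individual, row.population, row.locus
        if ind not in populations:
            individuals.append(ind)
            populations[ind] = pop
        elif populations[ind] != pop:
            raise ValidationError(f"individual {ind!r} listed in two populations")
        if locus not in loci:
            loci.append(locus)
        a_missing = pd.isna(row.allele1)
        b_missing = pd.isna(row.allele2)
        if a_missing != b_missing:
            raise ParseError(f"half-missing genotype for {ind!r} at {locus!r}")
        calls[(ind, locus)] = BLANK if a_missing else (int(row.allele1), int(row.allele2))
    return GenotypeDataset(individuals, populations, loci, calls)


def write_csv(ds: GenotypeDataset) -> str:
    """Serialise to the long-form CSV dialect; inverse of :func:`read_csv`."""
    rows = []
    for ind in ds.individuals:
        for locus in ds.loci:
            g = ds.calls[(ind, locus)]
            rows.append(
                {
                    "individual": ind,
                    "population": ds.populations[ind],
                    "locus": locus,
                    "allele1": "" if g is BLANK else g[0],
                    "allele2": "" if g is BLANK else g[1],
                }
            )
    return pd.DataFrame(rows).to_csv(index=False)
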