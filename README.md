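# msatpop

Population-genetics analysis of co-dominant microsatellite panels for studies
of **kin aggregation and chaotic genetic patchiness** in high-dispersal marine
species — the setting where a blooming broadcast spawner (e.g. a jellyfish
swarm) turns out to contain half-sib and full-sib dyads, homozygote excess and
small, temporally unstable among-sample differentiation. The package is aimed
at population geneticists who want this entire workflow as one scriptable,
seeded, tested library rather than a chain of GUI tools (GENETIX / Arlequin /
Microchecker / ML-Relate / FreeNA-style steps).

It provides:

- **Genotype data model and I/O** — GenePop (2/3-digit) and long-form CSV,
  blanks for amplification failures, strict validation.
- **Diversity and HWE** — N_A, Ho, unbiased He; exact Hardy–Weinberg tests by
  full enumeration (rational arithmetic) and by a seeded Markov chain over
  genotype tables; genotypic LD permutation tests; Bonferroni control.
- **Null alleles** — Chakraborty and Brookfield moment estimators, an EM
  estimator treating the null as an extra allele, and a deterministic
  corrected dataset (excess homozygotes re-labelled visible×null).
- **ML dyadic relatedness** — IBD coefficients k = (k0, k1, k2), relatedness
  r = k2 + k1/2, likelihood-ranked classification into UR/HS/FS(/PO), with
  optional null-allele accommodation:
  `P(g1,g2|k) = k0·P(g1)P(g2) + k1·P(g1)T1(g2|g1) + k2·P(g1)T2(g2|g1)`.
- **Kin tests** — mean intra/inter-sample r, label-permutation significance,
  paired two-tailed t-tests for with/without-null comparisons.
- **Sibship networks** — extended networks (connected components over HS∪FS
  edges) with nested FS families, reported in `k(m)` notation.
- **Population structure** — Weir–Cockerham θ (ratio of sums of the a/b/c
  variance components), permutation p-values, locus-bootstrap CIs, and the
  ENA null-allele correction of θ.
- **Synthetic data** — a Balding–Nichols generator with planted FS/HS
  families, inbreeding, drifting null alleles and a full truth bundle
  (pedigree, true dyad categories, true null frequencies, realized F_ST),
  so every estimator is testable without any deposited data.

## Worked example

Simulate a survey-shaped dataset (8 samples, 259 individuals, 9 loci, planted
families, inbreeding, null alleles), classify every within-sample dyad with
and without null-allele accommodation, compare the two, and estimate global
differentiation:

```python
import msatpop as m
from msatpop.data import allele_frequencies
from msatpop import relatedness, kintests, structure, nulls

ds, truth = m.generate_study_like_dataset(seed=1)
freqs = allele_frequencies(ds)
est = nulls.estimate_nulls(ds, seed=1)

table = relatedness.dyad_frequency_table(ds, freqs, est.em_table())
print(table.round(5).to_string(index=False))
t, df, p = kintests.paired_t_test(table["HS_NNA"], table["HS_NA"])
print(f"paired t = {t:.3f}, df = {df}, p = {p:.4f}")

theta = structure.wc_theta(ds)
lo, hi = structure.fst_bootstrap_ci(ds, iterations=50000, seed=2)
print(f"global theta = {theta:.5f} (95% CI {lo:.5f}-{hi:.5f})")
```

Output:

```
population  n  HS_NNA  FS_NNA   HS_NA   FS_NA
     NAD06 52 0.12217 0.01131 0.15762 0.01282
     UST10 43 0.12403 0.00775 0.12735 0.00997
     UST11 36 0.11746 0.00794 0.14286 0.00952
     UST12 24 0.10145 0.00362 0.14130 0.00362
     ISC10 13 0.07692 0.00000 0.07692 0.00000
     LIP11 53 0.13498 0.02104 0.15820 0.01887
     MES11 14 0.05495 0.00000 0.05495 0.01099
     MES12 24 0.13406 0.00725 0.15217 0.01087
paired t = -3.272, df = 7, p = 0.0136
global theta = 0.02277 (95% CI 0.01765-0.02762)
```

`HS_NNA`/`FS_NNA` are the frequencies of dyads classified half-sib/full-sib
(per n(n−1)/2 pairs) ignoring null alleles; the `_NA` columns accommodate the
EM-estimated null frequencies in the likelihood. The paired t-test asks
whether accounting for nulls changes the HS frequencies (here p = 0.014:
accounting for nulls raises the HS calls in this draw). The global θ of
0.023 sits on the simulation's
differentiation target of 0.02, with a 95% CI from 50,000 locus bootstraps.
Note the absolute HS frequencies are inflated relative to the planted truth
(≈0.02 in the largest sample): with only 9 loci, likelihood-rank
classification has a substantial unrelated→HS false-positive floor — see
`docs/methods.md` for why, and for what the confidence threshold in the
sibship-network stage does about it.

A command-line layer wraps the same functions
(`msatpop simulate | summarize | hwe | nulls | relate | kintest | sibship |
fst | run-all`); `msatpop run-all --seed 1 --out results/` writes the full
report bundle (diversity/HWE table, F_IS with CIs, dyad frequencies, kin
permutation p-values, sibship networks, pairwise θ matrix, JSON summary).

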