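# Methods

`msatpop` re-implements, as a tested library, the complete population-genetics
workflow used in small-scale kin-aggregation studies of marine broadcast
spawners scored at co-dominant microsatellite panels: within-sample diversity
and Hardy–Weinberg testing, null-allele estimation and correction,
maximum-likelihood dyadic relatedness with permutation tests of kin
aggregation, sibship-network reconstruction, and Weir–Cockerham F-statistics
with a null-allele ("ENA") correction. Because the motivating class of studies
rarely deposits raw genotypes, every stage is validated against a synthetic
data generator with fully known truth.

## Data model

A dataset is a matrix of diploid genotypes (unordered pairs of positive
integer allele labels, conventionally fragment sizes in base pairs) over
individuals × loci, with each individual assigned to exactly one population
sample. A completely failed amplification is a *blank* (`None`); half-called
genotypes are rejected at construction, since the genotyping pipelines this
format serves score either both alleles or neither. GenePop (2- or 3-digit
coding, all-zero code = blank) and a long-form CSV
(`individual,population,locus,allele1,allele2`) are supported for I/O; the
GenePop round-trip is the identity and is property-tested. Individual and
population order are preserved from input so that every seeded permutation
procedure is exactly reproducible.

## Diversity and Hardy–Weinberg testing

Per population × locus we report the allele count N_A, observed
heterozygosity Ho, and the *unbiased* expected heterozygosity
He = (2n/(2n−1))(1 − Σp²) (the GENETIX convention; the plug-in variant is a
one-line change but is not exposed, and the choice is recorded here because
printed tables rarely state it).

The HWE exact test conditions on the observed allele counts. Two
implementations exist:

- **Full enumeration** of genotype tables with the observed margins, with
  table probability n!·2^h·Πm_a!/((2n)!·Πn_gg!) computed in exact rational
  arithmetic. Feasible for small tables; serves as the oracle.
- **Markov chain** for realistic samples. The state is the list of n
  genotypes viewed as a labelled pairing of the 2n gametes; one step picks two
  genotypes and swaps one allele between them. Every labelled pairing is
  equally probable under the null and the proposal is symmetric, so the chain
  needs no Metropolis correction and its marginal distribution over genotype
  tables is exactly the conditional null. The p-value is the fraction of
  post-dememorization states whose table probability does not exceed the
  observed one (Fisher criterion, ties included, with a 1e-9 log-domain tie
  tolerance). Defaults follow common practice for this workflow: 1,000 chain
  steps after 10,000 dememorization steps; the test-suite uses longer chains
  and replicate-chain standard errors when comparing against enumeration,
  because single-chain draws are autocorrelated.

"Global" per-locus HWE across samples is Fisher's combination of the
per-sample exact p-values — a pragmatic choice, recorded as such, since the
combined statistic is not itself an exact test.

Genotypic linkage disequilibrium between two loci within a sample is tested by
permutation: the statistic is the log-probability of the two-locus genotype
contingency table under fixed margins, and the null is realised by permuting
one locus's genotypes among individuals. p-values use the add-one correction
(never exactly 0). Bonferroni control is `alpha/k`.

F_IS uses the Weir–Cockerham (1984) variance components b (among individuals
within samples) and c (within individuals): f = 1 − Σc/Σ(b+c), summed over
alleles and loci (ratio of sums — never the mean of per-locus values, which is
a different and worse estimator). Significance comes from re-pairing alleles at
random among individuals within each sample (one-tailed, upper: homozygote
excess); the CI on the overall value is a percentile bootstrap over loci.
A locus with no within-sample variation is reported "not evaluated".

## Null alleles

A null allele amplifies nothing: visible/null heterozygotes are scored as
visible homozygotes and null/null genotypes as blanks, which inflates observed
homozygosity. Three estimators of the per-cell null frequency r are computed
side by side (published Microchecker-style tables do not say which of its
estimators they print, so all are emitted):

- Chakraborty: r̂ = (He−Ho)/(He+Ho)
- Brookfield 1: r̂ = (He−Ho)/(1+He)
- **EM** (Dempster et al.), the estimator used downstream: the null is an
  extra allele under Hardy–Weinberg; the E-step splits each observed
  homozygote (i,i) between true (i,i) and (i,null) in ratio p_i : 2p_null and
  sends blanks to (null,null); the M-step re-normalises gamete counts. The
  log-likelihood trace is asserted non-decreasing. Blanks are included as
  null/null observations by default (a flag excludes them via the standard
  truncated-data augmentation, for data where blanks may be technical
  failures rather than null homozygotes). Because EM approaches the r = 0
  boundary sublinearly, the estimate snaps to the boundary when the null-free
  solution is at least as likely.

A cell is *flagged* as null-affected when it shows a significant one-sided
homozygote excess (exact HWE p < 0.05 with Ho < He) — the "strong deviation
from HWE" detection rule. The corrected dataset re-labels, per allele class,
the EM-expected number of excess homozygotes as (i, NULL) heterozygotes, where
NULL is a reserved out-of-range allele label (999). The relabelling is
deterministic: expected counts are floored, the remainder is allocated
largest-fractional-residual first with ties broken by allele order, and
individuals are taken in dataset order. The proprietary internals of the
original correction software are not published; this EM-expectation variant
reproduces its intent ("adjust the number of homozygote genotypes")
reproducibly. The expected blank count under the model is n·r².

## Dyadic relatedness

For a non-inbred pair, the IBD coefficients k = (k0,k1,k2) give the
probability of sharing 0/1/2 alleles identical by descent; relatedness is
r = k2 + k1/2. The per-locus likelihood is linear in k:

    P(g1,g2|k) = k0·P(g1)P(g2) + k1·P(g1)T1(g2|g1) + k2·P(g1)T2(g2|g1)

where T2 is the indicator of genotype identity and T1 draws the shared gene
uniformly from g1 and the other gene from the population. Both transitions are
verified *exactly* (rational arithmetic) against brute-force enumeration of
parental genotypes and gamete transmissions, and the likelihood is checked to
sum to 1 over all genotype pairs for any k.

Dyads are classified to the category with the highest likelihood among
{UR, HS, FS} (PO available, off by default: single-cohort adult samples).
Ties go to the least related category — conservative against inflating kin
counts. Null alleles are accommodated by summing the likelihood over the true
genotypes compatible with each observation (homozygote ↦ {hom, visible×null},
blank ↦ null×null) with EM-estimated frequencies. Classification uses the
allele frequencies of the population sample containing the dyad; the
whole-dataset relatedness matrix used by the kin tests uses pooled
frequencies, matching a single all-samples likelihood run.

k̂ (hence r̂) is maximised over the whole simplex by a vectorised
coarse-to-fine grid (0.1 halved to <1e-3), with an SLSQP polish in the
single-dyad path. The simplex is not restricted further; a dyad's r is only
reported when ≥5 polymorphic loci are typed in both members (configurable),
because the per-locus likelihood is linear in k and a handful of loci cannot
pin an interior maximum.

Known limitation: with few loci, HS-vs-UR discrimination is weak — a
likelihood share of 0.95 for an HS call essentially requires ≳20 informative
loci — and frequencies estimated from a small sample dominated by one family
are themselves distorted, further reducing power. The sibship tests therefore
use reference frequencies from unrelated individuals where the point is to
test network construction rather than frequency estimation.

## Kin-aggregation tests

Mean pairwise r is computed for every ordered cell of population pairs (intra
on the diagonal). The permutation test permutes individuals' population labels
globally (sample sizes preserved) and re-indexes the precomputed r matrix —
genotypes never move, so the dyad-r multiset is invariant by construction.
One-tailed upper p-values with add-one correction, per cell. Re-indexing
(rather than recomputing r from permuted per-sample frequency pools) is a
deliberate choice: it makes the null exactly exchangeable and the test exact,
which the calibration suite confirms; recomputation per permutation is
available by passing a frequency table explicitly. With/without-correction
comparisons are classic paired two-tailed t-tests pairing by sample in table
order — validated by reproducing published p-values that a two-sample test
does not reproduce.

## Sibship networks

Within-sample dyads classified HS or FS with classification confidence (the
winning category's likelihood share) ≥ 0.95 become edges; extended sibship
networks are the connected components with ≥2 members, singletons are
"unrelated", and FS families are the components of the FS-only subgraph,
each nested in one network. The reporting format lists each network's size
with its FS families in k(m) notation (k families of m members). Joint
pedigree-likelihood partitioning (as in full sibship-reconstruction software)
is out of scope; pairwise-classification networks track it closely except for
HS counts, and the confidence threshold is a likelihood-share proxy for a
posterior probability.

## Population structure

θ (F_ST) uses the full Weir–Cockerham components a/b/c per allele per locus,
ratio of sums across alleles and loci. Pairwise significance permutes whole
individuals between the two samples; the global CI bootstraps loci
(percentile, 50,000 draws by default — cheap, since per-locus components are
reused). Negative estimates are reported as computed, with a display option
flooring at 0. Blanks are excluded per locus (pairwise deletion).

**ENA correction.** The null-allele F_ST correction estimates, per cell, the
EM visible-allele frequencies *on the absolute scale* (summing to 1−r̂) and
the EM-expected per-allele heterozygote frequencies (observed heterozygotes
plus the expected visible×null heterozygotes hiding among observed
homozygotes; blanks enter the sample size as null/null individuals), then
computes θ with the null class excluded from the per-allele sums. When every
r̂ is 0 this reduces *exactly* to the raw estimator. The reason absolute
(not renormalised) frequencies matter: when the null allele drifts like any
other allele, the *conditional* visible composition is more differentiated
than the underlying loci — F_vis = F/((1−r)(1−F)+F) — which is precisely the
mechanism that inflates raw θ under nulls; excluding the null class from an
absolute-scale analysis removes it.

## Synthetic data generator

The generator emulates the statistical structure of an eight-sample,
nine-locus survey of a blooming jellyfish (259 individuals in samples of
52/43/36/24/13/53/14/24): allele counts spanning 5–18 per locus, planted
full-sib and half-sib families producing within-sample dyad frequencies of
roughly 0.001–0.05, per-locus inbreeding, hidden null alleles at 0.05–0.15,
and small among-sample differentiation (target 0.02).

- **Base frequencies**: symmetric Dirichlet per locus (concentration 0.8 by
  default — skewed spectra giving the observed He range).
- **Differentiation**: Balding–Nichols. Per population the joint composition
  over (visible alleles, null class) is Dirichlet with parameters
  p·(1−F)/F, so every class has mean p and variance F·p(1−p) — an analytic
  F_ST oracle, and the null allele drifts like any other allele (see ENA
  above). The realized differentiation of each draw is recorded in the
  truth bundle.
- **Pedigree**: an FS family is one sampled parent pair with independent
  Mendelian offspring; an HS family shares the "mother" (a label only) with a
  fresh mate per offspring; everyone else gets unique parents. With
  probability F (inbreeding), independently per offspring and locus, the
  second gamete is an IBD copy of the first, giving E[Ho] = (1−F)He — checked
  by simulation.
- **Observation**: each gamete independently becomes a null with the cell's
  null frequency (visible/null ⇒ visible homozygote, null/null ⇒ blank, blank
  fraction r²); optional uniform allele-replacement genotyping error
  (default 0, matching the common 0.005-scale default only when enabled).
- **Truth bundle**: pedigree, per-pair UR/HS/FS truth derived from shared
  parents, per-population null frequencies, target and realized
  differentiation, seed and config echo; serialises to JSON.

One root seed drives everything through `numpy` `SeedSequence` spawning, so
each stage is independently reproducible.

What the generator does **not** emulate: mutation (no stepwise-mutation
allele-size structure), overlapping generations, selection, spatial or
oceanographic structure, within-family null inheritance (masking is applied
per gamete, not tracked through the pedigree), and scoring artefacts such as
stutter or large-allele dropout. Tests passing on this generator therefore
demonstrate correctness of the estimators under the stated model, not
robustness to those real-data complications.

## Problem sizes and numerical choices

The acceptance experiments run at sizes chosen to separate signal from
Monte-Carlo noise while staying desk-scale: parameter recovery at n = 500–2000
individuals and 20–50 loci; type-I calibration over 200 null replicates of
small three-sample datasets with 199-permutation tests (the add-one permutation
p is exactly attainable at the 5% level with B = 199); the ENA experiment at
2×600 individuals and 50 loci (25 null-affected), where the raw-θ inflation
(≈+0.002 at F = 0.02, r = 0.2) exceeds the replicate noise (σ ≈ 0.0007).
Permutation and bootstrap p-values always use the add-one correction;
exact-test ties are included in the tail; EM tolerance is 1e-10 on parameter
change with a 2000-iteration cap; the k-grid refines to <1e-3.
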