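# Methods

## The question and the estimand

Given two populations A and B that recently split from a shared ancestor,
and an outgroup O that split from their common lineage much earlier, the
package asks whether one population accumulates germline mutations faster
than the other. The primary statistic is the **derived-allele proportion**:
for a pair of individuals (a ∈ A, b ∈ B) genotyped at polarized biallelic
loci, each locus where the pair's four alleles include both states
(0 < gₐ + g_b < 4, dosages counted on the derived allele) credits
max(gₐ − g_b, 0) excess derived alleles to a and max(g_b − gₐ, 0) to b.
Summing over loci gives (dₐ, d_b) and the proportions dₐ/(dₐ+d_b),
d_b/(dₐ+d_b). If the founder populations are equally related to the
outgroup and evolution is neutral, E[proportion] = 0.5 for both sides; a
population with an elevated mutation rate carries more recently derived
alleles and its mean proportion over all cross pairs rises above 0.5.

Two deliberate reading choices, made because the quantity is otherwise
underdetermined, are documented here as the package's definitions:

- the proportion's denominator is the **pair total** dₐ + d_b, so the two
  proportions of a pair sum to exactly 1 (population-level means then also
  sum to 1 when no pair is excluded);
- the replicate's reported "sd" is the sample standard deviation (ddof = 1)
  of the per-pair proportions; because each pair's proportions are
  complements, it is the same number for both populations and is printed
  once.

Pairs whose excess total is zero have no defined proportion; they are
excluded from the means with a logged warning rather than scored 0.5,
which would manufacture an observation where there is none.

## Polarization

A locus is polarized only if **every** outgroup individual is homozygous
for the **same** allele: a single outgroup heterozygote excludes the
locus, even if all homozygous outgroup calls agree. This is the strictest
rule and deliberately so — its purpose is to minimize the chance that
variation predating the A/B–outgroup split survives into the comparison.
Where the shared outgroup allele is the file's ALT, ancestral and derived
roles are swapped and study dosages are recoded d → 2 − d. Polarization
requires complete genotypes; the workflow therefore removes loci with any
missing call (across the outgroup and the selected study samples)
**before** polarizing. The order matters only for bookkeeping — retained
loci are identical either way — but fixing it keeps attrition logs
comparable across runs.

## Weir–Cockerham θ

`popstruct` implements the Weir & Cockerham (1984) estimator from
per-locus, per-population sample sizes nᵢ, alternate-allele frequencies
pᵢ, and observed heterozygote frequencies hᵢ, via the intermediate
quantities n̄, n_c, p̄, s², h̄ and the three variance components a (among
populations), b (among individuals within populations), c (within
individuals). Multi-locus combining is the **ratio of sums**
θ = Σa / Σ(a+b+c) — the combination Weir & Cockerham recommend and what
hierfstat reports — not the mean of per-locus ratios. Monomorphic loci
contribute zero components; loci where any population has fewer than two
called individuals are skipped. Negative θ estimates are reported as
computed: clipping at zero would bias the bootstrap's null behavior.
Confidence intervals are **percentile** bootstrap over loci (the variant
is a choice; BCa was not used) at a default 99% level over 1,000
replicates, with the locus as the resampling unit. `pairwise_fst_matrix`
spawns an independent seed stream per population pair so results do not
depend on evaluation order.

## STR diversity

The locus-quality filter drops a locus when its call log-likelihood fails
for **strictly more than half** of the individuals (a locus failing for
exactly half is retained). "Fails" defaults to ≤ −25, reading the
threshold as the genotyper's floor value; an exact-equality comparator is
available because the alternative reading is defensible. Per (population,
locus) the package computes Na, Ne = 1/Σp², Shannon's I = −Σp ln p, Ho
(heterozygous individuals / typed individuals), He = 1 − Σp²
(**uncorrected**, the GenAlEx-style default; the 2n/(2n−1)-corrected
variant is behind `bias_corrected_he`), F_IS = (He − Ho)/He (NaN at
monomorphic loci, flagged rather than zeroed), private alleles counted
against the union of all other populations' supports, and Botstein's
PIC = 1 − Σpᵢ² − Σᵢ<ⱼ 2pᵢ²pⱼ². Missing genotype calls reduce n_typed
instead of dropping the locus. Between-population comparison is a paired
two-sided t-test per metric across shared loci at α = 0.05; means are
reported with SE = sd/√L. The allele-frequency F_ST is Nei-style
(Ht − Hs)/Ht with unweighted population means, aggregated by summing Ht
and Hs over loci before the ratio.

## The synthetic-data generator

`simdata` emulates the study's statistical structure, not its sequencing:

- **Ancestral frequencies** of the derived allele are Beta(0.5, 2)
  (defaults), skewed toward rare derived alleles as a neutral frequency
  spectrum is.
- **Drift** perturbs each population's frequency with a Beta draw of mean
  q and variance F·q(1−q), F ∈ [0, 1) per population (default 0.02 — two
  recently separated populations). This creates realistic F_ST between A
  and B at a fraction of the cost of generation-by-generation
  Wright–Fisher simulation; θ recovered downstream is ≈ F when both
  populations share the intensity.
- **The outgroup** is fixed homozygous-ancestral at every locus — the
  idealization the polarization step assumes; with the default
  `n_outgroup=3` every simulated locus passes the homozygosity filter, so
  attrition tests use the missingness knob instead.
- **Injection** (the elevated-mutation knob): with probability
  `inject_rate_X` a locus is monomorphic ancestral everywhere except for a
  novel derived allele private to population X at 1–2 copies spread over
  carriers — the frequency range de novo mutations occupy. Injection
  probabilities share one uniform draw per locus, so the injected locus
  sets are nested as the rate grows; together with a fixed seed this makes
  the recovery grid (mean proportion vs rate) cleanly monotone.
- **VCF coding** of REF/ALT is randomized per locus, so roughly half of
  all loci exercise the ancestral-as-ALT recode path.
- **STRs**: allele supports are repeat-count offsets within ±`smm_steps`
  of a base count, weighted 0.6^|Δ| (stepwise-mutation-style decay), with
  the distinct-allele count per locus drawn around `allele_count_target`
  (default 6.7, a diverse multi-panel average) and Dirichlet frequencies
  mildly perturbed per population. `n_bad_loci` loci (default 10 of 54)
  get the failing likelihood (default −25) for a strict majority of the
  94 default individuals; all other likelihoods are drawn in (−8, −0.5),
  far from the threshold, so the filter's outcome is exact by
  construction.

What the generator does **not** emulate: linkage and recombination (loci
are independent), coalescent genealogies, sequencing error, allele
dropout, or real STR mutation-rate heterogeneity. Passing tests therefore
demonstrate that the estimators recover the parameters of *this* model —
symmetry gives 0.5, injection shifts it monotonically, drift gives
F_ST ≈ F — not that real datasets are free of the confounders
(relatedness, population structure, batch effects) the real study handled
with upstream filtering.

## Problem sizes and numerics

Library defaults mirror the reference design: 3 outgroup + 5 + 5
individuals, 25 pairs per replicate. The acceptance script uses ten
30,000-locus replicates for the symmetry check (≥ 10,000 informative loci
per pair at the default frequency spectrum) and the 54-locus/94-individual
fixture for the filter check; the test suite uses 1,000–20,000-locus
simulations, sizes at which every check runs in seconds on one core.
Dosages are int8 with −1 as the missing sentinel; proportions and θ are
float64 throughout. Ties and degenerate cases are fixed as: uninformative
pairs contribute zero to both excess totals; zero-variance loci contribute
zero θ components; He = 0 flags F_IS as NaN; an empty excess total flags
the pair undefined. Bootstrap quantiles use numpy's default linear
interpolation.

## Known limitations

- The polarization idealizes the outgroup as error-free; real outgroup
  genotyping error leaks derived alleles into the "ancestral" definition
  symmetrically for both populations, diluting but not biasing the
  proportion.
- The drift model has no shared post-split history (migration,
  admixture); F_ST from it is a single-parameter summary, not a fitted
  demography.
- The paired t-test across loci treats loci as exchangeable replicates;
  linked loci in real data would understate the p-values' denominator
  degrees of freedom.
- `merge_on_shared_loci` reconciles only identical or swapped REF/ALT
  pairs and never attempts strand flips; ambiguous A/T and C/G sites from
  mixed platforms should be pre-filtered upstream.
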