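# Methods

This note documents the statistical models, the numerical choices, and
the limits of what the bundled simulations can demonstrate.

## Clone discrimination

**MLG identification.** Two ramets share a multilocus genotype when
their diploid genotypes agree; genotypes are stored as unordered allele
pairs, and a call with one unreadable allele is treated as fully missing
(conservative: a half call can neither confirm nor refute identity).
Two matching policies are provided. *Strict* requires identical
genotypes *and* identical missingness patterns. *Permissive* (default)
requires equality only at mutually observed loci and closes links
transitively; with low missingness this avoids inflating the genet count
when a clone member has a single failed locus. The default follows the
low-missingness regime the package targets; use strict when missingness
is informative (e.g. null-allele-prone markers).

**psex.** The probability that an MLG observed `n` times among `N`
ramets arose repeatedly through sex rather than clonality. The genotype
probability under Hardy–Weinberg is `pgen = ∏_loci 2^h p_a p_b` (h = 1
at heterozygous loci). The *single* method conditions on one observed
carrier: `psex = P(X ≥ n−1)`, `X ~ Bin(N−1, pgen)`; the *multiple*
method is the unconditional upper tail `P(X ≥ n)` over all `N` draws.
Allele frequencies come from one representative per MLG by default
("genet" basis — frequencies from all ramets would be distorted by the
very clones being tested); a ramet basis and a round-robin basis (locus
ℓ frequencies from the partition rebuilt without locus ℓ) are offered.
Alleles absent from the chosen basis are floored at `1/(2·basis size)`.

**Bruvo distance.** SSR fragment sizes are converted to repeat units
`u = round((size − offset)/repeat_length)` with the per-locus offset
defaulting to the smallest observed allele (only differences matter, so
the offset cancels); conversions off the ladder by more than 0.15 repeat
units are flagged and rounded. The per-locus distance between diploid
genotypes is the minimum over the two perfect matchings of the mean of
`1 − 2^(−|ux − uy|)`; per-pair distances average over loci observed in
both ramets. Only the diploid exact-matching model is implemented (no
genome addition/loss — appropriate for a diploid species).

**MLL threshold prediction.** Scoring errors split true clones into
near-identical MLGs whose pairwise distances sit far below genuine
between-genet distances. The predictor sorts the between-MLG
representative distances, locates the distribution's dominant mode
(highest-count histogram bin; `max(10, ceil(sqrt(n)))` bins; ties broken
toward larger distances so a concentrated error peak near zero never
outvotes the between-genet bulk), and returns the midpoint of the
largest gap whose lower end lies below that mode. Bruvo distances over
a small locus panel are quantized, so exact ties among largest gaps are
common; ties are broken toward the gap nearest the mode, which in
simulation separates one- and two-error variants from true genets
(membership recovery ≥ 0.975 across seeds at a 1%-per-allele error
rate). A degenerate (single-valued or gap-free) distribution returns 0
with a warning — no collapsing. The exact rule inside the predictor is
this package's own choice; cutoffs estimated on other data sets by other
tools need not coincide.

**MLL collapsing** is single-linkage over MLG representatives at the
given threshold, inclusive (`≤`), with transitive chaining — matching
the behaviour of threshold-based clone assignment in the field's
standard tooling. Threshold 0 leaves MLLs ≡ MLGs.

**Genotypic diversity.** Richness `R = (G−1)/(N−1)`; rarefied expected
MLG count by hypergeometric rarefaction `E[G_g] = Σ_i (1 −
C(N−n_i, g)/C(N, g))`; Stoddart–Taylor `G* = 1/Σp_i²`; Simpson
`λ = 1 − Σp_i²`; evenness `E5 = (G* − 1)/(e^{H'} − 1)`. The Pareto slope
β regresses `log(N_{≥c}/G)` on `log c` over observed clone sizes by OLS
(β = −slope); an MLE fit is deliberately omitted — the OLS slope is the
quantity conventionally reported. The index of association
`r̄d = (V_O − V_E)/(2 Σ_{j<k} √(v_j v_k))` uses per-locus allele-mismatch
distances (0/1/2 under the best pairing); pairs with a missing genotype
receive the locus-mean distance so every locus sees the same pair count.
The permutation null shuffles genotypes within loci across the samples
retained at the chosen clone-correction level, so clonal replication
itself cannot drive significance.

## Genet-level diversity

Observed heterozygosity is the fraction of heterozygous genotyped
individuals; `uHe = 2n/(2n−1)(1 − Σp²)`; `FIS = 1 − Ho/uHe` (Nei),
multilocus via the ratio of averages. Allelic richness uses
hypergeometric rarefaction in gene copies, with the public API taking
the size in diploid individuals (`2g` copies); private allelic richness
(expected number of alleles present in a `g`-copy subsample of the focal
population and absent from equal subsamples of all others) takes its
size in gene copies directly. Both conventions are exposed explicitly
because the two units differ by a factor of two and are easy to confuse.
SNP nucleotide diversity π is the mean per-site `2n/(2n−1)·2p(1−p)` over
variant sites only, and the report flags that restriction.

HWE exact tests use the full conditional (Levene/Haldane) enumeration of
heterozygote counts for biallelic loci and a seeded Monte-Carlo
permutation of alleles into genotypes for multiallelic loci, with
two-sided p by probability ordering plus one-sided excess/deficit
versions; adjustment across loci is Benjamini–Hochberg (default, suited
to SNP panels) or Bonferroni (conventional for small SSR panels).
FST is Weir–Cockerham θ with components summed over alleles and loci
before the ratio and a delete-one-locus jackknife SE.

Two diagnostic correlations are built in: per-clone multilocus
heterozygosity vs ramet count (do outbred genets grow larger?), and
per-locus missingness vs FIS (Spearman; a strong positive correlation
implicates allele dropout in heterozygote deficits).

## LD-Ne

For allele A at locus 1 and B at locus 2, using the `S` individuals
complete at both loci, the Burrows composite disequilibrium is
`Δ̂ = (Σ x_i y_i)/(2S) − 2 p̂_A p̂_B`, rescaled by `S/(S−1)`, and
`r̂² = Δ̂² / ([p_A(1−p_A) + (h_A − p_A²)][p_B(1−p_B) + (h_B − p_B²)])`
with `h` the homozygote frequency. Biallelic loci contribute one allele
(the two pairings are identical); multiallelic loci contribute every
retained allele with equal weight. The overall r̂² is the unweighted
mean over comparisons and `S_harm` the harmonic mean of per-comparison
sample sizes — with pairwise-complete missing-data handling this is the
package's documented weighting choice. Screening masks alleles below
p-crit and singletons (alleles carried by exactly one heterozygote);
the headline setting is "exclude singletons, p-crit 0", with the full
ladder {0.05, 0.02, 0.01, 0} always computable.

The sampling component `1/S + 3.19/S²` (S ≥ 30; `0.0018 + 0.907/S +
4.44/S²` below) is subtracted and Ne obtained from
`N̂e = (1/3 + √(1/9 − 2.76 r̂²′))/(2 r̂²′)` (small-S variant
`(0.308 + √(0.308² − 2.08 r̂²′))/(2 r̂²′)`). A non-positive drift signal
returns +∞; beyond the quadratic's validity range the discriminant is
floored at zero so the mapping stays monotone. The branch switch at
S = 30 is exposed (`branch_at`) since samples near the boundary are
sensitive to it. Monogamy coefficient sets are available behind the
`mating` flag; the default is random mating.

**Confidence intervals.** The jackknife deletes one individual at a time
(default) or one locus at a time, forms the jackknife variance of mean
r̂², converts it to an effective degrees-of-freedom
`n′ = 2 r̄²²/V_J`, and maps the χ² interval on r² through the point
estimator (which is decreasing in r², so bounds swap). The parametric
CI uses the raw comparison count as df — with thousands of loci on few
individuals this is pseudoreplication and the interval is far too
narrow; the locus-subsampling routine (default 40 subsets × 800 loci,
seeded, independent draws without replacement) quantifies this by the
spread of per-subset point estimates. Both jackknife axes are provided
because either convention appears in practice; they answer slightly
different questions (uncertainty from sampled individuals vs sampled
loci).

**Corrections.** Physical linkage among loci biases N̂e downward by an
expected factor `0.098 + 0.219 ln(n_chrom)`; the published arithmetic
applies the divisor at two decimals (0.60 for 10 chromosomes), which is
the default here (`divisor_precision=None` gives full precision).
Generation time for an iteroparous perennial is `T = α + s/(1−s)`
(α = age at first flowering in years, s = annual adult survival), and
`ne_census_ratios` reports N̂e against both ramet and genet census
counts.

## Simulators

**Wright–Fisher mode** is the clean validation baseline: discrete
non-overlapping generations, `Ne` diploids, each offspring drawing two
uniformly random parents (multinomial family sizes) and one allele per
locus per gamete (free recombination), no mutation. SNP loci start at
frequencies uniform on (0.1, 0.9); SSR loci (used to seed the clonal
simulator's standing variation) start on a stepwise ladder of 4–8
alleles at Dirichlet(2) frequencies. Default 15–20 generations — LD
among unlinked loci equilibrates within a handful of generations, and
longer runs only lose polymorphism to fixation.

**Clonal mode** emulates a phalanx-clumped, partially clonal perennial:
founder genets drawn from a Wright–Fisher standing pool (default
ancestral Ne 200); each year every genet adds clonal ramets
(Poisson, mean `growth_rate·c`) inside a circular clump of radius
∝ √ramets, and the population gains sexual recruits (Poisson, mean
`G·growth_rate·(1−c)·flowering_fraction`) with both parents sampled
proportional to ramet count — large clumps flower more, which inflates
the variance in reproductive success and is itself a drift accelerant —
with optional selfing, establishment near the maternal clump, and
stepwise ±1-repeat SSR mutation at meiosis only. Clonal copies never
mutate (somatic mutation out of scope), so clone identity ground truth
is exact before noise. Genets persist across years: generations overlap,
as in real mixed-age sampling. Genotyping noise (independent
missingness per call; ±1-repeat miscalls for SSRs, allele flips for
SNPs) is applied last.

Two bundled scenarios fix the study conditions: *stable* (60 founder
genets, clonality c = 0.995 — the literature's 1:200 sexual:clonal
ratio — growth 0.2/genet/year over 40 years, ending near 550 ramets in
~60 genets) and *founder* (6 founder genets, c = 0.55, growth 0.25 over
60 years, ending near 500–650 ramets across ~150–190 genets). These
reproduce the qualitative contrast of a demographically stable, diverse
population versus a founder-bottlenecked expanding one: the founder
scenario shows a much smaller N̂e and far fewer private alleles despite
more genets.

**What the simulations do not show.** The clonal generator produces
relatively even clone sizes (same-age founders with Poisson growth), so
its evenness statistics run higher than field data where clump ages and
sizes vary over orders of magnitude; it has no dormancy, no mortality,
no pollinator behaviour, and its spatial coordinates are bookkeeping
only (never used in inference). Passing tests therefore validate the
statistical machinery, not the ecological realism of any particular
parameter set.

## Numerical choices and degenerate inputs

- Rarefaction binomial-coefficient ratios are computed in log space
  (`gammaln`) for stability at genomic scales.
- The pairwise r² engine is fully vectorised; with complete data it uses
  per-column frequencies and a single Gram matrix, with missing data it
  switches to pairwise-complete matrix products. Deleting one
  individual recomputes the Gram matrix; deleting one locus is a cheap
  downdate of per-locus comparison sums.
- Monomorphic loci: uHe = 0, FIS undefined (NaN); loci with fewer than
  two retained alleles drop out of LD estimation; a locus monomorphic
  across all populations is excluded from the FST component sums.
- MST ties are broken by node index; MLG labels follow first-seen sample
  order, so partitions are reproducible and order-insensitive up to
  relabelling.
- All stochastic routines take explicit seeds; the CLI derives
  per-stage substreams from a single global seed via `SeedSequence`, so
  adding a stage never changes earlier stages' randomness.
- Reports serialize floats at six significant digits and infinities as
  the token `Inf` (round-tripped by the JSON reader).

## Known limitations

- psex assumes Hardy–Weinberg proportions and independent loci when
  multiplying genotype probabilities; inbreeding inflates pgen and makes
  psex conservative in the direction of over-calling sexual origin.
- The LD method assumes a closed population; migration and admixture
  bias N̂e toward the metapopulation value, and age structure in
  mixed-age samples biases it downward — neither is corrected here.
- Effective-number-of-breeders (single-cohort) estimation and temporal
  (two-sample) methods are out of scope, as are outlier-locus detection
  and Bayesian clustering (supply exclusion lists externally).
- The problem sizes used by the test suite and the acceptance script
  (50 replicates × 200 loci; one 3,000-locus × 30-sample dataset;
  ~250-ramet clonal populations) were chosen as the smallest
  configurations at which the validated properties are stable across
  seeds.
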