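# Methods

## Segregation model

A locus of the allotetraploid is represented by four tagged chromosome
copies, two per ancestral genome (M = mandarin-derived, P =
poncirus-derived). Gamete formation is a three-component mixture over
meiotic modes:

* **Disomic** (probability 1 − τ): the four copies resolve into two fixed
  bivalents according to a *pairing scenario* — one of the three partitions
  of four copies into two pairs — and the gamete receives one copy from
  each bivalent, the four copy combinations equiprobable.
* **Random chromosome association** (probability τ(1 − β)): the gamete
  receives one of the six unordered copy pairs, equiprobably. This is
  random *bivalent* (chromosome-level) segregation, not random chromatid
  segregation; under a duplex AABB genotype it yields the class
  probabilities {τ/6, 1 − τ/3, τ/6}, which is the form the duplex
  closed-form estimator inverts.
* **Double reduction** (probability τβ): a single copy, uniform over the
  four, is transmitted twice. Modelling double reduction as a separate mode
  rather than through chromatid-level segregation keeps the two parameters
  interpretable (τ = proportion of gametes explicable by random
  association; β = double-reduction frequency *relative to* that fraction)
  and avoids introducing a centromere–locus recombination fraction that the
  data cannot resolve.

Copy-level outcomes are collapsed to unordered allele multisets; the null
(non-amplifying) allele "0" is an ordinary symbol at this level, its
observability being handled at the inference layer. Because the class
probabilities are linear in τ and τβ,
`P = d + τ(c − d) + τβ(r − c)` with d/c/r the three mode distributions,
each scenario reduces to three fixed coefficient vectors.

Scenario equivalence: the tetrasomic and double-reduction components are
scenario-independent, so two scenarios produce identical distributions for
all (τ, β) exactly when their disomic distributions coincide at the allele
level. Equivalence classes are computed symbolically with rational
arithmetic; e.g. a duplex AABB, and likewise an AA × BC locus, has two
classes (the homologous scenario versus the two mutually equivalent
heterologous ones), while four distinct alleles give three.

For a fully genus-differentiating locus under the homologous scenario the
probability that a gamete unites one M and one P allele is
`1 − τ/3 − (2/3)τβ`: disomy always transmits one copy per genome, a random
bivalent pair is heterogenomic with probability 2/3, and a doubled copy
never is. The τ = 0.42 duplex case gives 0.86, matching the low end of the
observed 86–97% per-locus intergeneric heterozygosity.

## Estimation and testing

**Likelihood.** Multinomial log-likelihood over gamete classes with the
combinatorial constant omitted; observed classes with zero model
probability give −∞, zero-count classes contribute nothing, and no
expected-count floors are applied.

**Optimization.** Deterministic coarse grid (step 0.01 in τ, and in β when
identifiable) followed by local refinement (bounded scalar search in one
dimension, Nelder–Mead with box bounds in two) to tolerance 1e-6, keeping
whichever of grid and refined solutions scores higher. The likelihood is
concave in (τ, τβ) — log of a linear function — so the grid start makes the
refinement reliable; the scheme is stochastic-optimizer-free and therefore
bit-reproducible. Scenario ties within 1e-9 are broken toward the
homologous scenario and flagged.

**β identifiability.** β is structurally flat whenever every
double-reduction product {a,a} is also producible by random pairing or
disomy (i.e. allele a occurs twice in the genotype), as in the di-allelic
duplex. This is detected symbolically per scenario (a class with r > 0 but
c = d = 0 must exist); when absent, β is fixed at 0 and reported
non-identifiable. Under the τ = 1 null the nested-model discipline applies:
β is re-optimized when identifiable, else held at 0. The biological ceiling
on the overall double-reduction proportion (τβ ≤ 1/6 under systematic
quadrivalent formation) is reported as a warning flag, not imposed as a
constraint, since β here is defined relative to τ.

**Likelihood-ratio test.** τ̂ lies on the boundary of [0, 1] under the full
tetrasomy null (τ = 1), so the LRT statistic is referred to the mixture
½χ²₀ + ½χ²₁: p = ½·Pr(χ²₁ ≥ LRT) for a positive statistic and 1 at zero.
Exact small-sample calibration for the duplex estimator at n = 58 gives a
4.9% type-I rate at the 5% level. Note that selecting the best of several
*distinguishable* scenarios before testing inflates the statistic slightly
(≈9% at n = 58 in simulation); the duplex path has a single free scenario
and is exactly calibrated, which is why the calibration guarantee is stated
for it.

**Distortion screen.** Pooled allele counts (two observations per gamete,
nulls counted when the constitution carries them) are compared with
parental dosage by Pearson chi-square, df = k − 1. Loci with p < 0.05
(configurable) are excluded — after null-allele rescue has been attempted.

**Null-allele constitutions.** Without dosage, AA and A0 both present as a
lone A, so candidate constitutions are compared on visible-allele
signatures: classes are merged by signature, the mixture is fitted on the
merged classes, and candidates are ranked by the deviance G = 2ΣO·ln(O/E)
at the fitted expectation. Candidates are the stated constitution plus
every variant that replaces duplicated copies (or re-duplicates a stated
null) within each genome — abcc vs abc0 for three visible alleles, the
aabb/aab0/abb0/ab00 family for two — filtered to those covering the
observed alleles. The reconstruction of this test is expectation-based; the
exact contingency layout used in the original analysis is not documented.

## Gamete inference

Each triploid progeny call (allele → dosage, summing to 3 when fully
amplifying) is resolved by removing exactly one copy of exactly one
maternal allele. Records with no removable maternal allele (off-types) or
with several distinct resolutions (only possible when a heterozygous
maternal genotype shares alleles with the tetraploid parent — such loci are
rejected at configuration load) are flagged and excluded, never guessed. A
homozygous maternal genotype may share its allele with the father (the
centromeric SNP design AA × AABB), since subtraction stays unique. Gametes
carrying nulls lower the visible dosage; the shortfall is restored as "0"
symbols when the active constitution carries nulls, and a progeny showing
only a maternal allele is classed as the double-null gamete iff a two-null
constitution is active.

## Population summaries

Per locus each gamete is intergenerically heterozygous (one allele per
genome), intragenerically heterozygous (two distinct same-genome alleles,
the null included), or homozygous. The overall intergeneric transmission
rate pools gamete-locus observations (1309/1450 = 90.3% on the packaged
dataset). The count-based intrageneric average over the 25 retained loci is
1.9%, lower than the 4.1% quoted in the source text, whose denominator
convention could not be reconstructed from the printed per-locus counts;
the count-based value is reported.

Intergeneric recombinants are scored per gamete and linkage group: at fully
genus-differentiating loci the gamete's M-allele dosage (0/1/2) must be
constant if it consists of two genus-constant haplotypes, so any dosage
change marks the gamete recombinant once — robust to marker count and
matching the per-group frequency semantics of the observed data. Linkage
groups aggregate τ̂ by mean and sample standard deviation (n − 1;
single-marker groups report 0); the published "±" dispersions are not
internally consistent with either sd convention, so only means are matched.
Simple-matching dissimilarity between gametes i, j is
`1 − (1/L_ij) Σ_l m_l/2` over pairwise-complete loci, with m_l the multiset
intersection of the two allele pairs; genus-recoded mode first maps alleles
to genome labels, isolating the intergeneric component.

## Simulator

The generator mirrors the study conditions by default: 58 gametes, the 25
retained loci on nine linkage groups with their published parental
constitutions, per-group τ set to the published means (0.09–0.47) and β to
the detected per-group rates (0–0.07), a fully differentiated maternal
parent at the SSRs and a homozygous shared-allele mother at the SNPs. One
meiotic mode is drawn per gamete and linkage group with probabilities
(1 − τ, τ(1 − β), τβ). Disomic meioses transmit one intact haplotype per
genome (the generative model's preferential pairing is homologous, matching
the fitted direction at every locus). Random-association meioses draw one
of the three pairings and one member per bivalent; heterogenomic bivalents
may exchange members between adjacent loci with a per-interval crossover
probability (default 0.25, a free parameter chosen so per-group recombinant
frequencies fall in the observed 0.1–0.3 range — the data constrain only
the per-group outcome, not per-interval rates). Intra-genomic crossovers
are not simulated: all downstream summaries are genus-level, to which they
are invisible. Double reduction duplicates one chromosome at a designated
focal locus per group (the first, by default); other loci of such gametes
follow the random-pairing draw, so the single-locus marginal is exact at
the focal locus and has an effective β = 0 elsewhere — full chromatid-level
modelling of multilocus double reduction is out of scope. Note that a
double-reduction gamete shows a genus-dosage change at the focal locus and
is therefore counted as recombinant, which is biologically coherent
(double reduction requires a multivalent and a crossover).

Seeding: one master seed; each (gamete, linkage-group) pair gets a child
stream derived by counter, so extending one group's marker list does not
perturb another group's draws. All outputs are byte-reproducible given the
seed.

The simulator emulates marker segregation only: no gamete/zygote viability
selection, no aneuploidy, no genotyping error or missingness, and
multilocus double reduction is focal-locus only. Tests passing on simulated
data therefore validate the estimators under the stated model, not the
wet-lab genotyping pipeline that produced real calls.

## Pipeline and numerical conventions

The driver runs: read and validate tables (heterozygous maternal overlap
fails at load; dosage sums are checked against ploidy with per-locus null
allowances) → gamete inference → null-allele constitution ranking for
< 4-allele loci → distortion screen (exclusion after rescue, mirroring the
one locus whose null constitution explains its frequencies) → per-locus
mixture fit → transmission, linkage-group, recombination, correlation and
dissimilarity summaries → tab-separated outputs plus a JSON run log
(versions, seed, stage counts). τ/β and LRT are displayed at two decimals
while full precision is stored. On the packaged dataset the screen excludes
exactly the three published distorted SSRs and fits 16 SSR + 9 SNP loci in
well under a minute; the heavier validation suites (exhaustive duplex
agreement for all count vectors with n ≤ 60, 200-replicate recovery at
n = 5000, 2000-replicate null calibration at n = 58) were sized to run in
tens of seconds and give Monte-Carlo error comfortably inside the asserted
bounds.

## Known limitations

* The original SSR fits used a constrained non-linear regression whose
  objective is not documented; this package defines the estimator as exact
  multinomial ML. Printed τ values differ from the exact-ML reconstruction
  by up to 0.04 at some SSR loci (e.g. one duplex SSR prints 0.58 where
  exact ML gives 0.62), so SSR τ/β point values are validated by estimator
  properties rather than table lookup; the duplex SNP estimates, the LRT
  p-value transform, the distortion p-values and all categorical outcomes
  reproduce the published tables at display precision.
* β is reported only where structurally identifiable; at loci where nulls
  or duplicate alleles mask double-reduction products the flat direction is
  fixed at 0 rather than reported as an estimate.
* Multi-locus joint likelihoods and interval estimates (bootstrap CIs) for
  τ are not implemented.
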