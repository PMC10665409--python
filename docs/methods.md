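# Methods

## Study design being modeled

A focal parent (FID) in a sire × dam mating transmits one gamete per
offspring.  With dense biallelic SNP genotypes on parents and many full sibs,
the parental phase can be resolved and each transmitted gamete decomposed
into a grandparental-origin sequence; every origin switch is a crossover that
occurred in one meiosis of the FID.  Two per-meiosis phenotypes follow:
crossover count (CC), and intra-chromosomal allelic shuffling
r̄ = Σₖ 2pₖ(1−pₖ)Lₖ², the probability that a random same-chromosome locus
pair was uncoupled during that meiosis.  Because each FID has many scored
meioses, repeated-records mixed models give heritabilities and genetic
correlations, and FID means support genome-wide association.

Coordinates are 1-based inclusive base pairs; dosages count the A1 allele;
1 Mb bins are half-open.

## Simulator

Chiasmata are simulated at the **bivalent** level: counts per chromosome are
Poisson(λ_sex · w_k · rate_i), optionally replaced by max(N, 1) (obligate
rule), positions i.i.d. from a piecewise-linear density over relative
position sampled by inverse CDF.  Each chiasma enters a sampled gamete
independently with probability ½ (two of four chromatids, no chromatid
interference) and toggles the copied strand.  One obligate chiasma therefore
gives 0.5 expected gamete crossovers — a 50 cM map; a gamete-level Poisson
shortcut would give 100 cM and contradict the obligate-crossover floor.
There is no crossover interference (a gamma-interference model is out of
scope).

Individual rate variation is multiplicative through a log link:
rate_i = exp(aᵢ + peᵢ − v/2), mean one by construction.  aᵢ is an additive
polygenic value over n_causal founder-segregating SNPs with per-sex target
variances and a configurable cross-sex effect correlation; per-sex values are
standardized empirically to the target variance rather than set in closed
form, so the realized h² of CC is a calibrated emulation, not an input.

Two presets define the default study conditions:

- **desk** (test scale): 5 acrocentric chromosomes × 40 Mb, 200 markers
  each, 60 sire×dam families × 20 offspring; female chiasma intensity set by
  solving λ + e^{−λ} = 2·CC_target so true mean gamete CC is 1.0 per
  chromosome (obligate), male 0.625 per chromosome non-obligate — a 1.6
  female:male CC ratio.  Male positional density is uniform on the distal
  10% of the chromosome; the female density is a broad pericentromere-biased
  ramp.  σ²ₐ = 0.02, σ²_pe = 0.01 per sex on the log scale, 200 causal loci,
  genotyping error 0.1% per allele, missingness 0.3% (matching a 0.997 call
  rate).
- **salmon-scale**: the 29 bundled salmon chromosome lengths (2,499 Mb),
  ~35K markers, λ calibrated so true mean gamete CC is 19.6 (female,
  obligate) and 12.1 (male).  The male target lies *below* the
  29-chromosome obligate floor of 14.5, which the source study attributes to
  undetected male crossovers on chromosomes with residual tetrasomic
  behavior; males are therefore simulated non-obligate so the truth-level
  mean matches the observed value.  Trait variances are set so h² of CC is
  near 0.1 in both sexes.

The simulator emulates: family structure, sex-dimorphic landscapes,
polygenic rate variation, allele-flip genotyping error, missingness.  It
does **not** emulate: crossover interference, quadrivalent/tetrasomic
pairing, array-merging artifacts, imputation, or a sex-determining region.
Passing tests therefore validate the estimators under a clean no-interference
meiosis model, not every property of real array data.

## Phasing

Families are built per distinct sire×dam pair with genotyped parents and at
least one genotyped offspring (default `min_offspring = 4` for phasing;
configurable to 1).  QC: offspring genotypes impossible given both parents
are set missing (Mendel check); per family, offspring genotype counts are
tested against Mendelian expectations by χ² goodness of fit and markers with
p < 0.01 are masked within that family (untestable configurations are kept).

Informative markers are those where the focal parent is heterozygous and the
transmitted allele is resolvable (other parent homozygous, or offspring
homozygous; double-heterozygous trios yield a missing origin for that
offspring only).  The parental phase is a binary orientation per informative
marker, solved by a greedy majority-vote chain in genome order: each marker
is oriented to keep the majority of offspring origins unchanged relative to
each offspring's most recent scored origin; ties keep the previous
orientation.  A coordinate-descent repair sweep then flips any single marker
whose flip strictly reduces the total origin-switch count.  On complete data
the per-step majority vote is exactly the minimum-recombination phasing
(the objective decomposes over adjacent markers), which the tests verify
against exhaustive enumeration up to 12 markers.  With sparse
double-heterozygous runs the objective has local optima and rare isolated
misorientations can survive; this is a known limitation of min-recombination
phasing in small families (likelihood-based multipoint phasing would resolve
it and is out of scope).  Origin labels are anchored to grandparental origin
where grandparents are genotyped (majority vote over markers where a
grandparent is homozygous); unanchored chromosomes are labeled arbitrarily,
which leaves CC and r̄ invariant.

## Phenotypes

Runs of identical origin shorter than `min_support` markers (default 3;
1 in truth-recovery tests) flanked on both sides by the opposite origin are
masked as genotyping error; each remaining state change emits a crossover
event localized to its bracketing informative-marker interval.  CC is the
genome-wide event count.  For r̄, breakpoints are placed at the physical
midpoint of each crossover interval (the data do not identify the position
within the interval; the resulting error in pₖ is bounded by half the
informative-marker spacing), chromosome ends extend the nearest origin, and
pₖ is physical-length-weighted (a marker-count mode exists for sensitivity
analysis).  Chromosomes without informative coverage contribute zero and set
a coverage flag rather than discarding the gamete.

## Linkage maps

Marker order is fixed to the genome.  Crossover events are counted per
meiosis between that meiosis's consecutive scored markers and assigned to
the marker interval containing the event midpoint; the denominator of an
interval is the number of meioses whose scored span covers it.  On fully
informative data this is exactly the classic share-of-recombinant-meioses
between adjacent markers; with family-mosaic informativeness it avoids the
distance loss that a strict adjacent-marker pairwise-complete count suffers
when neighboring markers are informative in disjoint families (zero-overlap
intervals would silently contribute 0 cM).  Interval fractions ≥ 0.5 are
capped at 0.49 with a warning (Haldane is undefined at 0.5); distances are
d = −50 ln(1−2r) cM, cumulated from 0; never-informative markers get cM
interpolated by physical position.  Binned rates divide the cM span by the
Mb span of the markers inside each 1 Mb bin (missing when fewer than two
markers); relative-position profiles average binned rates across acrocentric
chromosomes on a 0 = centromere → 1 = telomere axis (loess smoothing is
presentation, not inference, and is omitted).

## Variance components

GRM: VanRaden method 1, G = ZZᵀ / Σ2pⱼ(1−pⱼ), allele frequencies from the
analyzed sample, missing dosages mean-imputed, monomorphic markers dropped;
a 1e-6 ridge is added before factorization.  Inbreeding:
F = (O_hom − E_hom)/(m_obs − E_hom) per individual over its non-missing
polymorphic markers.

The repeatability model is fit per sex (sex-specific components), with
intercept and F as fixed effects.  Because all covariates are FID-level, the
observation-level REML likelihood factorizes exactly into (i) FID means with
covariance Vₐ·G + Vₚₑ·I + Vₑ·diag(1/nᵢ) and (ii) the pooled within-FID sum
of squares, Vₑ-scaled χ² — the representation the AI-REML engine consumes,
making fits on hundreds of thousands of records cheap.  Optimization:
3 EM-gradient warm-up iterations, then average-information steps with
step-halving, a gradient line search, and an EM fallback whenever a step
would decrease the restricted log-likelihood (logL is non-decreasing by
construction); convergence at |ΔlogL| < 1e-8, cap 200 iterations; variance
components floored at 1e-10 of the phenotypic scale.  Standard errors come
from the inverse AI matrix; h² and t SEs by the delta method.

Bivariate fits share the machinery with a 2×2 genetic (co)variance through
the GRM, trait-specific permanent-environment and residual variances, and a
structurally zero residual covariance (no meiosis carries both traits; for
cross-sex traits no individual does either).  r_g = cov_a/√(Vₐ₁Vₐ₂), clamped
to [−1, 1], undefined (flagged) when either Vₐ sits at the floor.
Phenotypic correlations are Pearson correlations of FID means.

## GWAS

Per-meiosis phenotypes are collapsed to FID means ȳᵢ with weights derived
from the repeatability decomposition Var(ȳᵢ) = Vₐ + Vₚₑ + Vₑ/nᵢ, expressed
as a residual scale relative to a single record:
dᵢ = ((t−h²) + (1−t)/nᵢ)/(1−h²); the weights enter the residual covariance
(D = diag(dᵢ)), not the GRM.  For each left-out chromosome, null variance
components are re-estimated by REML with G₍₋c₎ and D, then every SNP on that
chromosome is tested by GLS with a 1-df Wald χ².  Sexes are analyzed
separately; an unweighted mode (D = I) is provided and coincides with the
weighted analysis when every FID has one observation.  The Bonferroni
threshold is α/m with m the number of tested markers (the published worked
example, 0.05/49,087 = 1.02×10⁻⁶, is checked as an aggregation target).

## Problem sizes and numerical choices in the test suite

Test simulations run at desk scale (5 × 40 Mb chromosomes, 200–300 markers
per chromosome, tens of families), chosen so each suite completes in seconds
while keeping Monte-Carlo standard errors small relative to the tested
effects; tolerances are stated per test (3 Monte-Carlo SE for means, 2
reported SE for parameter recovery, binomial 95% intervals for error rates).
The truth-recovery check uses a crossover density supported on the interior
90% of the chromosome so every crossover falls inside some gamete's
informative-marker span — with hotspots at the extreme telomere, crossovers
beyond the last informative marker are undetectable by any phasing method,
which is a marker-coverage property, not an estimator defect.
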