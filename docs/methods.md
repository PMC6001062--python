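# Methods

## Model

The central quantity is the per-gene carrier fraction *f*: the proportion of
individuals in a reference cohort of size N who carry at least one qualifying
rare variant in the gene, under a chosen filtering scenario.  A scenario is a
`FilterKey`: population grouping (aggregate or one of five continental
superpopulations), a minor-allele-frequency threshold from the grid
{5%, 1%, 0.5%, 0.1%, 0.05%} (arbitrary thresholds are accepted for
user-built tables), a consequence class (protein-altering = missense/in-frame
plus LOF; LOF-only = splice-site within 2 bp of a junction, stop-gain,
frameshift), a zygosity requirement, and a counting mode (carriers, or
variant-carriage events where an individual with two qualifying variants in a
gene counts twice).

Significance tests treat each affected familial unit as an independent
Bernoulli trial whose chance success probability is *f* scaled by the
identity-by-descent sharing within the unit:

- unrelated proband: *f* (the zygosity channel of *f* matching the study's
  filter — f_hom for recessive designs, f_het/f_both for dominant ones);
- sib pair sharing a homozygous variant: *f*/4;
- consanguineous pair connected through a single common ancestor by paths
  with E independent edges: *f* · (1/2)^(E−1);
- a group of s relatives sharing a heterozygous variant by descent:
  r · *f* with relationship coefficient r = (1/2)^(s−1);
- de novo events: per-proband probability l_tx·d·c (transcript length ×
  per-nucleotide de novo SNV rate × the fraction of de novo events meeting
  the consequence threshold: c = 0.0285 for splice/nonsense only, 0.7064 for
  all protein-altering events).

Each homogeneous design yields the upper binomial tail P(X ≥ k),
X ~ Binomial(n, p).  All tails are computed with `scipy.stats.binom.sf` —
no normal approximation anywhere.

### Mixed designs

For n singletons (coefficient r₀ = 1) pooled with m familial units of one
kind (coefficient r₁), the probability of observing exactly a singleton
successes and b familial successes is modelled as

    P_{n,m,a,b} = P(X = n+m−a−b) · P(Y = a),
    X ~ Binomial(n+m, F),   F = 1 − (n/(n+m)) r₀ f − (m/(n+m)) r₁ f,
    Y ~ Binomial(a+b, r₀n / (r₀n + r₁m)),

and the P-value is the sum of P_{n,m,a,b} over all outcomes on the grid
0 ≤ a ≤ n, 0 ≤ b ≤ m whose probability does not exceed that of the observed
(k, j) — the observed outcome always included.  Ties in outcome probability
are compared with a relative tolerance of 1e−12 so the summation is
insensitive to order-of-evaluation rounding.

This mixture is not a normalized joint distribution: its probabilities need
not sum to 1 over the restricted grid.  It is nonetheless implemented
verbatim as the package's default because it is the method's defining
summation; an exact alternative treating singleton and familial successes as
two independent binomials is available via `method="independent"` on
`pvalue_combined`.  The Monte-Carlo calibration (below) shows the mixture's
tail probabilities agree with its own generative model, which is what the
P-value claims.

### Zero-carrier genes

A gene with no observed carriers has an undefined (not zero) carrier
frequency in a finite cohort.  The significance layer substitutes
f = 1/(2N) — half an individual in a cohort of N — when the caller opts in
(`zero_substitute=True` / `--zero-sub`); `query_fraction` itself never
substitutes silently.  For predictive calculations with a larger reference
panel showing zero carriers, `f_upper_bound` returns 1/N_ref, or 3/N_ref
under the rule-of-three conservative variant.

### Bonferroni correction

Corrected P-values are min(1, P × G) where G is the number of genes the study
actually interrogated (exome-wide ≈ 20,000; candidate panels use the panel
size; follow-up sequencing of a single gene uses G = 1).

## Collapsing pipeline

Cohort genotypes enter as a VCF plus a consequence-annotation sidecar TSV
(variant key → consequence term, gene ids, transcript ids); sample sex and
population come from a samples TSV.  Choices where the procedure was
genuinely open:

- **Coordinates**: VCF positions are 1-based; internal exon and domain
  intervals are 0-based half-open.
- **Multi-allelic sites** are decomposed into biallelic records before MAF
  filtering; missing genotypes are excluded from MAF denominators and treated
  as non-carrier when collapsing.
- **MAF** is the cohort alternate-allele frequency folded to the minor
  allele; filtering is strict (< threshold).  When collapsing per-population
  subsets, MAF is still computed on the full cohort by default
  (`per_population_maf=True` switches to within-subset frequencies).
- **Male X chromosome**: hemizygous calls are recoded additively — an
  alternate call behaves as homozygous for zygosity purposes and contributes
  one allele to frequency denominators.  Heterozygous male X calls are
  rejected as data errors.
- **Compound heterozygotes without phase**: an individual qualifies for the
  CHet/Hom channel with ≥ 1 homozygous qualifying site or ≥ 2 distinct
  heterozygous qualifying sites in the gene — the standard conservative
  surrogate when phase is unknown.  CHet/Hom is undefined in
  variant-multiplicity mode.
- **Indel consequences** (frameshift vs in-frame) are taken from the
  annotation source, never recomputed.

Absent features in a burden table mean zero carriers: tables are dense over
the annotated gene universe at build time, and queries outside that universe
warn and return 0.

Gene ranking by intolerance sorts ascending on rare-LOF carrier count with
tie-breaking by successively broader scenarios (rare protein-altering, then
less-rare protein-altering); genes still tied share a midrank.  Population
divergence reports the five superpopulation fractions, their population
(ddof = 0) variance, and the population(s) deviating most from the mean.

## Domain depletion

For each protein-domain instance, with v_dom and v_gene the per-individual
variant counts in the domain and the gene (multiplicity mode; default filter
rare MAF < 0.5% heterozygous LOF) and L_dom, l_tx the domain and transcript
lengths:

    score = (v_dom / v_gene) / (L_dom / l_tx)

so proportional placement scores exactly 1 and depleted domains score below
1.  The printed-formula precedence is ambiguous; this orientation is the only
reading under which the stated chance expectation of 1 holds.  The P-value is
the lower binomial tail P(X ≤ v_dom_count), X ~ Binomial(V_gene_total,
L_dom/l_tx), using cohort-total variant events as the integer trial count
(a per-individual mean cannot index a binomial).  P-values are PHRED-scaled
(−10·log₁₀ p; the constant is configurable, p = 0 capped at 990 with a
warning).  Filtering drops genes with no observed variants and domains
spanning more than 50% of their transcript (exactly half is kept).
Significance is Bonferroni-corrected by the number of genes surviving
filters, not the number of domain instances.  Genome-wide domain-type
summaries average repeated instances within a gene first, then take the mean
and variance across genes, weighting genes equally.

## Synthetic generators

`simulate_cohort` plants per-site genotype probabilities (p_het, p_hom) and
draws genotypes independently per variant and individual; per-gene carrier
probabilities per zygosity channel then follow in closed form and are written
to the truth table (sex-weighted for X genes).  The default reference-cohort
stand-in used in tests is a few hundred to 2000 individuals with per-site
heterozygote probabilities of 0.2–5% — the scale at which the real panel's
rare-variant burden lives — with a 50:50 sex ratio.  What the generator does
**not** emulate: linkage disequilibrium, a realistic site-frequency spectrum
(sites are point masses, keeping the truth exact), population structure in
allele frequencies, sequencing error and missingness patterns.  Passing tests
therefore validate the counting, filtering and probability machinery, not
robustness to real-data artifacts.

`simulate_family_study` draws unit successes at the exact per-unit chance
probabilities above times an enrichment multiplier (1 = null).
`simulate_domain_placement` drops V variants uniformly on a transcript and
returns the empirical depletion-score and count distributions.

## Problem sizes and calibration checks

The packaged calibrations use problem sizes chosen to make Monte-Carlo error
small relative to the quantities checked while keeping runs interactive:
10⁶ replicates for the combined-test oracle (standard errors ~10⁻⁴ on tail
probabilities of 10⁻³–10⁻¹), 1000–2000 replicate null family studies for the
type-I error rate, a 2000-individual cohort for planted-fraction recovery
(99% binomial envelopes), and 10⁴–5×10⁴ placements for the depletion null.

## Known limitations

- The de novo rate d ships with no default; published per-nucleotide rates
  vary and several are CpG-adjusted, so the value (and its citation) is a
  required user input.
- Study designs mixing singletons with more than one kind of familial unit
  have no closed-form test here and raise; evaluate kinds separately.
- A handful of published study rows that motivated the formula catalogue
  cannot be reproduced from their printed inputs because the underlying
  pedigree parameters (path edge counts, family shapes) were not published;
  the deterministic test suite covers only the rows whose inputs are
  complete.  One published worked PPV example rounds to "roughly 1.0%"
  where the direct arithmetic on its own inputs gives 0.58%; the package
  reports the arithmetic result.
- Burden tables shipped or built here are synthetic stand-ins; real
  population-panel tables must be built from genotype data the user supplies.
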