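# sorva

Mutational-burden frequency tables and a family-structure-aware significance
calculus for rare-variant studies of Mendelian and complex disorders.

## The problem

When exome or genome sequencing of a handful of affected individuals turns up
rare variants in a candidate gene, the question is always the same: how likely
is that constellation of findings by chance alone?  The answer depends on how
often healthy individuals carry qualifying rare variants in that gene — its
mutational burden in the general population — and on the family structure of
the affected sample, because relatives share variants identical by descent.

This package provides, for researchers vetting candidate genes from
next-generation sequencing studies:

- **Burden tables** (`sorva.freqtable`, `sorva.collapse`): per-gene and
  per-protein-domain counts of individuals in a reference cohort (N = 2504
  emulating a population panel across five continental superpopulations) who
  carry a qualifying variant, over a grid of minor-allele-frequency thresholds
  (5%, 1%, 0.5%, 0.1%, 0.05%), consequence classes (protein-altering vs.
  loss-of-function only), and zygosity requirements (het, hom, either, or
  compound-het/hom).  The fraction *f* = count/N is the a-priori probability
  that a random individual carries such a variant.
- **Significance tests** (`sorva.significance`): every study design maps to an
  upper binomial tail P(X ≥ k), X ~ Binomial(n, p), on the number of
  "successful" familial units, with the per-unit chance probability p scaled
  by identity-by-descent sharing:

  | study design                         | per-unit probability    |
  |--------------------------------------|-------------------------|
  | k of n unrelated affecteds           | *f*                     |
  | k of n sib pairs, homozygous sharing | *f*/4                   |
  | consanguineous pair, E path edges    | *f* · (1/2)^(E−1)       |
  | relatives sharing het variants       | *r* · *f*               |
  | de novo events in s of n probands    | *l*_tx · *d* · *c*      |

  where *r* is the coefficient of relationship ((1/2)^(s−1) for s members
  sharing through common ancestors), *l*_tx the transcript length, *d* the
  per-nucleotide de novo SNV rate, and *c* the fraction of de novo events
  meeting the consequence threshold.  Mixed designs (n singletons plus m
  familial units) are evaluated by summing the probabilities of all outcomes
  at most as likely as the observed one.  Genes with zero observed carriers
  use the conservative substitution *f* = 1/(2N).
- **Domain depletion** (`sorva.domains`): a binomial test for protein domains
  carrying fewer variants than their share of the transcript predicts, with
  PHRED-scaled scores (−10·log₁₀ p).
- **Predictive genomics** (`sorva.predictive`): Bayesian positive predictive
  value of a qualifying genotype, PPV = P(B|A)·P(A)/P(B), with sensitivity
  P(B|A), incidence P(A) and carrier fraction P(B) from the burden tables.
- **Synthetic cohorts** (`sorva.synthetic`): seed-deterministic generators for
  diploid cohorts with planted carrier probabilities (VCF + annotation
  sidecar + exact truth), null family studies, and uniform domain placements.

## Worked example

A dominant-disorder study sequences 10 unrelated affected individuals and
finds rare heterozygous loss-of-function variants in the same gene in 7 of
them.  In the reference cohort, 5 of 2504 individuals carry such a variant
(*f* = 5/2504 ≈ 0.0020).  Testing exome-wide (20,000 genes):

```
$ sorva pvalue --f 5/2504 --design "singletons=10:7" --genes-tested 20000 --format json
{
 "p_value": 1.5109589768104982e-17,
 "corrected_p_value": 3.0219179536209966e-13,
 "genes_tested": 20000,
 "a_priori": 0.001996805111821086,
 "method": "recurrent"
}
```

Seeing 7 of 10 unrelated carriers by chance has probability 1.5 × 10⁻¹⁷;
even after Bonferroni correction for every gene in the exome the finding
remains overwhelmingly significant (3.0 × 10⁻¹³).

For prenatal screening: a fetus carries compound-heterozygous variants in a
congenital-muscular-dystrophy gene that explains 10% of cases of a disorder
with incidence 1:21,500, and 2 of 2504 reference individuals carry such
variants:

```
$ sorva ppv --sensitivity 0.10 --incidence 1:21500 --f 2/2504 --format json
{
 "ppv": 0.005823255813953488,
 "sensitivity": 0.1,
 "specificity": 0.9992012779552716,
 ...
}
```

The genotype is a highly specific (99.9%) but weakly predictive (PPV ≈ 0.58%)
test — rare-disease incidence dominates the calculation.

Other subcommands: `sorva build` (burden tables from a VCF), `sorva query`
(table lookup), `sorva domains` (depletion scoring), `sorva simulate`
(synthetic data).  Run `sorva <cmd> --help` for options.

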