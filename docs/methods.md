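# Methods

## The model

famseg targets the design of multiplex-family exome studies of a dominant
trait: multiple affected relatives per family, a shared rare variant
assumed to enter each family through a single founder and to pass only
from parent to child, and full penetrance among carriers *for the purpose
of co-segregation scoring* (an affected non-carrier is treated as evidence
against the variant, which is exactly how the filter guards against
phenocopies and genotyping error). Zygosity is irrelevant under dominance:
"carrier" means heterozygous or homozygous-alternate.

### Obligate carriers

Given the single-founder dominant model, an unaffected individual is an
obligate carrier when every consistent transmission configuration forces
them to carry. The defining semantics is enumerative: a carrier set is any
member subset containing all affected individuals and exactly one founder,
in which every non-founder carrier has a carrier parent; obligate carriers
are the unaffected members present in every such set. The implementation
avoids the exponential enumeration: for each *feasible source founder*
(a founder from whom every affected member descends), the forced carriers
are the dominators of the affected set in the parent→child DAG (members
whose removal disconnects some affected member from the source), and the
obligate set is the intersection over feasible sources restricted to
unaffected members. The two formulations agree — a member avoidable under
some source appears in a valid carrier set excluding them — and the test
suite checks the equivalence on hundreds of random pedigrees, including
consanguineous (non-tree) ones, where the dominator route needs no
special-casing because reachability is computed on the DAG, not a tree.
When no founder reaches every affected member the pedigree cannot
segregate a single dominant variant and both routes raise the same
"non-segregating pedigree" error naming an offending affected pair.

### Blood relatives

Configuration B requires an unaffected *blood* relative, excluding
married-in relatives, but pedigree files do not label blood status. famseg
derives it structurally: every non-founder is a blood relative; a founder
is one exactly when it is a feasible single source for all affected
members (fallback, for families with no affected member or no feasible
source: founders with any affected descendant). This excludes the typical
married-in spouse, whose only link to the affected core runs through their
own children, while keeping both parents of an affected nuclear family —
the structurally honest choice, since either could be the transmitting
parent.

### Family configurations

With sequenced-member counts and the relationship classifier (full
siblings require both recorded parents shared; half-siblings and anything
more distant are "other"):

- **A** — ≥ 3 sequenced affected, or ≥ 2 sequenced affected plus a
  sequenced obligate carrier (declared or inferred);
- **B** — ≥ 2 sequenced affected with some pair "other", plus ≥ 1
  sequenced unaffected blood relative;
- **C** — ≥ 2 sequenced affected, all pairs sibling/parent–child;
- otherwise uninformative. Members of unknown affection are ignored.

A variant qualifies by co-segregating in ≥ 1 A family, else ≥ 1 B family,
else ≥ 2 C families; the rule label records the strongest evidence class.
The optional *strict unaffected* mode additionally requires absence from
every sequenced unaffected blood relative; it is off by default (the base
criteria do not demand it) and the strict candidate set is always a subset
of the default one. Reports print the affected/obligate/unaffected count
triple with the third number as *unaffected sequenced*, and carry separate
unaffected-carrier counts, because published tables are ambiguous about
which of the two the third figure means.

## Filters: numerical conventions

- Depth: per-sample masking (default) because downstream segregation needs
  trustworthy per-person carrier calls; a variant falls only when every
  carrier genotype is masked. A site-level strict mode (`depth_mode:
  site`) fails the variant when any sample is under-covered, for studies
  that filtered on aggregate site depth.
- Boundaries are inclusive for retention: frequency exactly 0.005 passes
  (the rule excludes only > 0.5%), CADD exactly 15 passes (≥ 15), in-house
  counts (3, 50) pass (> 3 / > 50 exclude).
- Missing population frequency counts as 0 (unobserved alleles are the
  rare ones of interest); missing CADD fails (deleteriousness cannot be
  asserted); a missing segmental-duplication flag passes with an audit
  note.
- Rules are applied in the order depth, segdup, frequency, inhouse,
  functional, cadd for `first_failed_rule` attribution, but all six
  results are recorded and the verdict is order-invariant.
- A missing genotype in a required carrier defeats co-segregation
  (conservative: absence of evidence is not evidence of carriage).

## Statistics

- **Hypergeometric tail** accumulated from log-pmf values via
  log-sum-exp; `k = 0` returns exactly 1. The universe size is a
  configuration value (default 23,000 protein-coding genes) because
  curated pathway knowledge bases rarely publish their reference set; at
  that default a 6-of-38 overlap from 608 candidates gives p = 4.47×10⁻⁴,
  and the tail ranges from 9.3×10⁻⁴ to 2.9×10⁻⁴ as the universe sweeps
  20,000–25,000 — the order of magnitude, not the third digit, is the
  robust statement.
- **Fisher exact test**, two-sided, minimum-likelihood convention: with
  margins fixed the table probabilities are proportional to
  `C(r1, j)·C(r0, c1−j)`, so tie decisions are exact integer comparisons
  and the p-value is a ratio of integers converted once to float.
- **Odds ratio**: Woolf's log-scale interval reproduces the reported
  (1.4, 14) interval for the reconstructed 14/183 vs 4/233 deficiency
  table; an empty cell triggers the Haldane–Anscombe 0.5 correction,
  flagged in the result. Display convention: one decimal below 10, two
  significant figures at or above 10.
- **Count reconstruction** from printed proportions rounds half away from
  zero (197 × 0.071 = 13.987 → 14; 237 × 0.017 = 4.029 → 4).
- **Group comparison** defaults to the Wilcoxon rank-sum test — exact
  when both groups are ≤ 20 and tie-free, otherwise the normal
  approximation *without* continuity correction so a perfectly central
  statistic (identical groups) yields p = 1 exactly; Welch's t and a
  10,000-resample permutation test are selectable because published
  reports often leave the test unstated.
- Fisher and chi-square p agree within a factor of 2 only for expected
  cell counts ≥ 5 *and* p ≳ 10⁻³; in the far tail the χ² approximation's
  multiplicative error grows without bound, which is why the package
  reports both rather than treating them as interchangeable.

## Synthetic cohorts

The generator emulates the sampling structure of a large multiplex-family
study: 97 families by default — 35 configuration-A (alternating
three-affected-sibling families and affected-grandparent/obligate-parent/
affected-grandchild families), 31 avuncular configuration-B families with
a sequenced unaffected sibling, 31 affected sib-pair configuration-C
families — 13 planted causal variants in 12 genes cycling through the
three qualification rules, and one distractor per violation mode: depth,
segmental duplication, population frequency, either in-house count,
synonymous consequence, low CADD (8.943, a value reported for a rejected
candidate), a phenocopy (absent from one affected member), and a variant
co-segregating in only one sib-pair family. One planted variant sits
exactly on every retention boundary (AF 0.005, CADD 15.0, in-house 3/50)
so the inclusive boundary semantics is exercised end to end. Depths are
normal (mean 60, sd 12) clipped at 12 so planted variants are clean by
construction; genotype missingness (default 2%) applies only outside
supporting families.

The serum panel draws 197 cases and 237 controls with deficiency flags
Bernoulli(0.071)/Bernoulli(0.017) and magnesium values from truncated
normals (means 1.9/2.1 mg/dL, sd 0.25) placed strictly on the flagged
side of the 0.7 mmol/L (1.7017 mg/dL) threshold. Because a single panel
contains only ~4 deficient controls, per-panel odds ratios are highly
variable (and occasionally infinite); generator validation therefore
pools counts across hundreds of seeds and compares the pooled OR with the
rate-implied value (0.071/0.929)/(0.017/0.983) = 4.42.

What the generator does *not* emulate: linkage disequilibrium, sequencing
error models, relatedness-driven genotype correlation at non-causal
sites, age structure, or ascertainment bias. Passing the planted-truth
tests therefore demonstrates the correctness of the filtering and
segregation logic under the stated model, not robustness to real-world
artifacts beyond the violation modes explicitly planted.

All randomness flows through a single seeded generator; identical
configurations produce byte-identical files, and the pipeline itself is
fully deterministic (the manifest digests inputs so any byte change is
visible).

## Problem sizes

Tests and the acceptance script run cohorts of 97 families (~260
sequenced samples) with ~22 variants, 20 seeds for the recovery property,
200 random pedigrees of ≤ 12 members for the obligate-carrier
equivalence, every 2×2 table with total ≤ 60 for the exact-test
equivalence, and 100,000 resamples for the Monte-Carlo check of the
hypergeometric tail — sizes chosen so each check is exhaustive or tightly
concentrated while the whole suite stays interactive.

## Known limitations

- X-linked and recessive models, kinship estimated from genotypes,
  penetrance modeling, and haplotype phasing are out of scope.
- The blood-relative derivation is structural; with a recruitment-time
  label available it should be supplied as declared obligate/affection
  data instead.
- Gene symbols match case-insensitively with no alias resolution; supply
  consistently normalized annotation and GMT inputs.
- The annotation table is consumed as given: consequence prediction,
  CADD scoring, and frequency lookups happen upstream.
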