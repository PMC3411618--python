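# Methods

## The analysis model

The package analyses a case-control cohort typed at the three
polymorphic DLA class II loci (DRB1, DQA1, DQB1). Because the class II
region is in strong linkage disequilibrium, a breed segregates a small
set of conserved three-locus haplotypes, and the analysis unit is the
chromosome: a cohort of n dogs contributes 2n chromosomes per group.
The pipeline phases genotypes into haplotypes, compares allele and
haplotype frequency distributions between cases and controls, and
estimates per-category odds ratios.

## Phasing

Phasing is combinatorial, not statistical. A three-locus genotype
heterozygous at h loci has 2^(h-1) phase configurations (at most 4), so
with a modest known-haplotype set phase is usually forced:

1. *Triple homozygotes* are assigned the doubled haplotype; each dog
   adds 2 to that haplotype's observation tally.
2. *Double homozygotes* (exactly two loci homozygous) split their
   heterozygous locus across two otherwise-identical haplotypes — a
   unique decomposition, confirming known haplotypes or adding new ones.
3. *Remaining dogs* are resolved against the known set, iteratively:
   among all phase configurations, those with both haplotypes known are
   candidates, ordered by descending combined observation tally with
   lexicographic tie-break (the tally order expresses that frequent
   haplotypes are the more parsimonious explanation; the tie rule is a
   determinism device, nothing more). If no known pair exists but
   exactly one configuration pairs a known haplotype with a single new
   one, that haplotype is proposed as novel; a dog whose resolution
   would require inventing two haplotypes at once stays unresolved and
   is reported. Passes repeat (the known set only grows) until a pass
   changes nothing, with a hard cap of 10 passes as a termination
   guarantee.

Conservation — the per-locus allele multisets of every assignment equal
the dog's genotype — is asserted on every dog after phasing.

Ambiguity handling matters only for cohorts whose haplotype pools
contain "rectangles" (two known pairs consistent with one genotype);
the pass log records every ambiguous choice so an analyst can audit
them.

## Association testing

Frequency tables are 2×n chromosome-count tables. Significance uses
the Pearson statistic with a Monte-Carlo null rather than the
asymptotic chi-squared distribution, which is invalid for the sparse
categories typical of MHC tables:

* Null tables are drawn uniformly from all tables with both margins
  equal to the observed ones, by allocating the case row with a
  multivariate hypergeometric draw. This is the standard conditional
  null for contingency tables.
* The empirical p-value is (1 + #{χ²_sim ≥ χ²_obs})/(1 + trials): a
  valid p-value, never exactly zero. Default 100,000 trials (Monte-
  Carlo SE ≈ √(p(1−p)/trials), i.e. ~3·10⁻⁴ at p ≈ 0.01).
* **T1** tests the full table. **T2** first *clumps* sparse categories:
  every category whose expected count in either group is below 5 joins
  a pooled category, and the pool keeps absorbing the smallest
  remaining category (by pooled count, label tie-break) until its own
  expected counts reach 5 in both groups. The partition is computed
  once from the observed table and applied unchanged to every simulated
  table, so observed and simulated statistics live on the same cells.
  Stopping the absorption only when the clump itself reaches expected
  5 is essential: on the bundled DRB1 table the four sparse alleles
  pool to an expected case count of 3.52, and a clump left that sparse
  changes the T2 p-value by a factor of ~2.
* Ties count as exceedances, with a 1e-9 absolute slack against float
  round-off. A fixed seed gives a bit-identical result.

At small totals (a few hundred chromosomes) the conditional null is a
lattice distribution; its tie atoms mean the Monte-Carlo p can differ
from the asymptotic chi-squared tail by more than Monte-Carlo error
even when all expected counts exceed 5. The asymptotic-agreement test
therefore uses cell counts in the hundreds.

## Odds ratios

OR = ad/bc from a 2×2 collapse, at two exposure levels: *chromosome*
(a = case chromosomes carrying the category, a+b = 132 etc.), the
convention for alleles; and *carrier* (a = case dogs with ≥ 1 copy),
the convention for haplotype risk — homozygotes make the two differ.
Confidence intervals are Woolf's: exp(ln OR ± z_{1−α/2}·√(1/a+1/b+1/c+1/d)).
If any cell is zero, 0.5 is added to all four cells
(Haldane–Anscombe) and the result is flagged. When ORs are pooled
across simulation replicates, pooling is on the log scale with the
+0.5 correction applied in every replicate (as in meta-analysis);
the arithmetic mean of raw ad/bc ratios is upward-biased by the
estimator's heavy right tail when a cell's expectation is small
(~10 control carriers in the recovery experiment below) and is not a
faithful recovery summary.

Frequency filtering (default: keep categories reaching 1% in either
group) treats the threshold as inclusive, so a category at exactly 1%
of pooled chromosomes is kept.

Multiplicity: allele tests use a per-locus Bonferroni threshold
α/3 (three loci → 0.0167, conventionally quoted as 0.017); haplotype
tests use unadjusted α = 0.05. Both are configurable.

Printed confidence intervals in the source tables do not match Woolf
intervals on the same counts (the interval method used there is not
stated), and the protective haplotype's published OR of 0.26 matches
neither the chromosome-level (0.23) nor carrier-level (0.21)
computation; the package reports its own conventions, clearly
labelled, and makes no attempt to reverse-engineer those values.

## Synthetic cohorts

`PopulationModel` holds a haplotype pool with frequencies summing to 1,
per-haplotype odds multipliers (default 1.0 = null), a baseline odds of
disease, target cohort sizes and a seed. `simulate` forms diplotypes by
Hardy–Weinberg random mating (two independent draws from the pool),
assigns status by Bernoulli with odds = baseline_odds × effect(h1) ×
effect(h2), and rejection-samples until exactly n_case cases and
n_control controls are collected, mirroring case-control ascertainment.
All randomness flows from the single model seed.

Defaults emulate the study conditions: pool = the control-group
haplotype frequencies of the bundled reference tables, n = 66/84,
baseline_odds = 0.25 (≈ 20% baseline disease probability — a realistic
case yield for a referral-population disease; under it a per-copy odds
effect of 3.0 at pool frequency 6.5% implies a true carrier-level OR of
≈ 3.1). What the simulator does **not** model: pedigree relatedness,
age/sex structure, genotyping error, locus-level recombination within
the class II block (haplotypes are drawn as intact units), and
population stratification. Passing tests therefore show correctness of
the inference machinery under Hardy–Weinberg mixing of intact
haplotypes, not robustness to those real-data complications.

`fixture_from_tables` rebuilds the 150-dog reference cohort from the
printed chromosome counts. Margins and the stated homozygote facts
(one case and two control dogs homozygous for the risk haplotype, none
for the protective one) are reproduced exactly; the pairing of the
remaining chromosomes is unknowable from printed margins, so a
deterministic admissible pairing is used (stated homozygotes first;
remaining chromosomes of the two homozygote-constrained haplotypes
paired against the most-abundant other haplotype; remaining haplotypes
paired with themselves; odd leftovers paired in table order). Every
reported statistic depends only on the margins and the homozygote
facts, not on the pairing. The two sub-1% "other" chromosomes are
represented by one distinct singleton haplotype per group whose allele
composition is chosen to match every allele margin the study text
prints (case singleton 02301/00401/00501, control singleton
012v/00201/01303).

## Numerical and testing choices

* Problem sizes in the test suite: type-I error is estimated from
  1,000 null cohorts at 2,000 trials per test (band 0.05 ± 0.02);
  effect recovery from 500 replicate cohorts at the study's sample
  sizes; phasing accuracy from 200 simulated cohorts over a 5-haplotype
  pool at n = 60/60, scored only where every segregating haplotype is
  anchored by at least one homozygote (the regime the sequential
  method assumes); the resolver-vs-oracle equivalence on 1,000
  randomized dogs.
* Degenerate inputs: tables with fewer than two non-empty categories,
  groups with zero totals, and clumping that would swallow the whole
  table raise typed errors rather than returning numbers.
* Determinism: phasing is deterministic given input order; all
  Monte-Carlo results carry their seed; the pipeline summary is
  reproducible for a fixed config.

## Known limitations

* The sequential phaser is exact only when the segregating haplotypes
  are anchored by homozygotes or forced splits; cohorts with many rare
  haplotypes and no anchors yield unresolved dogs (reported, never
  dropped) rather than probabilistic assignments. An EM-style phaser is
  deliberately out of scope.
* T2 clumping depends on the observed margins; alternative published
  clumping variants (maximum single-category statistic, best
  partition) are not implemented.
* Woolf intervals are reported for orientation; exact conditional
  intervals are not implemented.
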