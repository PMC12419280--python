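# Methods

## Study design and scope

The package analyses an extreme-phenotype sequencing design for a
quantitative lipid trait. Sampling only the tail of the triglyceride (TG)
distribution enriches for rare, large-effect variants relative to a
population-wide association scan, at the cost of generalisability and of
any inference about common variation. The pipeline starts from called
genotypes and per-variant annotations: read alignment, variant calling,
predictor scores, database allele frequencies and population-structure
correction are all upstream and consumed as given.

## Cohort selection and baseline statistics

The extreme group is the set of samples with TG at or below a threshold
(default 0.45 mmol/L, the clinical cut used for the extremely-low-TG
stratum); controls are drawn from the TG > threshold stratum. Matching is
greedy: the control sex split is set to the extreme group's male fraction
(rounded), and within each sex the controls nearest the extreme group's
mean age are taken. This is a deliberate simplification — no caliper, no
optimal assignment — adequate when the control pool is large and age
homogeneous, as in a student cohort.

Baseline comparisons follow clinical-reporting convention. Normality is
assessed per group by Shapiro–Wilk at α = 0.05 (Kolmogorov–Smirnov by
flag); only if both groups pass is the pooled-variance two-sample *t*-test
used with mean (SD) summaries, otherwise the Mann–Whitney rank-sum with
median (IQR). Shapiro–Wilk was made primary because it is the more
powerful omnibus test at these group sizes. Sex uses the Pearson
chi-square on the 2×2 table without continuity correction. A trait with
zero variance in both groups reports p = 1 with a warning rather than
raising: such columns occur in practice (coded constants) and should not
abort a report. Report rounding is two decimals, round-half-even.

Post hoc power for the group comparison uses the noncentral *t*
distribution: ncp = d·√(n₁n₂/(n₁+n₂)), df = n₁+n₂−2, two-sided. At
d = 0.65, n = 111/102, α = 0.05 this gives 0.997, consistent with the
design claim of exceeding 0.90; the observed TG separation itself
(means 0.40 vs 1.43, SDs 0.04/0.13) corresponds to d ≈ 10.9, so 0.65 is a
very conservative planning figure. The analytic power is cross-checked in
the test suite against a 20,000-replicate Monte-Carlo of the pooled
*t*-test (agreement within 0.01).

Pooled ("totality") trait summaries are size-weighted means of the group
means. Two published pooled cells (TG 0.90, TC 4.12) are inconsistent
with their own printed group summaries by one final digit; the package
computes from data and reproduces the four arithmetically consistent
cells (HDL-C 1.43, LDL-C 2.34 at n = 102/111; cohort HDL-C 1.44 at
n = 1297/2069) but not those two.

## Region and functional taxonomy

Variants are classified against minimal transcript models (sorted
non-overlapping exons, CDS ⊆ exons, strand) into fifteen categories:
eleven single-gene labels and four compound cross-gene labels
(UTR5/UTR3, exonic/splicing, splicing/ncRNA_exonic, upstream/downstream)
assigned when a site receives exactly that pair of labels from two
overlapping genes. Any other multi-gene conflict resolves by severity
precedence (exonic > splicing > ncRNA_exonic > ncRNA_splicing > UTR5 >
UTR3 > intronic > ncRNA_intronic > upstream > downstream); the position of
ncRNA_splicing, absent from the named ordering, was slotted directly after
ncRNA_exonic to mirror the coding-gene ordering. The splice window is
2 bases beyond an exon boundary and the upstream/downstream flank is 1 kb
— the conventional annotator defaults the category names imply; no gene
within the flank is intergenic. The categories partition the input by
construction: every classified position receives exactly one label
(property-tested; the analogous published fifteen category counts sum
exactly to their SNV total, 671,127).

Functional classes of coding exonic variants: insertions/deletions are
frameshift iff the signed length difference is not divisible by three;
single-base substitutions are translated in codon context (standard code,
strand-aware via reverse complement) into synonymous / nonsynonymous /
stopgain / stoploss. Any untranslatable context — no CDS hit, missing
reference sequence, truncated codon, multi-base substitution — returns
"unknown" rather than raising, since annotation tables routinely contain
such rows. Classification is invariant to describing the same event on a
minus-strand model (tested).

InDel lengths (len(alt) − len(ref)) are binned into the ten standard
report bins (±1–5, 6–10, 11–15, 16–20, >20) with percentages to two
decimals; SNVs are excluded and counted separately.

## The prioritization cascade

Four gates run in order: HGMD known/novel flag (annotation only, never
removes), deleteriousness (region exonic or splice-affecting AND
≥ `min_predictors_damaging` of six predictor calls; dbscSNV, a splice
predictor, counts only at splice-affecting sites), frequency (strictly
below every cap: 1000 Genomes 0.001, ESP6500 0.01, self-controls 0.01,
internal reference database 0.005; absent frequencies pass by default),
and quality (fraction of samples with call quality < Phred 20 at most
0.50, site quality letter not "L", homology flag = 1).

Two readings of the source filtering text are possible; this package
keeps variants *below* the caps, because a low-frequency variant screen
is only coherent in that direction and the final carrier tables (a
handful of carriers per gene in ~200 samples) require it. Strict "<" at
every frequency cap and "≤" at the low-quality fraction follow the
stated wording. One damaging predictor suffices by default because no
combination rule is given; the threshold is configurable. The homology
column and the quality letter grade are treated as opaque upstream
annotations (equality / exclusion checks only) — their upstream semantics
are not defined and nothing downstream depends on them beyond the gate.

Because the gates are independent per-variant predicates, the surviving
set is identical under any stage order and the cascade is idempotent
(both property-tested); only the attrition accounting depends on order.
Lowering any cap can only shrink the survivor set (tested over a
threshold grid).

## Gene-level burden

Per gene, samples collapse to (A, B, C) = (wild-type, het-carrier,
hom-carrier); a sample missing at every surviving site of a gene is
excluded from that gene's table, so per-gene totals may fall below the
enrolled count. The carrier-rate ratio divides per-group carrier
frequencies and is **truncated** (not rounded) to three decimals —
truncation is the only reporting rule consistent with all published
example values (e.g. 1111/216 = 5.1435 → 5.143, 1010/108 = 9.3519 →
9.351). With zero control carriers the extreme-group carrier count is
reported instead (the published zero-control convention). The statistic
is carrier-based, not allele-based: a het+hom pattern of 10+1 carriers
reproduces the published 10.287 only when the hom sample counts once.

The exact test is the hypergeometric tail of the observed or more
extreme carrier split; the default two-sided convention doubles the
smaller tail and caps at 1, with the min-likelihood convention by flag.
The implementation is checked against full enumeration with exact
rational arithmetic on all small tables. The published per-gene p-values
are not reproducible under any standard convention (doubling,
min-likelihood, or asymptotic chi-square all differ from the printed
values, and identical p's are printed for different tables), so the rate
column — which is exactly reproducible — is the package's reproduction
surface and p-values are reported under the documented conventions
without multiple-testing correction (none is part of the design; the
top-k cut is rank-based).

Ranking is ascending p, ties by descending rate, then descending external
gene score (an optional phenotype-relevance score table), then gene
symbol.

## Sequencing QC

FASTQ profiles (per-position mean Phred quality, base composition,
expected error rate 10^(−Q/10)) are computed over the reads covering each
position. The per-sample gates are inclusive: raw yield ≥ 6 Gb, Q30 base
fraction ≥ 0.80, mean target depth ≥ 50×, fraction of target bases at
≥ 10× of at least 0.90 ("6G" is read as gigabases of raw yield, the
standard exome usage). Gates are reported, not enforced — whether failing
samples are excluded is a cohort decision, not a library default.

## Synthetic data generator

The generator emulates the study's inputs so that every stage is testable
without sequencing data. Defaults are the study conditions: 111 extreme /
102 control samples; per-trait group means/SDs as published (TG 0.40
(0.04) vs 1.43 (0.13) mmol/L, etc.); male fractions 0.477/0.480; TG drawn
from normals truncated at the 0.45 mmol/L threshold per group (other
traits truncated at zero); 100 genes × 3 sites; three genes planted at
carrier probabilities 0.10 (extreme) vs 0.005 (control) with hom fraction
0.1; background carrier probability 0.01 identical in both groups (a
realistic rare-carrier background: ~1–2 carriers per group per gene);
per-call missingness 0.02, which reproduces per-gene table totals of
~209 out of 213 enrolled as in the published tables. Carriers receive
their genotype at one uniformly chosen site of the gene (published
per-gene SNV and carrier counts are nearly equal, supporting single-site
carriers; a flag enables multi-site carriers). Annotation fields are
drawn so that the fraction of sites passing the frequency caps converges
to `rare_fraction` and the fraction passing the deleteriousness gate to
`deleterious_fraction`.

Traits are independent truncated normals per group — only means and SDs
are published, so no covariance structure is modelled. Consequences: the
generator reproduces every published summary statistic but not the
correlations between lipid fractions, linkage disequilibrium between
sites, relatedness, or batch structure in missingness. Passing tests
therefore demonstrate the correctness of the statistical machinery and
the recoverability of planted enrichment under independence, not
robustness to those real-data features. Truncating the extreme-group TG
at the threshold shifts its expectation to 0.3918, slightly below the
nominal 0.40 — the exact truncated-normal mean is the oracle used in
tests.

Randomness: one root seed spawns child streams (0 = phenotypes,
1 = variants, 2 = genotypes), so each generator is independently
reproducible and equal (seed, config) gives byte-identical outputs.

## Numerical choices and degenerate inputs

- Rate truncation uses exact integer arithmetic
  (`(1000·k_e·n_c) // (k_c·n_e) / 1000`), never floating floor.
- Degenerate 2×2 tables (an empty margin) return p = 1.
- Zero-SD trait distributions generate the constant mean exactly.
- Ties in TG-ranked selection break by sample id; all sorts are stable,
  making every output deterministic for a given seed.
- Coordinates are 0-based half-open internally; VCF/TSV positions are
  1-based and converted at the I/O boundary. Multi-allelic VCF records
  are split into biallelic sites on read.

## Problem sizes used in the test and acceptance suites

Simulation-based checks use 200–500 replicate seeds at the study's group
sizes (108/101 effective, matching the published per-gene tables) with
100 genes × 3 sites for recovery checks and smaller gene panels for
distributional checks; the power Monte-Carlo uses 20,000 replicates.
These sizes give Monte-Carlo error well inside every asserted tolerance
(3-SE bands for means; ≥ 90% recovery over 200 seeds) while keeping the
full suite under a minute of simulation time.

## Known limitations

- The ratio-of-frequencies estimator is upward-biased (Jensen) when the
  control carrier count is small; the package reports it as the published
  convention does, with the exact test carrying inference.
- The matcher is greedy, not optimal; with a small or skewed control pool
  it can leave residual age imbalance.
- No multiple-testing correction and no covariate adjustment are applied
  at the burden stage (none are part of the design being implemented).
- Compound region categories are closed to the four published ones; other
  cross-gene conflicts resolve by precedence.
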