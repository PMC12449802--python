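# Methods

This note documents the models, defaults and numerical choices behind
magselect, and what the synthetic-cohort tests do and do not establish.

## Abundance model

Contig coverage is total aligned read nucleotides divided by contig length;
aligned nucleotides are counted from primary SAM alignments only, summing
CIGAR operations that consume both query and reference (M, =, X). Soft- and
hard-clipped bases, insertions and deletions are excluded, as are secondary
(0x100), supplementary (0x800) and unmapped records. Whether a given
upstream pipeline counted clipped bases or secondary alignments is generally
unknowable from its outputs, so the rule used here is fixed, documented, and
recorded implicitly by the implementation; both choices only rescale
coverages slightly and cancel in rank-based statistics.

Genome abundance defaults to the literal form `Σ coverage / Σ length` over
the genome's contigs. Dimensionally this is coverage per base pair, not mean
per-base coverage; the conventional length-weighted mean
`Σ coverage·length / Σ length` is exposed as `mode="weighted_mean"` because
the two differ whenever contig lengths differ. The default is kept at the
literal form for fidelity with MaxBin-style output; all downstream
statistics are either rank-based or ratio-based and are insensitive to which
convention is used consistently.

## Differential abundance

Group means are arithmetic means over included samples; `excluded` samples
(adenoma-type intermediate diagnoses) are dropped from every statistic. The
effect measure is `log2((d + ε)/(h + ε))` with ε = 1e-6 by default — small
relative to any observable coverage, so the statistic equals the plain
log-ratio whenever both means are positive, while staying finite for
all-zero genomes. ε is configurable.

Significance uses a two-sided Mann–Whitney rank-sum test (exact enumeration
when both groups have ≤ 8 samples, otherwise the normal approximation with
tie correction), or a seeded permutation test of |difference of group means|
with p = (1 + #{permuted ≥ observed}) / (1 + B). Both are assumption-light
choices appropriate for continuous coverage values; a count-model (TMM /
negative-binomial) stack is deliberately not used, since coverages are not
counts, and every written report carries a header noting the substitution.
Genomes constant across all included samples get p = 1 and a `degenerate`
flag. In the permutation test the permuted statistic always assigns the
smaller group first from a canonically ordered sample axis, which makes
p-values exactly invariant under a disease/healthy label swap with the same
seed. FDR is Benjamini–Hochberg (statsmodels step-up). The `significant`
flag uses raw p ≤ 0.05 — the scatter-plot highlight convention — not FDR.

## Importance and selection

Importance is the classical mean decrease accuracy: a 1,000-tree random
forest (sqrt-feature subsampling, unlimited depth, bootstrap, seeded) is fit
once on the full matrix, then for every tree the accuracy on its out-of-bag
samples is compared with the accuracy after shuffling one genome's column
among those samples (10 seeded shuffles per tree × genome by default), and
the decreases are averaged. Scoring on out-of-bag rather than training
samples is essential, not cosmetic: a many-tree forest interpolates its
training data, so training-set permutation importance degenerates to zero
for every feature once a handful of informative columns back each other up.
Impurity (Gini) importance — the default of common toolkits — is available
as `mode="impurity"`. Ties in the ranking break by ascending genome id for
determinism.

Subsets are evaluated by stratified k-fold CV (k = 10, lowered to the
minority-class count when necessary, logged), repeated 3× with reshuffled
folds; each repeat's held-out class-probability scores are pooled into one
AUROC (pooling avoids degenerate per-fold AUROCs at small fold sizes; a
per-fold mean would be the alternative), and repeats are averaged. CV
forests default to 500 trees (200 in the heavy planted-cohort checks): the
1,000-tree setting is reserved for importance extraction, while CV cost
scales with subsets × folds × repeats and tree count there is a
cost/variance trade-off. AUROC itself is the Mann–Whitney probability that
a random positive outranks a random negative with half credit for ties.
The best subset is the smallest prefix attaining the maximal mean AUROC
(parsimony tie-break). Ablations reuse the identical CV seeding, so an
empty exclusion reproduces the best AUROC exactly and differences are
attributable to the removed genomes, not to fold noise.

Importance is extracted from the full data set before cross-validation, so
the reported CV AUROC of a given subset is optimistically biased as an
estimate of out-of-sample performance (the ranking has seen the test folds).
This matches the two-step design being emulated; the package's claims are
therefore comparative (curve shapes, ablation deltas), not absolute
generalization estimates.

## Filters and summaries

MIMAG medium quality: completeness ≥ 50 (inclusive — "at least"), 
contamination < 10 (exclusive, the MIMAG medium convention). Uncultivated
flag: ANI absent by default (`absent_only`); the `below_threshold` rule also
flags reported ANI < 95%, the classifier's species-confidence floor.

Cohort mean abundance is the grand mean over all matrix cells of included
samples (one scalar per cohort); a per-genome mean-of-means variant is
available. A selected genome is "low abundance" iff its own mean abundance
is strictly below that grand mean. Species identity for cross-cohort Venn
counts is full 7-rank taxonomy-string equality; empty ranks bucket to
"Unclassified" in distributions.

## Synthetic cohorts

The generator emulates the statistical shape of a co-assembled case/control
gut cohort, not its sequences: per-genome baselines μ_G are log-normal
(log-mean −0.5, log-sd 1.5, giving a grand mean near 1.87×, the scale of
real cohort means ~1.4–1.9×); a fraction of genomes (default 5%) carry a
planted effect, the disease mean being μ_G·2^(±effect) with the sign
randomized so both disease- and healthy-enriched genomes occur; planted
genomes are drawn from the below-median-baseline stratum with probability
`low_abundance_bias` (default 0.9), reproducing the concentration of high
fold-of-change at low abundance; per-sample values are gamma with the group
mean and squared coefficient of variation `noise_dispersion`. Defaults for
group sizes (74/54) and the uncultivated fraction (39/351) follow the larger
real cohort.

`noise_dispersion` defaults to 2.0. Gut species abundances across hosts are
strongly overdispersed (squared CV of order 1–3; overdispersion is the
reason count-model packages exist for such data), and this value makes a
planted 4-fold effect individually informative (per-genome AUROC ≈ 0.7) but
individually insufficient, so high classification accuracy requires
combining on the order of tens of genomes — the regime the method is for.
At low dispersion (e.g. 0.2, used in the fold-change-recovery test where it
is explicitly part of that check) a single planted genome nearly separates
the classes and the selection problem is trivial.

The generator uses a median split of baselines to define its low-abundance
stratum (balanced by construction); the reporting side uses the grand-mean
threshold described above. Gamma noise on a log-normal baseline was chosen
over negative-binomial counts because the data being emulated are continuous
coverages. The generator does not simulate read sampling, assembly or
binning error, compositional coupling between genomes, or inter-genome
correlation; a green planted-recovery test therefore establishes that the
statistics and the selection machinery recover known structure under
realistic marginal noise — not that they are robust to assembly artifacts or
compositionality.

## Reproducibility

All randomness flows from explicit seeds. The pipeline derives per-stage
seeds as the first 4 bytes of SHA-256("<master-seed>:<stage>") mod 2^31, so
any stage can be rerun in isolation and reproduce the full run. Manifests
record config, derived seeds, library versions and per-output SHA-256
checksums; two runs with the same config and seed are byte-identical
(forests run single-threaded — parallel scoring would not change results
but keeps timing honest on one CPU).

## Known limitations

- No TMM or compositional (CLR) normalization; abundances are treated as
  given.
- No alternative learners and no nested CV for hyperparameter tuning.
- The CV AUROC of the selected subset is biased upward as a generalization
  estimate (see above).
- `read_genome_tables` joins on genome id and silently (but loggedly) drops
  one-sided genomes; sample ids in the matrix without metadata are a hard
  error instead, since silent sample loss would bias group means.
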