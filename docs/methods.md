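# Methods

## The collapsing model

`rarebin` tests whether *groups of rare variants* — rather than single
markers — differ in aggregate burden between two phenotype groups.  The
unit of analysis is the **bin**: a biologically defined set of loci
whose rare alleles are summed per individual.

**Rarity.** At each locus the minor allele frequency (MAF) is the
frequency of the *second most frequent* allele, computed separately in
the case and the control group from observed (non-missing) alleles.  A
locus is rare when MAF < *t* (strict) in **either** group; the
threshold *t* is configurable (0.02–0.10 are typical choices).  All
non-major alleles of a rare locus are binned identically; a
polyallelic locus contributes every non-major allele, and when both
groups trigger, each group's non-major alleles are pooled.  Judging
rarity per group keeps loci that are fixed in one population but
polymorphic in the other inside the analysis — those loci carry most of
the signal in population-contrast runs — while loci common in both
groups are discarded entirely.

Two boundary rules matter in practice and are fixed here: the rarity
inequality is strict (MAF = *t* is not binned), and an exact 50/50 tie
for the major allele is broken lexicographically (logged at debug
level).  Alleles observed in neither group are never binned, which
excludes loci monomorphic in the whole sample.

**Bins.** Bin boundaries come from a local knowledge store of *regions*
(labelled `[start, stop]` segments: genes, exons, conserved elements)
and *groups* (sets of regions: pathways), held in a single SQLite file
with 1-based inclusive coordinates (BED input is converted on load).
Three feature types are built:

* *gene bins* — one per gene region containing ≥ 1 rare locus
  (containment is inclusive on both ends; overlapping genes each claim
  the locus — bins are deliberately not independent);
* *pathway bins* — the deduplicated union of the member genes' rare
  loci;
* *intergenic bins* — fixed, non-overlapping windows (default 50 kb)
  tiling each chromosome from position 1, emitted only for rare loci
  assigned to **no** requested gene/pathway bin.  Window k covers
  `[kW+1, (k+1)W]` and is named `chrom:window_k` with the 0-based
  index.  Feature selection fully drives assignment: in a run without
  the gene feature, a genic locus falls to its window.

Bins can be refined before testing: exon/intron splitting (a locus is
exonic iff inside any exon of a gene containing it; intergenic bins
pass through unchanged since they have no parent gene) and
functional-prediction splitting (one bin per category; loci without a
prediction record are dropped from the analysis, mirroring how
prediction filters behave).

**Burden.** Entry (bin, sample) is the additive count of binned alleles
across the bin's loci — 0, 1 or 2 per diploid locus; missing alleles
contribute 0.  Dominant/recessive encodings are out of scope.

## Statistical testing

The bin matrix is the product; the bundled analysis layer is one
reasonable choice, not the only one.  Each bin is tested with a
two-sided Wilcoxon 2-sample rank-sum test (two-sided because a bin can
accumulate risk **or** protective variants).  Burdens are small
integers, so ties dominate; the implementation uses midranks with

* exact enumeration of the permutation distribution of the rank sum
  when min(n₁, n₂) ≤ 8 and at most 2·10⁵ arrangements (valid under
  ties), two-sided p = Pr(|W − μ| ≥ |w − μ|);
* otherwise the tie-corrected normal approximation with continuity
  correction — numerically identical to R's default `wilcox.test`
  (cross-checked in the suite to 1e-9).

The approximation is accurate to ~0.01 in the decision-relevant tail
(permutation p ≤ 0.1); in the mid-range, heavy ties make the two-sided
normal p deviate from the permutation p by up to ~0.07 — an inherent
property of the classical recipe, characterized empirically in the test
suite, and irrelevant to rejection decisions at conventional levels.
Zero-variance bins are reported with p = 1 (flagged degenerate) rather
than dropped, so the multiple-testing count m stays interpretable.
Multiple testing is plain Bonferroni with m = bins tested in the
current run; results are ranked by ascending unadjusted p with bin-id
tie-breaks for determinism.

## The simulation harness

The evaluation harness measures the type I error and power of the
single-bin Wilcoxon test on simulated rare-variant regions.

**Region simulator.** A forward-time Wright–Fisher haplotype-pool model
of a 5 kb region, no recombination, infinite-sites mutation at
1.8 × 10⁻⁸ per nucleotide per generation.  The demographic history is
three epochs with exponential within-epoch size interpolation:
Ne 8100 for 5000 generations, a 10-generation shift to 7900, then a
370-generation expansion to 900 000 — a bottleneck-plus-explosive-growth
history that piles up an excess of very rare alleles the way human
resequencing data does.  (The published form of this schedule lists
four sizes against three durations; the epoch reading adopted here is
recorded in every pool's metadata.)  Purifying selection is genic
(multiplicative across a haplotype) with per-mutation coefficients from
a gamma distribution of deleterious effects, shape 0.206, mean 0.043 —
a Kryukov-style missense model.

Simulating Ne = 900 000 forward in time is not a desk job, so the
standard rescaling is built in: sizes and durations divide by λ while
mutation rate and selection coefficients multiply by λ, preserving
θ = 4Nμ and Ns.  The harness, CLI and acceptance script use λ = 100;
the unscaled path (λ = 1) remains available.  Rescaling preserves
pairwise diversity (verified against the neutral 4NμL expectation in
the suite) but *not* the count of ultra-rare segregating sites seen by
a large sample — a scaled pool holds ~200 sites where a full-scale run
would hold ~1000 — so sample-size-dependent quantities carry the
scaled-down caveat.  A scaling that pushes any epoch below 50 diploids
is rejected as degenerate.

**Phenotype model.** Case/control status is assigned by a logistic
model whose log-odds are additive in per-site derived-allele counts:
odds ratio 2.5 per detrimental allele, 0.9 per protective allele,
baseline prevalence 0.5 at the mean genetic score (balanced
ascertainment), with rejection sampling until the per-group quotas are
met.  Under the null (both odds ratios 1.0) labels are a balanced
random permutation, independent of genotype.  Which sites are causal is
not identifiable from first principles; the defaults — every
segregating site causal, detrimental with probability 0.9 — encode a
deleterious-dominated effect architecture consistent with the Kryukov
selection model, and place a balanced 250–2000-sample design in the
classical operating regime for these odds ratios (power climbing from
roughly one-half to near one).  Both knobs are recorded in study
metadata and freely configurable.

**Study design.** A study simulates a set of haplotype pools (default
100; each replicate rotates over them, so pool-level heterogeneity is
averaged — with ~25 pools the power estimate at n = 500 still varied by
±0.08 between pool sets, with 100 it is stable to ~0.01), draws a
balanced cohort per replicate, bins the whole region as one bin at the
MAF threshold (default 0.05), and reports the fraction of replicates
with p ≤ 0.05.  Per-component random streams (pool simulation, effect
assignment, per-replicate sampling) are spawned from one seed, so
phenotype re-randomization on a fixed pool set is reproducible.

**Spike-in.** A fully penetrant synthetic variant — heterozygous in
every case, homozygous reference in every control, adding exactly
(number of cases) variants — probes signal recovery as a function of
bin size: in an 87-sample cohort the spike dominates a bin of ≤ 20 loci
(rank 1, Bonferroni-significant) but drowns among ≥ 300 background rare
variants.

**Toy fixtures.** The toy generator writes a self-consistent
VCF/phenotype/region-table/GMT quartet in which every locus's per-group
allele counts are placed exactly, so rarity at the generation threshold
is known by construction and expected bins are derivable without
running the engine.  It emulates the file plumbing and the rarity
boundary conditions, not population genetics: genotypes are placed
count-exactly rather than drawn from any evolutionary model, there is
no linkage, no missingness beyond what a test injects, and gene
coordinates are regular.  Passing the round-trip tests therefore
demonstrates correctness of the pipeline's bookkeeping, not robustness
to the messiness of real cohorts (batch effects, relatedness,
population structure, genotyping error are all out of scope).

## Numerical and design choices

* Frequencies use observed-allele denominators; each group's record
  includes every allele of the locus (zeros for alleles the group does
  not carry), which is what lets fixed-in-one-group loci be binned.
* Multiallelic VCF records are never split; phasing is ignored.
* The Monte-Carlo problem sizes used by the acceptance script — 150
  pools at λ = 100, 3000 null replicates, 800 power replicates — were
  chosen so that Monte-Carlo spread is small against the quantities'
  own scale (binomial SE ≤ ~0.008 for power, ≤ ~0.004 for the null
  rate).
* All primary outputs are byte-deterministic for fixed inputs and
  seeds; headers carry no timestamps.

## Known limitations

* No covariate adjustment, regression testing, or population-structure
  correction: the bin matrix is designed to feed such analyses, not to
  replace them.
* The rank-sum test loses power when bins are large and noisy — the
  spike-in experiment quantifies exactly this — and its mid-range
  p-values are approximate under heavy ties (see above).
* The haplotype-pool simulator has no recombination and genic (not
  diploid) selection; rescaling trades away the ultra-rare tail of the
  site-frequency spectrum.
* Knowledge input is loader-driven (region tables and GMT files);
  there are no downloaders for public annotation feeds and no
  build-to-build liftover.  Conflicting gene boundaries across sources
  are stored independently per source, not reconciled.
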