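# Methods

## The estimation problem

A founder cohort is a single sampled generation: no parent is
genotyped, and the only information about relatedness is the realised
genomic relationship matrix (GRM). Two features make this harder than
it looks. First, VanRaden's GRM is centred on allele-frequency
estimates, and when a few large sib families dominate a sample, the
observed frequencies are pulled toward those families; the resulting
mis-centring systematically shrinks the apparent relationship inside
large families (a family of k sibs contributes k correlated copies of
its parents' alleles to the frequency estimate). Second, frequency
estimates from a *small* unrelated subset carry sampling noise whose
effect on the GRM is not symmetric: for two individuals outside the
frequency sample the shared centring error inflates every relationship
by roughly 1/m, where m is the subset size. The pipeline therefore
alternates between sibship assignment and frequency re-estimation, and
its reliability depends on the number of unrelated founders available
— and wild-sourced founder collections can yield only a few dozen
fish per river with no parents in common.

## Genomic and pedigree relationships

The GRM is VanRaden method 1, `G = ZZᵀ / (2Σpⱼqⱼ)` with `Z = M − 2P`.
Missing calls are imputed by the genotype-dosage mean `2pⱼ`, so an
imputed cell contributes zero to `Z`; with a fraction µ of missing
calls this attenuates off-diagonal expectations by ≈ (1 − µ)². At the
default study conditions (≲2% missingness on QC-surviving markers) the
attenuation is below 5% and immaterial to the 0.375/0.125 decision
boundaries.

The pedigree numerator relationship matrix `A` uses the tabular
method processed in parents-first order; unknown parents contribute
zero and the diagonal is `1 + a(sire, dam)/2`. For the one-generation
dummy-parent pedigrees built here its off-diagonal entries are exactly
{0, 0.25, 0.5}.

## Sibship assignment

Thresholds formalise "approximately 0.5 / approximately 0.25" as
midpoint cut-offs: full-sib at relationship ≥ 0.375, half-sib for
between-group means in [0.125, 0.375). Both are configurable
(`PipelineConfig`).

Grouping uses average-linkage agglomeration cut at the full-sib
threshold rather than connected components of the thresholded graph.
The block structure a clustered heatmap shows is average-level
structure, and the two rules differ exactly where it matters: two true
half-sib families of sizes 10 and 12 expose 120 between-family pairs
whose true mean is 0.25; under pair-level thresholding a single noisy
pair crossing 0.375 merges the families, and the chance of at least
one such crossing is non-negligible at realistic marker counts.
Average linkage requires the *mean* between-cluster relationship to
cross the threshold, which concentrates as family sizes grow. A
cohesion audit still logs any accepted group whose internal mean
relationship falls below 0.4.

Half-sib links are reduced to a realisable parent-sharing structure:
each group owns two parent slots; candidate links are processed by
closeness of their mean relationship to 0.25, joining an existing
shared parent only when every induced group pair is itself a
candidate, otherwise opening a fresh shared parent while slots remain;
an overflowing link is dropped with a warning. "Sire" and "dam" in the
emitted pedigree are positional slots, not sexes.

## The unrelated set and the de-biasing loop

The maximal unrelated set is built greedily from `A`: first every
individual with zero relationship to all others; then repeatedly the
remaining individual with the lowest mean off-diagonal relationship
(ties to input order), removing it and all its relatives. The output
is an independent set in the relatedness graph and is maximal; both
properties are cheap (O(n²)) and re-checked in the test suite by
exhaustive verification on random sibship pedigrees.

One refinement pass (unrelated set → frequencies → GRM → sibship) is
not always enough: when the first-pass assignment shatters a large
family, the "unrelated" set still contains several sibs and the
rebuilt GRM remains partially biased. The pipeline therefore iterates
the pass until the assignment reaches a fixed point, capped at
`max_refine_passes = 4`; on the default synthetic conditions the fixed
point is reached within three passes and re-running the pipeline with
a higher cap changes nothing (idempotence is tested).

## Quality control details

* Marker filter: retention is inclusive at both boundaries (missing
  rate ≤ 0.05, MAF ≥ 0.05), MAF computed over all non-missing calls.
* Fragment dedup: one uniformly chosen SNP per fragment, seeded; the
  survivor count equals the number of distinct fragments regardless of
  seed.
* LD pruning: r² is the squared Pearson correlation of allele counts
  over pairwise-complete individuals. Undefined r² (monomorphic after
  subsetting, or < 2 complete pairs) imposes no constraint. Because
  pairwise-complete correlations do not change when a third SNP is
  removed, the matrix is computed once and masked as SNPs drop out.
  Ties at the maximum resolve to the lexicographically smallest index
  pair; the removed member of the pair is a seeded uniform choice.
* HWE: classical 1-df χ² per SNP × population with expected counts
  from the same sample's allele frequency, no continuity correction,
  run on the preliminary unrelated subsets so that sib structure is
  not read as disequilibrium. The Dunn–Šidák family size m counts the
  tests actually performed (monomorphic combinations are skipped, as
  they carry no evidence); m can be fixed explicitly via `n_tests`.

## Population-genetic summaries

* Heterozygosity: H_exp = 2p̂(1 − p̂) without small-sample correction
  by default (the n/(n−1) factor is available); paired t across SNPs
  compares H_obs with H_exp within a population; between-population
  differences in mean H_exp use a permutation test with the add-one
  p-value convention (1 + exceedances)/(1 + n_sim).
* F_ST: Weir & Cockerham (1984) per-locus variance components a, b, c
  combined as θ = Σa / Σ(a+b+c) over loci with defined components;
  the 95% CI is percentile-based over 2000 resamples of loci with
  replacement. The per-locus components are verified in the tests
  against an independent scalar transliteration of the published
  formulas and by parameter recovery on Balding–Nichols simulations.
* AMOVA: two levels (among populations / among individuals within),
  within-individual variance not partitioned. Distances are
  allele-count Hamming distances over pairwise-complete loci rescaled
  by the number of loci used; SNPs above the 10% missing cut-off are
  dropped first. Significance permutes individuals across populations.
* Rarefaction: expected distinct alleles in a sample of q gene copies
  per locus, `Σₐ (1 − C(N−Nₐ, q)/C(N, q))`, with private richness the
  expected count of alleles present in one population's rarefied
  sample and absent from all others'; binomial coefficients are
  evaluated through log-gamma for stability. `max_g` must not exceed
  any population's smallest per-locus gene count.
* Cluster scan: genotypes mean-imputed and centred, all positive-
  variance principal components retained by default, K-means for
  K = 1..20 scored by `BIC(K) = n·ln(WSS/n) + K·ln(n)`; K values that
  reach WSS = 0 are excluded. The default number of K-means restarts
  is 20; the analysis that motivated this scan used many more, and the
  parameter is exposed (`n_starts`) — on the low-dimensional projections
  involved the optimum is insensitive to restarts well below that.

## The synthetic-data generator

The generator emulates the sampling design end to end: ancestral MAFs
Uniform(maf_low, maf_high) with random polarity; population
frequencies Balding–Nichols (Beta with parameter F, the expected
Wright F_ST — chosen because only a differentiation *level*, not a
demographic history, is specified); founder genotypes binomial(2, p)
(HWE); offspring by Mendelian gene drop of one uniformly chosen allele
per parent; loci unlinked. Genotyping error perturbs a call to a
uniformly chosen different count. Missingness defaults to a *bimodal*
per-marker profile — 15% of markers carry most of the missingness,
the rest sit well under the QC threshold — reflecting the strongly
marker-clustered call rates of reduced-representation platforms; a
uniform per-call profile is available (`missing_profile="uniform"`).
Under a uniform profile with mean equal to the QC threshold, the
missingness filter becomes a coin flip on binomial noise and discards
~40% of markers to no informational end, which is not how these
panels behave.

The default scenario (`default_config`) is a half-scale replica of a
three-river founder collection: one river of mostly singletons
(50 singletons + families of 4 and 3), two rivers dominated by a few
large families (16 singletons + families 12/10/8/6/5 with one half-sib
link; 16 singletons + 14/12/10/8 with one link); 3000 raw SNPs with a
low-MAF tail (maf_low = 0.02), F = 0.01 between rivers, 5% missing
calls, 0.1% genotyping error, 15% of fragments carrying two SNPs.
Family sizes are chosen, not inferred — the emulated study does not
report them — and the singleton counts put the per-river unrelated
sets (~20–52) in the few-dozen regime of real founder collections,
where frequency re-estimation from the unrelated set is informative
rather than noise-dominated.

What the generator does **not** emulate: linkage (fragment-mates are
labelled but statistically independent, so LD pruning is exercised by
family-structure-induced correlation only), null alleles and
allelic-dropout error structure, multi-generation pedigrees, selection
and non-equilibrium demography. Passing tests therefore demonstrate
the pipeline's behaviour under idealised Mendelian data at realistic
scale, not robustness to every DArT artefact.

## Numerical and degenerate-input choices

* Missing sentinel is a flag value (−9) never included in arithmetic;
  all statistics go through explicit masks.
* G symmetrised by averaging with its transpose to kill float drift;
  construction refuses an all-monomorphic frequency vector.
* Ward/average clustering uses the dissimilarity `max(G) − g`, which
  preserves ranking and needs no PSD repair; single-individual
  populations skip clustering.
* Permutation and bootstrap p-values/CIs never return 0 by
  construction (add-one convention; percentile CI).
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical configuration implies
  bit-identical output (tested).

## Known limitations

* Threshold sibship assignment degrades when marker counts drop below
  a few hundred post-QC SNPs or unrelated sets shrink below ~10: the
  1/m centring inflation then approaches the half-sib decision band.
  The pipeline warns when the unrelated set is smaller than
  `min_unrelated`.
* Half-sib links between singleton pairs rest on a single relationship
  value and are the least reliable call the assigner makes.
* Avuncular or grandparental relationships (also ≈ 0.25) are
  indistinguishable from half-sibship in a single-generation sample;
  the dummy-parent encoding would mis-specify them.
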