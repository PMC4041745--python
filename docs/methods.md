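# Methods

## The consensus enrichment procedure

The pipeline tests whether genes harbouring modest allelic associations
cluster in functional categories.  It deliberately does **not** combine
p-values across SNPs or tools; instead it applies a conservative
*consistency* filter that mimics how practitioners reconcile discordant
enrichment web tools:

1. SNPs are assigned to genes under two window schemes.  With flank width
   *w* (kb), SNP *s* (1-based position `pos`) maps to gene *g* iff
   `start(g) − 1000·w ≤ pos−1 < end(g) + 1000·w` on the same chromosome.
   Gene intervals are BED-native (0-based, half-open); SNP positions are
   PLINK-native (1-based) and converted at exactly this comparison.  A SNP
   in two overlapping windows counts for both genes: the subsequent
   best-SNP collapse makes double assignment harmless, and no principled
   exclusivity rule exists without LD information.
2. Each mapped gene is scored by its minimum SNP p-value (ties broken by
   smaller position, then SNP id — purely for determinism).  Gene lists
   take every gene with `best_p < τ` (strict inequality, matching the
   `<0.01`-style convention of published count tables), for the τ grid
   {0.01, 0.005} × windows {0, 20 kb} by default — four lists.
3. Each list is scored against each gene-set collection by ORA.  All
   counts (query size n, category size K, overlap k) are taken after
   intersection with the background universe — here, all genes of the
   supplied gene-model file, the pipeline's certifiable proxy for a
   whole-genome background.  Collections supplied as separate GMT files
   are corrected separately, mirroring tools that treat GO and KEGG as
   independent databases; the correction family m is every category with
   K ≥ 1 in the background.
4. A method profile *supports* a category if it flags it enriched
   (adjusted p < α **and** k ≥ 2 query genes) in **every** required list.
   A category is consistently enriched when ≥ `min_methods` (default 2)
   profiles support it.  Both filters are anti-monotone in their
   parameters, which the tests enforce.

## Method profiles

The behavioural spread of published enrichment tools — different
statistics, corrections and practical thresholds — is represented by four
named profiles rather than wrapped web services (offline, reproducible,
and the consensus logic only needs independent verdicts):

| profile      | statistic      | correction | α     |
|--------------|----------------|-----------|-------|
| default-0.05 | hypergeometric | BH        | 0.05  |
| mid-0.01     | chi-square     | BH        | 0.01  |
| strict-1e4   | binomial       | none      | 1e-4  |
| strict-1e6   | hypergeometric | none      | 1e-6  |

The two "strict" profiles model high-output tools that are used in
practice with raw-p working cutoffs of 1e-4/1e-6; the other two model
adjusted-p tools at 0.05 and 0.01.  These are an *emulation* of tool
diversity, not a reconstruction of any specific tool's internals.
Profiles are frozen dataclasses; ad-hoc profiles can be given on the CLI
as `statistic:correction:alpha`.

## Statistics

* Hypergeometric tail `P(X ≥ k)` via `scipy.stats.hypergeom.sf` —
  verified in the test suite against exhaustive enumeration of all draws
  for every universe up to N = 12 and against one-sided Fisher exact
  p-values to 12 significant digits, including the 1e-6 regime.
* Binomial tail `P(Bin(n, K/N) ≥ k)` via `scipy.stats.binom.sf`.
* One-sided 2×2 chi-square: p = 1 whenever k is at or below its expected
  count n·K/N (under-representation never scores) or any cell expectation
  is zero (untestable category, logged); optional Yates correction.
* Corrections (BH step-up, Holm, Bonferroni) via
  `statsmodels.stats.multitest.multipletests`, tested element-wise against
  independently coded sorted-formula oracles.
* The simulator's allelic test is the Pearson 1-df chi-square on the 2×2
  allele-count table without continuity correction (the standard "allelic"
  model); a Yates variant exists behind a flag.  Monomorphic markers
  return p = 1.

## The synthetic study

`SimulationSpec` defaults define the reference condition used by the test
suite and the acceptance script:

* **369 cases vs 369 controls** — the two-group survival contrast the
  pipeline is designed around.
* **2,000 genes**, mean length 15 kb, mean intergenic gap 30 kb
  (geometric draws; the exact length law is immaterial downstream), 100
  genes per chromosome.  This geometry makes the ±20 kb flank meaningful —
  it frequently captures intergenic SNPs and occasionally a neighbouring
  gene — without letting every window swallow many genes; the flank scale
  matches typical European haplotype-block lengths (≈6–16 kb).
* **~3 SNPs per gene body** (Poisson) plus an equal number of intergenic
  SNPs, so roughly half of all SNPs fall outside gene bodies, as in real
  tagging-SNP panels.
* **MAF ~ U(0.05, 0.5)**; the 0.05 floor mirrors the usual MAF ≥ 5%
  marker QC filter.  Alleles are drawn independently (HWE holds by
  construction), so genotype-level QC is not modelled.
* **Planted signal**: θ = 1.8 per-allele odds ratio on one causal SNP in
  each of a random half (`causal_gene_frac = 0.5`) of a 25-gene set, the
  weakest condition that the default pipeline still recovers reliably at
  this sample size; θ = 1 gives an exact null.

What the generator does **not** emulate: linkage disequilibrium between
SNPs (each SNP is independent), population structure, covariates,
genotyping error, or survival-time modelling.  Passing tests therefore
demonstrate the pipeline's statistical correctness and its power under
idealized independence — not robustness to LD-induced SNP clustering,
which in real data is partly absorbed by the best-SNP-per-gene collapse.

All randomness flows from a single spec-level seed through decoupled
stage streams, so an identical spec yields byte-identical association
files; output floats are written with 17 significant digits so write/read
round-trips are exact.

## Problem sizes and numerical choices

The acceptance script uses a ~20,000-SNP null scan for calibration
(rejection rate at α = 0.05, binomial Monte-Carlo error ≈ 0.0015) and ten
replicate pipeline runs per condition for the recovery rates; the test
suite uses twenty seeds.  These sizes give comfortable statistical margins
while keeping a full run in seconds on one core.  Degenerate inputs are
defined explicitly: empty enriched set in any required list empties a
method's consistent set; a zero-size category under restriction reports an
*undefined* (NaN) overlap percentage, never 0; k = 0 tails are exactly 1.

## Known limitations

* The consensus criterion compares category identities only; a concept
  appearing under different ids in two collections is never merged.
* The background universe is the supplied gene-model file, not a
  transcriptome-aware universe per tool.
* Method profiles share the same input gene lists; real web tools also
  differ in identifier mapping and annotation versions, a source of
  divergence this package intentionally removes.
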