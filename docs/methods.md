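# Methods

`eqtlscan` implements a whole-blood-style expression quantitative trait locus
(eQTL) analysis as a reusable pipeline, together with a synthetic cohort
generator that plants a known truth so every stage can be validated without
access to real cohort data.  This note records the statistical model, the
simulator's assumptions, the numerical choices, and the design decisions that
were genuinely open.

## The association model

For every SNP–probe pair the pipeline fits the simple additive model

    y_i = alpha + beta * g_i + e_i,

where `y_i` is the (residualized) expression of a probe in individual `i` and
`g_i in {0, 1, 2}` counts copies of the ALT allele.  The ALT allele is always
the reported effect allele; dosage recoding `g -> 2 - g` flips the sign of
`beta` and nothing else, and all direction-consistency accounting is
allele-aware, so the choice of counted allele is harmless as long as it is
recorded.  Estimation is ordinary least squares on pairwise-complete cases
(missing genotype calls are dropped per pair, which is why the per-pair `n`
varies across results); the test is the two-sided t test of `beta = 0` on
`n - 2` degrees of freedom.

Two independent code paths produce these numbers: `regress_single` delegates
to `scipy.stats.linregress`, while `scan`/`pairwise_stats` is a vectorized
closed-form implementation (central co-moments accumulated by matrix
products, with a masked path for missing data).  The two routes are compared
against each other — and against `statsmodels` OLS in the tests — and must
agree to 1e-8 relative; in practice they agree to ~1e-14.

Numerical choices: p-values are floored at 1e-300 and floored values carry a
flag; zero residual variance (a perfect fit) and constant dosages are flagged
degenerate and excluded from calling; ties in lead-SNP selection break by
smaller position, then lexicographic SNP id.

## cis/trans definition and multiple testing

A pair is *cis* when the SNP lies within 500 kb of the transcription unit:
`tx_start - 500000 <= pos <= tx_end + 500000`, inclusive at both boundaries
(the window is clamped at zero near chromosome starts).  The boundary is
inclusive by design; an off-by-one at exactly 500 kb is not observable
against any published count, so the convention is fixed and documented here.
All coordinates are 0-based half-open internally (BED native; VCF positions
convert on read).

Significance is family-wise Bonferroni: `alpha / n_tests` with `alpha = 0.05`
and `n_tests` the number of *enumerated* cis pairs (respectively trans
tests).  The engine always computes its own exact denominator and carries
thresholds at full precision; rounding to three significant figures happens
only at display time.  With the canonical whole-blood test counts this
reproduces the familiar values: `0.05 / 8,308,176 = 6.02e-9` for cis, and
replication thresholds `0.05 / 4,116 = 1.21e-5`, `0.05 / 161 = 3.1e-4`.

## Expression confounder correction

Latent structure (batch, cell-type composition, environment) is removed by
principal-component residualization.  PCs are computed on the
probe-standardized matrix via SVD; component signs are fixed by making the
largest-magnitude probe loading positive, so the decomposition is
deterministic.  `residualize` centers the input by its own column means and
projects the component scores out without rescaling — this keeps the
operation idempotent and leaves effect sizes on the original expression
scale.

The number of PCs to remove is a config value (defaults: 55 for cis scans,
25 for trans, 50 for cis replication).  No objective selection rule is
imposed: `pc_sweep` emits, for each k in {0, 5, 10, ..., 100}, the mean
standard error, mean |beta| and the significant cis/trans counts, and the
analyst chooses k from that table.  At replication time, PCs that are
themselves associated with the SNP under test (nominal p < 0.05 by default;
no multiplicity correction, since the per-SNP family is small and erring
toward exclusion only costs a few residual degrees of freedom) are excluded
from the residualization so that genuine trans signal absorbed by a PC is
not regressed away.

## SNP quality control

Inclusion requires, with strict inequalities, minor allele frequency > 5%
(computed on non-missing calls), call rate > 95%, and an exact
Hardy-Weinberg equilibrium test p > 1e-6.  The HWE test is the conditional
exact test: given the allele counts, the probability of each possible
heterozygote count is evaluated (log-gamma arithmetic), and the p-value sums
the probabilities of all configurations no more probable than the observed
one (a 1e-10 relative guard protects ties against floating-point noise).
The exact test rather than chi-square is used because it is the QC standard
and remains well defined at low counts; the tests verify it against an
exact-integer enumeration oracle for every genotype configuration with
total ≤ 50.  X-chromosome SNPs receive no special treatment: all SNPs are
handled autosomally, and sample-level QC is out of scope.

## Calling, LD pruning and locus clumping

cis: all enumerated pairs with p ≤ threshold are retained; per probe the
smallest-p SNP is flagged lead.  trans: pairs at p ≤ threshold go through two
steps.  First, any trans SNP with r² > 0.5 to a significant cis SNP is
dropped (its trans signal is plausibly a shadow of the cis effect).  Second,
the remaining SNPs are greedily clumped into loci by ascending best p: a SNP
joins the existing locus whose lead it exceeds r² 0.5 with (highest r² wins
when several qualify), otherwise it founds a new locus.  "High LD" is
interpreted as r² > 0.5 — not |r| — because r² is the convention for pruning;
the threshold is configurable.  LD is composite: the squared Pearson
correlation of dosage vectors on complete cases.  Invariants enforced by
tests: retained trans SNPs have no r² > 0.5 with significant cis SNPs,
members exceed r² 0.5 with their locus lead, and locus leads are pairwise
r² ≤ 0.5.

Discovery totals count cis as SNP-probe calls and trans as loci
(`total = n_cis + n_trans_loci`), with companion counts of distinct genes,
multi-probe genes and gene-unassigned calls.

## Replication

Each discovery call is re-tested per cohort at the per-class Bonferroni
threshold `alpha / n_discovered` (the denominator is discovered SNP-probe
associations, not loci).  When the discovery SNP is missing from a cohort, a
proxy is substituted: the highest-r² SNP within 500 kb at r² ≥ 0.8, with r²
taken from the discovery genotypes acting as the reference panel.  The 0.8
floor is a design choice (configurable): lower proxies change the tested
signal too much to count as the same association.  Effect directions are
harmonized for ref/alt swaps between cohorts and for the sign of the
proxy-index correlation before consistency is scored; consistency is defined
only for records that passed.  Headline percentages count cis at the
SNP-probe level and trans at the locus level (a locus replicates when any
member association replicates), replicated means passed in at least one
cohort, and all percentages are recomputed from raw counts and rounded half
away from zero to integers.

## Downstream analyses

*Master regulatory loci*: confirmed trans loci associated with five or more
distinct target genes (probe ids stand in where no gene is assigned); loci
with two or more targets are reported separately.  *Cross-study gene
overlap*: `round(100 * shared / denominator)` where `shared` is the number of
genes significant in both studies and the denominator is this study's
significant cis gene count.  Published comparison tables computed with this
formula are not always internally consistent for small compared studies
(e.g. a shared count of 171 over 3,449 cannot print as 68%); the operation
implements the stated formula and leaves such discrepancies to the reader.
*Triangles*: for a SNP, a transcript and a trait, the three marginal OLS
edges (transcript~SNP, trait~SNP, trait~transcript) are fitted on
pairwise-complete cases; the verdict flag requires all three p ≤ alpha
(default 0.05, nominal — these are follow-up analyses, not discovery).  No
mediation decomposition is attempted: only the three marginal edges are
reported.

## The synthetic cohort generator

The generator emulates exactly the structure the analysis assumes, no more:

* **Genotypes** — HWE at every SNP, common allele frequencies (MAF uniform
  on (0.05, 0.5), matching the post-QC spectrum), and blockwise LD.  The LD
  model is a sequential correlated-allele scheme: within a block all SNPs
  share one sampled MAF and each haplotype allele is copied from its left
  neighbour with probability `ld_decay` (default 0.95), else drawn fresh.
  This keeps marginals exactly in HWE and gives dosage correlation
  `ld_decay^lag` (adjacent r² 0.90, lag-2 0.81, lag-3 0.74 at the default),
  so both proxy search at r² ≥ 0.8 and pruning at r² > 0.5 are exercised.
  Blocks (10 SNPs, 10 kb spacing) are mutually independent.
* **Expression** — per-probe Gaussian noise at SD 1 (expression is treated
  as standardized, so betas are in SD units; array-normalization itself is
  upstream and out of scope), plus latent confounders (`loadings x factors`)
  and planted additive genetic effects `beta * (g - mean(g))`.
* **Genome layout** — SNPs on chromosome 1; probes default to chromosome 2
  so un-planted probes are trans to every SNP, and a probe carrying a
  planted cis effect is relocated 1 kb from its SNP.
* **Traits** — `beta * source_column + noise` with a probe or SNP source.
* **Replication cohorts** — drawn from the same truth: identical allele
  frequencies, LD structure, planted-effect map and confounder loadings;
  fresh individuals, factors and noise.
* **RNG** — one `SeedSequence(seed)` spawns four streams in fixed order
  (MAF, haplotypes, expression, traits), so stages are individually
  reproducible and a replication cohort re-seeds only haplotypes and noise.

What the generator does **not** model — population structure and admixture,
imputation uncertainty (hard calls only), probe cross-hybridization,
non-Gaussian expression, allele-frequency differences between cohorts —
bounds what the tests show: passing recovery and consistency checks
demonstrates that the pipeline's machinery is correct under its own
assumptions, not that those assumptions hold in any particular real cohort.

The truth ledger lists every planted nonzero effect exactly once and is the
reference for all recovery experiments.

## Validation experiments and problem sizes

`eqtlscan.experiments` (used by the test suite and `scripts/acceptance.py`)
measures, at sizes chosen to complete in minutes on one CPU:

* scan-vs-single-pair agreement on 100 random pairs with ~2% missing calls;
* family-wise error over 200 pure-null cohorts (200 samples, 2,000
  independent SNPs x 200 probes) at the all-pairs Bonferroni threshold —
  the null runs with `ld_decay = 0` because "pure null" here means
  independent tests, the regime the binomial error band describes;
* recovery of five planted cis effects (beta 0.6 SD, n = 500) by the lead
  SNP or an r² > 0.8 proxy, 20 replicates;
* recovery of a 13-target trans hotspot (beta 0.5 SD, n = 900) as a master
  locus with its full target count, 20 replicates.  The hotspot block's MAF
  is planted at 0.30: observed master-regulator variants are common SNPs
  with per-target t statistics around 7–18, which a rare-end draw would not
  emulate;
* LD-pruning invariant violations on a mixed cis/trans cohort (must be 0);
* allelic-direction consistency across two shared-truth replication cohorts
  (discovery n = 890, replication n = 976 and 842, trans beta 0.8, three
  latent confounders, three PCs removed), 50 replicates;
* the HWE exact test against exhaustive exact-integer enumeration for all
  genotype totals ≤ 50.

## Known limitations

* The generator's LD is blockwise-stationary with a single decay parameter;
  real LD is heterogeneous and long-ranged near structural variation.
* Trans test denominators depend on the enumerated pair set; when cis
  enumeration is empty, all pairs count as trans.
* The clumping algorithm is greedy and p-ordered; other orderings can
  partition borderline SNP sets differently (locus counts are stable in the
  simulated regimes, but the partition itself is algorithm-dependent).
* `pc_sweep` reports the table; it deliberately does not pick k.
* No mixed models, kinship correction, FDR alternatives, conditional
  secondary-signal analysis, meta-analysis across cohorts, or pathway
  enrichment.
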