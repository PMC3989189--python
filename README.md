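# eqtlscan

Expression quantitative trait locus (eQTL) discovery and replication for
population-scale genotype/expression cohorts, of the kind produced by
array-based whole-blood studies.  The package covers the full path from raw
matrices to confirmed regulatory loci:

* SNP quality control (MAF > 5%, call rate > 95%, exact Hardy-Weinberg test
  P > 1e-6);
* removal of latent expression structure by principal-component
  residualization, including the PC-number sweep and replication-time
  exclusion of PCs associated with the SNP under test;
* a vectorized additive-model association scan of all SNP-probe pairs, with
  cis pairs enumerated inside a 500 kb window around the transcription unit;
* family-wise Bonferroni calling (`alpha / n_tests`), cis lead-SNP selection,
  and LD pruning of trans signals (r² > 0.5) into genomic loci by greedy
  clumping;
* replication in independent cohorts with proxy-SNP substitution (r² ≥ 0.8)
  and allelic-direction-consistency accounting;
* downstream integration: master regulatory loci (trans loci hitting ≥ 5
  distinct genes), cross-study gene-overlap percentages, and triangular
  SNP–transcript–trait association tests.

Because real cohort genotypes are not redistributable, the package ships a
first-class synthetic cohort generator (`eqtlscan.simulate`) that plants cis
effects, trans hotspots, latent confounders and trait models into HWE
genotypes with blockwise LD, and records everything in a truth ledger — so
every pipeline stage is testable end to end with known answers.

## The model in brief

For each SNP–probe pair, OLS on pairwise-complete cases:

    y = alpha + beta * g + e,    g in {0, 1, 2} (ALT-allele dosage)

with the two-sided t test of `beta = 0` on `n - 2` df.  Expression is
residualized on the top expression PCs beforehand, so `beta` is in
(approximately) SD units per allele copy.  Significance is Bonferroni at
`0.05 / n_tests` per class; with the canonical whole-blood test counts this
gives the familiar `0.05 / 8,308,176 = 6.02e-9` (cis) and replication
thresholds `1.21e-5` / `3.1e-4`.  See `docs/methods.md` for the full account.

## Worked example

```python
from eqtlscan import *

cfg = SimulationConfig(
    n_individuals=500, n_snps=100, n_probes=20,
    cis_effects=[(15, 0, 0.8)],                      # SNP 15 -> probe 0, +0.8 SD
    trans_hotspots=[(55, [5, 6, 7, 8, 9], [0.5]*5)], # 5-gene trans hotspot
    n_confounders=2, seed=42,
)
cohort = simulate_cohort(cfg)

geno, report = snp_qc(cohort.genotypes)              # 100 of 100 SNPs pass
resid = residualize(cohort.expression, compute_pcs(cohort.expression, 2))

pairs, n_cis, _ = enumerate_cis_pairs(geno.snps, cohort.annotation)
cis_res = scan(geno, resid, pairs=pairs)             # 66 cis pairs
trans_res = scan(geno, resid, pairs="trans", annotation=cohort.annotation)

thr = ThresholdSet(alpha=0.05, n_cis_tests=n_cis, n_trans_tests=len(trans_res))
cis_calls = call_cis(cis_res, thr.cis_threshold, geno.snps, cohort.annotation)
trans_calls, loci, _ = prune_trans(trans_res, thr.trans_threshold, cis_calls, geno)

print(summarize_discovery(cis_calls, trans_calls, loci))
master, _ = detect_master_loci(trans_calls, loci, cohort.annotation)
print(master[["locus_id", "lead_snp", "n_targets"]])
```

prints

```
{'n_cis': 10, 'n_trans_pairs': 34, 'n_trans_loci': 1, 'n_total': 11,
 'n_genes': 1, 'n_multiprobe': 0, 'n_unassigned': 0}
  locus_id lead_snp  n_targets
0     L000   s00055          5
```

The planted cis SNP block yields 10 significant cis pairs (the planted SNP
`s00015` is the lead for probe `p00000`, beta 0.70, p = 3.1e-26 — LD
neighbours are significant too but not flagged lead), and the planted
hotspot collapses into a single trans locus led by `s00055` that qualifies
as a master regulatory locus with all 5 target genes.  `n_total` counts cis
calls plus trans loci.

Every stage is also a CLI subcommand (`eqtlscan simulate | qc | residualize |
scan | call | replicate | hotspots | overlap | triangle | sweep`); run
`eqtlscan --help`.

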