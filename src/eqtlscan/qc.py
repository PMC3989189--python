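"""SNP-level quality control: MAF, call rate and the HWE exact test.

Inclusion filters mirror standard array-based eQTL practice: minor allele
frequency strictly above 5%, call rate strictly above 95%, and an exact
Hardy-Weinberg equilibrium test p-value strictly above 1e-6.  The HWE test is
the conditional exact test (probability of heterozygote counts, given the
allele counts, no more probable than the observed one), which is well defined
at low genotype counts where the chi-square approximation breaks down.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .config import AnalysisConfig
from .types import GenotypeMatrix


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional HWE test p-value for one SNP's genotype counts.

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of all configurations no more probable
    than the observed one.  Returns a p-value in (0, 1].
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise ValueError("all genotype counts are zero")
    n_ref = 2 * n_hom_ref + n_het
    n_alt = 2 * n_hom_alt + n_het
    rare = min(n_ref, n_alt)
    # possible het counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    n_rare_hom = (rare - hets) // 2
    n_common_hom = n - n_rare_hom - hets
    logw = (
        hets * np.log(2.0)
        - gammaln(n_rare_hom + 1)
        - gammaln(hets + 1)
        - gammaln(n_common_hom + 1)
    )
    logw -= logw.max()
    w = np.exp(logw)
    probs = w / w.sum()
    p_obs = probs[hets == n_het][0]
    # tolerance guards ties lost to floating point
    p = probs[probs <= p_obs * (1.0 + 1e-10)].sum()
    return float(min(p, 1.0))


def hwe_exact_test_vector(n0: np.ndarray, n1: np.ndarray, n2: np.ndarray) -> np.ndarray:
    """Per-SNP HWE exact p-values; NaN where a SNP has no genotype calls."""
    out = np.full(len(n0), np.nan)
    for i, (a, b, c) in enumerate(zip(n0, n1, n2)):
        if a + b + c > 0:
            out[i] = hwe_exact_test(int(a), int(b), int(c))
    return out


@dataclass
class QcReport:
    n_input: int
    n_pass: int
    n_fail_maf: int
    n_fail_callrate: int
    n_fail_hwe: int
    table: pd.DataFrame  # per-SNP metrics and pass/fail flags


def snp_qc(genotypes: GenotypeMatrix, config: AnalysisConfig | None = None) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the three inclusion filters (all strict inequalities).

    MAF is computed on non-missing calls; a SNP may fail several filters and
    is counted once per filter.  An empty pass-set is legal.
    """
    if genotypes.n_snps == 0:
        raise ValueError("genotype matrix has no SNPs")
    config = config or AnalysisConfig()
    maf = genotypes.maf()
    call_rate = genotypes.call_rate()
    n0, n1, n2 = genotypes.genotype_counts()
    hwe_p = hwe_exact_test_vector(n0, n1, n2)

    pass_maf = maf > config.maf_min
    pass_callrate = call_rate > config.callrate_min
    pass_hwe = hwe_p > config.hwe_p_min
    passed = pass_maf & pass_callrate & pass_hwe

    table = pd.DataFrame(
        {
            "snp_id": genotypes.snps["snp_id"],
            "maf": maf,
            "call_rate": call_rate,
            "hwe_p": hwe_p,
            "pass_maf": pass_maf,
            "pass_callrate": pass_callrate,
            "pass_hwe": pass_hwe,
            "pass": passed,
        }
    )
    report = QcReport(
        n_input=genotypes.n_snps,
        n_pass=int(passed.sum()),
        n_fail_maf=int((~pass_maf).sum()),
        n_fail_callrate=int((~pass_callrate).sum()),
        n_fail_hwe=int((~pass_hwe).sum()),
        table=table,
    )
    return genotypes.subset_snps(np.flatnonzero(passed)), report
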