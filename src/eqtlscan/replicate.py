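"""Replication of discovery eQTL calls in independent cohorts.

Each discovery SNP-probe call is re-tested in every replication cohort with a
per-class Bonferroni threshold (alpha divided by the number of discovered cis
respectively trans SNP-probe associations).  When the discovery SNP is absent
from a cohort a proxy is substituted: the highest-r^2 SNP within 500 kb at
r^2 >= 0.8 (r^2 taken from the discovery genotypes, which act as the
reference panel).  Replication regressions run on expression residualized for
the replication PC numbers, with PCs associated with the SNP of interest
excluded.  Effect alleles are harmonized across cohorts (and across the proxy
substitution) before scoring allelic-direction consistency.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .association import regress_single
from .calling import ThresholdSet
from .config import AnalysisConfig
from .confounders import compute_pcs, residualize_column, snp_associated_pcs
from .types import ExpressionMatrix, GenotypeMatrix


class Cohort(NamedTuple):
    name: str
    genotypes: GenotypeMatrix
    expression: ExpressionMatrix


def percent(count: float, denominator: float) -> int:
    """Integer percentage, rounded half away from zero."""
    if denominator == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    value = 100.0 * count / denominator
    return int(math.floor(value + 0.5)) if value >= 0 else -int(math.floor(-value + 0.5))


def replication_thresholds(
    n_cis_discovered: int,
    n_trans_discovered: int,
    alpha: float = 0.05,
) -> ThresholdSet:
    """Per-class Bonferroni thresholds over the discovered association counts
    (SNP-probe pairs, not loci)."""
    if n_cis_discovered < 1 or n_trans_discovered < 1:
        raise ValueError("discovered counts must be >= 1")
    return ThresholdSet(alpha=alpha, n_cis_tests=n_cis_discovered, n_trans_tests=n_trans_discovered)


def find_proxy(
    snp_id: str,
    cohort_genotypes: GenotypeMatrix,
    reference_genotypes: GenotypeMatrix,
    r2_min: float = 0.8,
    window: int = 500_000,
) -> tuple[str, float, float] | None:
    """The SNP itself if present in the cohort, else the best proxy.

    Returns ``(snp_used, r2, r)`` with r the signed dosage correlation in the
    reference panel (needed for direction harmonization), or ``None`` when no
    candidate reaches ``r2_min``.  Absence of a proxy is a value, not an error.
    """
    cohort_idx = cohort_genotypes.snp_index()
    if snp_id in cohort_idx:
        return snp_id, 1.0, 1.0
    ref_idx = reference_genotypes.snp_index()
    if snp_id not in ref_idx:
        return None
    target = reference_genotypes.snps.iloc[ref_idx[snp_id]]
    x = reference_genotypes.dosages[:, ref_idx[snp_id]]
    best: tuple[str, float, float] | None = None
    candidates = reference_genotypes.snps[
        (reference_genotypes.snps["chrom"] == target["chrom"])
        & (np.abs(reference_genotypes.snps["pos"] - target["pos"]) <= window)
        & (reference_genotypes.snps["snp_id"].isin(cohort_idx))
        & (reference_genotypes.snps["snp_id"] != snp_id)
    ]
    for _, cand in candidates.iterrows():
        y = reference_genotypes.dosages[:, ref_idx[cand["snp_id"]]]
        mask = ~(np.isnan(x) | np.isnan(y))
        if mask.sum() < 3 or np.ptp(x[mask]) == 0 or np.ptp(y[mask]) == 0:
            continue
        r = float(np.corrcoef(x[mask], y[mask])[0, 1])
        if r * r >= r2_min and (best is None or r * r > best[1]):
            best = (str(cand["snp_id"]), r * r, r)
    return best


def _allele_flip_sign(disc_snps: pd.DataFrame, cohort_snps: pd.DataFrame, snp_id: str) -> float:
    """-1 when the cohort's ref/alt coding is swapped relative to discovery."""
    d = disc_snps.loc[disc_snps["snp_id"] == snp_id]
    c = cohort_snps.loc[cohort_snps["snp_id"] == snp_id]
    if len(d) == 0 or len(c) == 0:
        return 1.0
    d, c = d.iloc[0], c.iloc[0]
    if d["ref"] == c["alt"] and d["alt"] == c["ref"]:
        return -1.0
    return 1.0


RECORD_COLUMNS = [
    "snp_id", "probe_id", "class", "locus_id", "beta_discovery", "p_discovery",
    "cohort", "assessable", "snp_used", "proxy_r2", "n", "beta", "p",
    "passed", "direction_consistent",
]


def replicate_calls(
    calls: pd.DataFrame,
    cohorts: list[Cohort],
    config: AnalysisConfig,
    discovery_genotypes: GenotypeMatrix,
    thresholds: ThresholdSet | None = None,
) -> pd.DataFrame:
    """Re-test every discovery call in every cohort.

    ``calls`` needs columns ``snp_id, probe_id, class, beta, p`` (plus
    ``locus_id`` for trans rows).  Returns one record per (call, cohort) in
    long form; ``passed`` uses the per-class replication threshold and
    ``direction_consistent`` compares harmonized effect signs (defined only
    where passed).
    """
    n_cis = int((calls["class"] == "cis").sum())
    n_trans = int((calls["class"] == "trans").sum())
    if thresholds is None:
        thresholds = replication_thresholds(max(n_cis, 1), max(n_trans, 1), config.alpha)
    records: list[dict] = []
    for cohort in cohorts:
        expr = cohort.expression
        rank = min(expr.n_samples - 1, expr.n_probes)
        bases = {
            "cis": compute_pcs(expr, min(config.n_pc_cis_replication, rank)),
            "trans": compute_pcs(expr, min(config.n_pc_trans, rank)),
        }
        probe_col = expr.probe_index()
        cohort_idx = cohort.genotypes.snp_index()
        for _, call in calls.iterrows():
            rec = {
                "snp_id": call["snp_id"],
                "probe_id": call["probe_id"],
                "class": call["class"],
                "locus_id": call.get("locus_id", ""),
                "beta_discovery": call["beta"],
                "p_discovery": call["p"],
                "cohort": cohort.name,
                "assessable": False,
                "snp_used": "",
                "proxy_r2": np.nan,
                "n": 0,
                "beta": np.nan,
                "p": np.nan,
                "passed": False,
                "direction_consistent": pd.NA,
            }
            if call["probe_id"] not in probe_col:
                records.append(rec)
                continue
            proxy = find_proxy(
                call["snp_id"], cohort.genotypes, discovery_genotypes,
                r2_min=config.proxy_r2_min, window=config.proxy_window,
            )
            if proxy is None:
                records.append(rec)
                continue
            snp_used, proxy_r2, proxy_r = proxy
            dosage = cohort.genotypes.dosages[:, cohort_idx[snp_used]]
            basis = bases[call["class"]]
            excluded = snp_associated_pcs(basis, dosage, alpha=config.pc_assoc_alpha)
            y = expr.values[:, probe_col[call["probe_id"]]]
            y_res = residualize_column(y, basis.drop(excluded))
            res = regress_single(dosage, y_res)
            flip = _allele_flip_sign(discovery_genotypes.snps, cohort.genotypes.snps, snp_used)
            threshold = (
                thresholds.cis_threshold if call["class"] == "cis" else thresholds.trans_threshold
            )
            passed = bool(not res.degenerate and res.p <= threshold)
            rec.update(
                assessable=True,
                snp_used=snp_used,
                proxy_r2=proxy_r2,
                n=res.n,
                beta=res.beta,
                p=res.p,
                passed=passed,
            )
            if passed:
                harmonized = np.sign(res.beta) * flip * np.sign(proxy_r)
                rec["direction_consistent"] = bool(harmonized == np.sign(call["beta"]))
            records.append(rec)
    return pd.DataFrame(records, columns=RECORD_COLUMNS)


@dataclass
class ReplicationSummary:
    n_discovery_cis: int
    n_discovery_trans_pairs: int
    n_discovery_trans_loci: int
    n_replicated_cis: int
    n_replicated_trans_pairs: int
    n_replicated_trans_loci: int
    pct_overall: int | None
    pct_cis: int | None
    pct_trans: int | None
    pct_direction_consistent: int | None
    per_cohort: dict


def summarize_replication(records: pd.DataFrame) -> ReplicationSummary:
    """Aggregate long-form replication records into headline percentages.

    A call is replicated when it passed in at least one cohort; a trans locus
    is replicated when any member association is.  Overall percentage counts
    cis as SNP-probe calls and trans as loci.  Percentages are recomputed
    from raw counts (integer, half away from zero).
    """
    if len(records) == 0:
        return ReplicationSummary(0, 0, 0, 0, 0, 0, None, None, None, None, {})
    key = ["snp_id", "probe_id", "class"]
    per_call = records.groupby(key, sort=False).agg(
        replicated=("passed", "any"), locus_id=("locus_id", "first")
    ).reset_index()
    cis = per_call[per_call["class"] == "cis"]
    trans = per_call[per_call["class"] == "trans"]
    n_cis, n_trans_pairs = len(cis), len(trans)
    n_rep_cis = int(cis["replicated"].sum())
    n_rep_trans_pairs = int(trans["replicated"].sum())
    loci = trans.groupby("locus_id")["replicated"].any() if n_trans_pairs else pd.Series(dtype=bool)
    n_trans_loci = len(loci)
    n_rep_trans_loci = int(loci.sum())
    n_total = n_cis + n_trans_loci
    n_rep_total = n_rep_cis + n_rep_trans_loci

    passed = records[records["passed"].astype(bool)]
    pct_dir = (
        percent(int(passed["direction_consistent"].astype(bool).sum()), len(passed))
        if len(passed)
        else None
    )
    per_cohort = {}
    for name, group in records.groupby("cohort", sort=False):
        g_call = group.groupby(key, sort=False).agg(
            replicated=("passed", "any"), locus_id=("locus_id", "first")
        ).reset_index()
        g_cis = g_call[g_call["class"] == "cis"]
        g_trans = g_call[g_call["class"] == "trans"]
        g_loci = (
            g_trans.groupby("locus_id")["replicated"].any()
            if len(g_trans)
            else pd.Series(dtype=bool)
        )
        g_total = len(g_cis) + len(g_loci)
        g_rep = int(g_cis["replicated"].sum()) + int(g_loci.sum())
        per_cohort[name] = {
            "n_replicated_cis": int(g_cis["replicated"].sum()),
            "n_replicated_trans_loci": int(g_loci.sum()),
            "pct_overall": percent(g_rep, g_total) if g_total else None,
            "pct_cis": percent(int(g_cis["replicated"].sum()), len(g_cis)) if len(g_cis) else None,
            "pct_trans": percent(int(g_loci.sum()), len(g_loci)) if len(g_loci) else None,
        }
    return ReplicationSummary(
        n_discovery_cis=n_cis,
        n_discovery_trans_pairs=n_trans_pairs,
        n_discovery_trans_loci=n_trans_loci,
        n_replicated_cis=n_rep_cis,
        n_replicated_trans_pairs=n_rep_trans_pairs,
        n_replicated_trans_loci=n_rep_trans_loci,
        pct_overall=percent(n_rep_total, n_total) if n_total else None,
        pct_cis=percent(n_rep_cis, n_cis) if n_cis else None,
        pct_trans=percent(n_rep_trans_loci, n_trans_loci) if n_trans_loci else None,
        pct_direction_consistent=pct_dir,
        per_cohort=per_cohort,
    )
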