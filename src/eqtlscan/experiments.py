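"""End-to-end Monte-Carlo experiments on simulated cohorts.

These functions exercise the full pipeline on cohorts with planted truth and
measure its operating characteristics: family-wise error under the null,
lead-SNP recovery of planted cis effects, recovery of a planted trans
hotspot, LD-pruning invariants, cross-cohort allelic-direction consistency,
and agreement between the vectorized scan and the single-pair regression
route.  Problem sizes are scaled to run on a single CPU in minutes; each
function derives all randomness from one integer seed.
"""
from __future__ import annotations

import numpy as np

from . import association, calling, downstream, qc, replicate
from .config import AnalysisConfig, SimulationConfig
from .confounders import compute_pcs, residualize
from .simulate import (
    probe_annotation,
    sample_block_mafs,
    simulate_cohort,
    simulate_expression,
    simulate_genotypes,
    simulate_replication_cohort,
)
from .types import replace


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(np.random.SeedSequence(seed)).integers(2**31 - 1, size=n)


def fwer_null_experiment(
    seed: int,
    n_samples: int = 200,
    n_snps: int = 2000,
    n_probes: int = 200,
    n_reps: int = 200,
    alpha: float = 0.05,
) -> dict:
    """Family-wise error rate of the Bonferroni-thresholded all-pairs scan
    under a pure null (independent SNPs, no planted effects)."""
    threshold = calling.bonferroni_threshold(n_snps * n_probes, alpha)
    seeds = _spawn_seeds(seed, n_reps)
    hits = 0
    for rep_seed in seeds:
        cfg = SimulationConfig(
            n_individuals=n_samples, n_snps=n_snps, n_probes=n_probes,
            ld_block_size=1, ld_decay=0.0, seed=int(rep_seed),
        )
        geno = simulate_genotypes(cfg)
        expr, _ = simulate_expression(geno, cfg)
        st = association.pairwise_stats(geno.dosages, expr.values)
        if np.nanmin(st["p"]) <= threshold:
            hits += 1
    sd = float(np.sqrt(alpha * (1 - alpha) / n_reps))
    return {"fwer": hits / n_reps, "bound": alpha + 3 * sd, "n_reps": n_reps,
            "threshold": threshold}


def cis_recovery_experiment(
    seed: int,
    n_reps: int = 20,
    n_samples: int = 500,
    beta: float = 0.6,
    n_snps: int = 100,
    n_probes: int = 10,
    n_effects: int = 5,
    proxy_r2: float = 0.8,
) -> dict:
    """Lead-SNP recovery of planted cis effects.

    A planted effect counts as recovered when its probe has a significant cis
    call whose lead SNP is the planted SNP or an LD proxy at r^2 > ``proxy_r2``
    in the realized genotypes.
    """
    # plant each effect mid-block, one probe per effect
    snp_idx = [5 + 20 * i for i in range(n_effects)]
    cis_effects = [(s, i, beta) for i, s in enumerate(snp_idx)]
    seeds = _spawn_seeds(seed, n_reps)
    recovered = total = 0
    for rep_seed in seeds:
        cfg = SimulationConfig(
            n_individuals=n_samples, n_snps=n_snps, n_probes=n_probes,
            cis_effects=cis_effects, seed=int(rep_seed),
        )
        cohort = simulate_cohort(cfg)
        pairs, n_pairs, _ = association.enumerate_cis_pairs(
            cohort.genotypes.snps, cohort.annotation, flank=500_000
        )
        res = association.scan(cohort.genotypes, cohort.expression, pairs=pairs)
        threshold = calling.bonferroni_threshold(n_pairs)
        calls = calling.call_cis(res, threshold, cohort.genotypes.snps)
        leads = dict(zip(calls.loc[calls["lead"], "probe_id"], calls.loc[calls["lead"], "snp_id"]))
        col = cohort.genotypes.snp_index()
        for planted_snp, planted_probe, _b in sorted(cohort.truth.planted_cis):
            total += 1
            lead = leads.get(planted_probe)
            if lead is None:
                continue
            if lead == planted_snp:
                recovered += 1
            else:
                r2 = calling.ld_r2(
                    cohort.genotypes.dosages[:, col[lead]],
                    cohort.genotypes.dosages[:, col[planted_snp]],
                )
                if r2 > proxy_r2:
                    recovered += 1
    return {"recovery": recovered / total, "n_planted": total, "n_reps": n_reps}


def hotspot_recovery_experiment(
    seed: int,
    n_reps: int = 20,
    n_samples: int = 900,
    beta: float = 0.5,
    n_targets: int = 13,
    n_snps: int = 100,
    n_probes: int = 20,
    hotspot_maf: float = 0.30,
) -> dict:
    """Recovery of a planted trans hotspot as a master locus with its full
    distinct-target count.

    The hotspot block's allele frequency is planted at a common value, as the
    observed master-regulator variants are common array SNPs.
    """
    hotspot_snp = 45
    targets = list(range(n_targets))
    cfg0 = SimulationConfig(
        n_individuals=n_samples, n_snps=n_snps, n_probes=n_probes,
        trans_hotspots=[(hotspot_snp, targets, [beta] * n_targets)], seed=0,
    )
    block = hotspot_snp // cfg0.ld_block_size
    seeds = _spawn_seeds(seed, n_reps)
    full = 0
    for rep_seed in seeds:
        cfg = replace(cfg0, seed=int(rep_seed))
        mafs = sample_block_mafs(cfg)
        lo = block * cfg.ld_block_size
        mafs[lo : lo + cfg.ld_block_size] = hotspot_maf
        geno = simulate_genotypes(cfg, mafs=mafs)
        expr, truth = simulate_expression(geno, cfg)
        annot = probe_annotation(cfg)
        res = association.scan(geno, expr, pairs="all")
        threshold = calling.bonferroni_threshold(len(res))
        trans_calls, locus_table, _ = calling.prune_trans(
            res, threshold, cis_calls=res.iloc[0:0], genotypes=geno
        )
        master, _multi = downstream.detect_master_loci(
            trans_calls, locus_table, annotation=annot, min_targets=5
        )
        hotspot_id = geno.snps["snp_id"].iloc[hotspot_snp]
        for _, locus in master.iterrows():
            locus_members = locus_table.loc[
                locus_table["locus_id"] == locus["locus_id"], "members"
            ].iloc[0].split(",")
            if hotspot_id in locus_members and locus["n_targets"] == n_targets:
                full += 1
                break
    return {"recovery": full / n_reps, "n_reps": n_reps}


def pruning_invariants_experiment(
    seed: int,
    n_samples: int = 500,
    n_snps: int = 120,
    n_probes: int = 30,
) -> dict:
    """Run discovery with planted cis and trans effects and count violations
    of the pruning invariants (all must be zero):

    * no retained trans SNP has r^2 > 0.5 with any significant cis SNP;
    * within a locus every member has r^2 > 0.5 with its lead;
    * locus leads are pairwise r^2 <= 0.5.
    """
    cfg = SimulationConfig(
        n_individuals=n_samples, n_snps=n_snps, n_probes=n_probes,
        cis_effects=[(5, 0, 0.7), (25, 1, 0.7), (45, 2, 0.7)],
        trans_hotspots=[(26, [10, 11, 12], [0.6] * 3), (85, [13, 14], [0.6] * 2)],
        seed=seed,
    )
    cohort = simulate_cohort(cfg)
    geno, expr, annot = cohort.genotypes, cohort.expression, cohort.annotation
    cis_pairs, n_cis_pairs, _ = association.enumerate_cis_pairs(geno.snps, annot)
    cis_res = association.scan(geno, expr, pairs=cis_pairs)
    all_res = association.scan(geno, expr, pairs="all")
    cis_set = {(s, p) for s, p in cis_pairs.tolist()}
    snp_pos = {s: i for i, s in enumerate(geno.snps["snp_id"])}
    probe_pos = {p: i for i, p in enumerate(expr.probes)}
    is_cis = np.array(
        [(snp_pos[s], probe_pos[p]) in cis_set for s, p in zip(all_res["snp_id"], all_res["probe_id"])]
    )
    trans_res = all_res[~is_cis]
    thr = calling.ThresholdSet(alpha=0.05, n_cis_tests=n_cis_pairs, n_trans_tests=len(trans_res))
    cis_calls = calling.call_cis(cis_res, thr.cis_threshold, geno.snps)
    trans_calls, locus_table, _ = calling.prune_trans(
        trans_res, thr.trans_threshold, cis_calls, geno
    )
    col = geno.snp_index()
    violations = 0
    cis_snps = cis_calls["snp_id"].unique()
    for t in trans_calls["snp_id"].unique():
        for c in cis_snps:
            r2 = calling.ld_r2(geno.dosages[:, col[t]], geno.dosages[:, col[c]])
            if r2 > 0.5:
                violations += 1
    leads = list(locus_table["lead_snp"])
    for _, locus in locus_table.iterrows():
        for member in locus["members"].split(","):
            if member == locus["lead_snp"]:
                continue
            r2 = calling.ld_r2(
                geno.dosages[:, col[member]], geno.dosages[:, col[locus["lead_snp"]]]
            )
            if not r2 > 0.5:
                violations += 1
    for i in range(len(leads)):
        for j in range(i + 1, len(leads)):
            r2 = calling.ld_r2(geno.dosages[:, col[leads[i]]], geno.dosages[:, col[leads[j]]])
            if r2 > 0.5:
                violations += 1
    return {
        "violations": violations,
        "n_trans_loci": len(locus_table),
        "n_cis_calls": len(cis_calls),
        "n_trans_calls": len(trans_calls),
    }


def direction_consistency_experiment(
    seed: int,
    n_reps: int = 50,
    n_discovery: int = 890,
    n_replication: tuple[int, int] = (976, 842),
    beta: float = 0.8,
    n_snps: int = 60,
    n_probes: int = 30,
    n_planted: int = 15,
    n_confounders: int = 3,
    n_pcs: int = 3,
) -> dict:
    """Two-cohort shared-truth replication: allelic-direction consistency
    among replicated trans associations, plus the replicated fraction of
    discovered planted pairs."""
    snp_idx = [3 + 4 * i for i in range(n_planted)]
    hotspots = [(s, [i], [beta]) for i, s in enumerate(snp_idx)]
    ana = AnalysisConfig(n_pc_cis=n_pcs, n_pc_trans=n_pcs, n_pc_cis_replication=n_pcs)
    seeds = _spawn_seeds(seed, 3 * n_reps).reshape(n_reps, 3)
    n_passed = n_consistent = n_records = 0
    n_planted_discovered = n_planted_replicated = 0
    for rep_seeds in seeds:
        cfg = SimulationConfig(
            n_individuals=n_discovery, n_snps=n_snps, n_probes=n_probes,
            trans_hotspots=hotspots, n_confounders=n_confounders,
            confounder_sd=1.5, seed=int(rep_seeds[0]),
        )
        geno = simulate_genotypes(cfg)
        expr, truth = simulate_expression(geno, cfg)
        basis = compute_pcs(expr, n_pcs)
        res = association.scan(geno, residualize(expr, basis), pairs="all")
        threshold = calling.bonferroni_threshold(len(res), ana.alpha)
        trans_calls, locus_table, _ = calling.prune_trans(
            res, threshold, cis_calls=res.iloc[0:0], genotypes=geno
        )
        if len(trans_calls) == 0:
            continue
        cohorts = [
            replicate.Cohort(f"rep{i}", *simulate_replication_cohort(
                truth, cfg, int(rep_seeds[1 + i]), n_individuals=n_rep
            ))
            for i, n_rep in enumerate(n_replication)
        ]
        records = replicate.replicate_calls(trans_calls, cohorts, ana, geno)
        passed = records[records["passed"].astype(bool)]
        n_records += len(records)
        n_passed += len(passed)
        n_consistent += int(passed["direction_consistent"].astype(bool).sum())
        planted = truth.planted_pairs()
        call_pairs = set(zip(trans_calls["snp_id"], trans_calls["probe_id"]))
        discovered = planted & call_pairs
        n_planted_discovered += len(discovered)
        rep_ok = records.groupby(["snp_id", "probe_id"])["passed"].any()
        n_planted_replicated += sum(bool(rep_ok.get(pair, False)) for pair in discovered)
    return {
        "direction_consistency_pct": 100.0 * n_consistent / n_passed if n_passed else float("nan"),
        "replicated_fraction": n_planted_replicated / n_planted_discovered
        if n_planted_discovered
        else float("nan"),
        "n_passed": n_passed,
        "n_reps": n_reps,
    }


def scan_oracle_experiment(seed: int, n_pairs: int = 100, n_samples: int = 300,
                           n_snps: int = 50, n_probes: int = 20) -> dict:
    """Maximum relative disagreement between the vectorized scan and the
    single-pair regression route on random pairs (with missing dosages)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cfg = SimulationConfig(
        n_individuals=n_samples, n_snps=n_snps, n_probes=n_probes, seed=int(rng.integers(2**31 - 1))
    )
    geno = simulate_genotypes(cfg)
    # knock out ~2% of calls to exercise pairwise-complete handling
    miss = rng.uniform(size=geno.dosages.shape) < 0.02
    geno.dosages[miss] = np.nan
    expr, _ = simulate_expression(geno, cfg)
    pairs = np.column_stack(
        [rng.integers(n_snps, size=n_pairs), rng.integers(n_probes, size=n_pairs)]
    )
    res = association.scan(geno, expr, pairs=pairs)
    max_rel = 0.0
    for _, row in res.iterrows():
        j = geno.snp_index()[row["snp_id"]]
        k = expr.probe_index()[row["probe_id"]]
        single = association.regress_single(geno.dosages[:, j], expr.values[:, k])
        if single.degenerate or row["degenerate"]:
            continue
        for field in ("beta", "se", "p"):
            a, b = float(row[field]), float(getattr(single, field))
            max_rel = max(max_rel, abs(a - b) / max(abs(b), 1e-300))
    return {"max_rel_err": max_rel, "n_pairs": n_pairs}


def hwe_enumeration_check(max_total: int = 50) -> dict:
    """Exhaustively compare the HWE exact test against an exact-integer
    enumeration oracle over every genotype configuration with total <= max_total."""
    from math import comb

    def oracle(n0: int, n1: int, n2: int) -> float:
        n = n0 + n1 + n2
        rare = min(2 * n0 + n1, 2 * n2 + n1)
        weights = {}
        for h in range(rare % 2, rare + 1, 2):
            na = (rare - h) // 2
            nb = n - na - h
            # integer weight: multinomial coefficient times 2^h
            weights[h] = comb(n, na) * comb(n - na, h) * (2**h)
        total = sum(weights.values())
        w_obs = weights[n1]
        return sum(w for w in weights.values() if w <= w_obs) / total

    max_err = 0.0
    n_checked = 0
    for total in range(1, max_total + 1):
        for n0 in range(total + 1):
            for n1 in range(total - n0 + 1):
                n2 = total - n0 - n1
                p_impl = qc.hwe_exact_test(n0, n1, n2)
                p_oracle = oracle(n0, n1, n2)
                max_err = max(max_err, abs(p_impl - p_oracle))
                n_checked += 1
    return {"max_abs_err": max_err, "n_checked": n_checked}
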