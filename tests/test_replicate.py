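"""Replication: thresholds, proxy search, harmonization, summaries."""
import numpy as np
import pandas as pd
import pytest

from eqtlscan import (
    AnalysisConfig,
    Cohort,
    SimulationConfig,
    find_proxy,
    percent,
    replicate_calls,
    replication_thresholds,
    simulate_cohort,
    simulate_expression,
    simulate_genotypes,
    simulate_replication_cohort,
    summarize_replication,
)
from eqtlscan.types import replace
from tests.conftest import make_genotypes


def test_replication_threshold_values():
    thr = replication_thresholds(4_116, 161)
    assert thr.cis_threshold == pytest.approx(1.21e-5, abs=0.005e-5)
    assert thr.trans_threshold == pytest.approx(3.1e-4, abs=0.05e-4)
    both = replication_thresholds(1, 1)
    assert both.cis_threshold == 0.05 and both.trans_threshold == 0.05
    with pytest.raises(ValueError):
        replication_thresholds(0, 1)


def test_percent_rounds_half_away_from_zero():
    assert percent(3_847, 4_210) == 91
    assert percent(3_768, 4_116) == 92
    assert percent(79, 94) == 84
    assert percent(915, 1000) == 92  # 91.5 rounds up
    with pytest.raises(ZeroDivisionError):
        percent(1, 0)


def _shared_truth_setup(seed=404):
    cfg = SimulationConfig(
        n_individuals=500, n_snps=30, n_probes=10,
        trans_hotspots=[(5, [0], [0.8]), (15, [1], [-0.8])], seed=seed,
    )
    geno = simulate_genotypes(cfg)
    expr, truth = simulate_expression(geno, cfg)
    return cfg, geno, expr, truth


def test_find_proxy_same_snp_and_block_mate():
    cfg, geno, expr, truth = _shared_truth_setup()
    rep_geno, rep_expr = simulate_replication_cohort(truth, cfg, new_seed=7)
    assert find_proxy("s00005", rep_geno, geno) == ("s00005", 1.0, 1.0)
    # drop the target SNP from the cohort: its block-mate becomes the proxy
    keep = [j for j in range(geno.n_snps) if j != 5]
    reduced = rep_geno.subset_snps(np.array(keep))
    proxy = find_proxy("s00005", reduced, geno, r2_min=0.8)
    assert proxy is not None
    snp_used, r2, r = proxy
    assert snp_used in {"s00004", "s00006"} and r2 >= 0.8
    # no proxy below the r2 floor
    assert find_proxy("s00005", reduced, geno, r2_min=0.9999) is None


def _calls_frame(truth):
    rows = [
        {"snp_id": s, "probe_id": p, "class": "trans", "locus_id": f"L{i:03d}",
         "beta": b, "p": 1e-12}
        for i, (s, p, b) in enumerate(sorted(truth.planted_trans))
    ]
    return pd.DataFrame(rows)


def test_replicate_calls_shared_truth_passes_with_consistent_direction():
    cfg, geno, expr, truth = _shared_truth_setup()
    calls = _calls_frame(truth)
    cohorts = [
        Cohort("c1", *simulate_replication_cohort(truth, cfg, new_seed=11)),
        Cohort("c2", *simulate_replication_cohort(truth, cfg, new_seed=12)),
    ]
    ana = AnalysisConfig(n_pc_cis_replication=2, n_pc_trans=2)
    records = replicate_calls(calls, cohorts, ana, geno)
    assert len(records) == 4
    assert records["passed"].all()
    assert records["direction_consistent"].astype(bool).all()
    summary = summarize_replication(records)
    assert summary.pct_overall == 100
    assert summary.pct_direction_consistent == 100
    assert set(summary.per_cohort) == {"c1", "c2"}


def test_replicate_calls_null_cohort_rarely_passes():
    cfg, geno, expr, truth = _shared_truth_setup()
    calls = _calls_frame(truth)
    null_cfg = replace(cfg, trans_hotspots=[], seed=909)
    null_geno = simulate_genotypes(null_cfg)
    null_expr, _ = simulate_expression(null_geno, null_cfg)
    ana = AnalysisConfig(n_pc_cis_replication=2, n_pc_trans=2)
    records = replicate_calls(calls, [Cohort("null", null_geno, null_expr)], ana, geno)
    assert records["assessable"].all()
    assert not records["passed"].any()  # threshold 0.05/2 with no signal


def test_allele_flip_harmonization():
    cfg, geno, expr, truth = _shared_truth_setup()
    calls = _calls_frame(truth)
    rep_geno, rep_expr = simulate_replication_cohort(truth, cfg, new_seed=21)
    flipped = make_genotypes(2.0 - rep_geno.dosages)
    flipped.snps = rep_geno.snps.copy()
    flipped.snps[["ref", "alt"]] = flipped.snps[["alt", "ref"]].to_numpy()
    ana = AnalysisConfig(n_pc_cis_replication=2, n_pc_trans=2)
    records = replicate_calls(calls, [Cohort("flip", flipped, rep_expr)], ana, geno)
    assert records["passed"].all()
    # raw betas flip sign, but harmonized direction stays consistent
    assert records["direction_consistent"].astype(bool).all()
    assert np.sign(records["beta"]).tolist() != np.sign(records["beta_discovery"]).tolist()


def test_missing_probe_marks_record_not_assessable():
    cfg, geno, expr, truth = _shared_truth_setup()
    calls = _calls_frame(truth)
    rep_geno, rep_expr = simulate_replication_cohort(truth, cfg, new_seed=31)
    rep_expr.values = rep_expr.values[:, 2:]
    rep_expr.probes = rep_expr.probes[2:]
    ana = AnalysisConfig(n_pc_cis_replication=2, n_pc_trans=2)
    records = replicate_calls(calls, [Cohort("c", rep_geno, rep_expr)], ana, geno)
    assert not records["assessable"].any()
    assert not records["passed"].any()


def test_replicate_calls_invariant_to_cohort_order():
    cfg, geno, expr, truth = _shared_truth_setup()
    calls = _calls_frame(truth)
    a = Cohort("a", *simulate_replication_cohort(truth, cfg, new_seed=41))
    b = Cohort("b", *simulate_replication_cohort(truth, cfg, new_seed=42))
    ana = AnalysisConfig(n_pc_cis_replication=2, n_pc_trans=2)
    r1 = replicate_calls(calls, [a, b], ana, geno)
    r2 = replicate_calls(calls, [b, a], ana, geno)
    key = ["cohort", "snp_id", "probe_id"]
    merged = r1.merge(r2, on=key, suffixes=("_1", "_2"))
    assert np.allclose(merged["p_1"], merged["p_2"])


def test_summarize_replication_empty_and_locus_granularity():
    empty = summarize_replication(pd.DataFrame())
    assert empty.pct_overall is None
    records = pd.DataFrame(
        [
            # locus L0: two member pairs, one replicates -> locus replicates
            {"snp_id": "a", "probe_id": "p1", "class": "trans", "locus_id": "L0",
             "cohort": "c1", "passed": True, "direction_consistent": True},
            {"snp_id": "b", "probe_id": "p1", "class": "trans", "locus_id": "L0",
             "cohort": "c1", "passed": False, "direction_consistent": pd.NA},
            # locus L1 fails everywhere
            {"snp_id": "c", "probe_id": "p2", "class": "trans", "locus_id": "L1",
             "cohort": "c1", "passed": False, "direction_consistent": pd.NA},
            # one cis call, replicates
            {"snp_id": "d", "probe_id": "p3", "class": "cis", "locus_id": "",
             "cohort": "c1", "passed": True, "direction_consistent": True},
        ]
    )
    s = summarize_replication(records)
    assert s.n_discovery_cis == 1 and s.n_replicated_cis == 1
    assert s.n_discovery_trans_pairs == 3 and s.n_replicated_trans_pairs == 1
    assert s.n_discovery_trans_loci == 2 and s.n_replicated_trans_loci == 1
    assert s.pct_cis == 100 and s.pct_trans == 50
    assert s.pct_overall == percent(2, 3)
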