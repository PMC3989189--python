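"""Bonferroni thresholds, cis lead selection, LD r2, trans pruning/clumping."""
import numpy as np
import pandas as pd
import pytest

from eqtlscan import (
    SimulationConfig,
    bonferroni_threshold,
    call_cis,
    format_threshold,
    ld_r2,
    prune_trans,
    simulate_genotypes,
    summarize_discovery,
)
from tests.conftest import make_genotypes


def test_bonferroni_threshold_values():
    assert format_threshold(bonferroni_threshold(8_308_176)) == pytest.approx(6.02e-9)
    assert format_threshold(bonferroni_threshold(4_116)) == pytest.approx(1.21e-5)
    assert bonferroni_threshold(1) == 0.05
    assert bonferroni_threshold(100, alpha=0.01) == pytest.approx(1e-4)
    with pytest.raises(ValueError):
        bonferroni_threshold(0)


def _assoc(rows):
    frame = pd.DataFrame(rows, columns=["snp_id", "probe_id", "n", "beta", "se", "t", "p"])
    frame["degenerate"] = False
    return frame


def _snps(ids, pos):
    return pd.DataFrame({"snp_id": ids, "chrom": "1", "pos": pos, "ref": "A", "alt": "G"})


def test_call_cis_lead_selection_and_ties():
    snps = _snps(["a", "b", "c", "d"], [100, 50, 200, 300])
    assoc = _assoc([
        ("a", "p1", 10, 1.0, 0.1, 10, 1e-12),
        ("b", "p1", 10, 1.0, 0.1, 10, 1e-10),
        ("c", "p1", 10, 1.0, 0.1, 10, 0.5),   # not significant
        ("c", "p2", 10, 1.0, 0.1, 10, 1e-8),
        ("d", "p2", 10, 1.0, 0.1, 10, 1e-8),  # tie: c at smaller position wins
    ])
    calls = call_cis(assoc, threshold=1e-6, snps=snps)
    assert len(calls) == 4  # both significant p1 SNPs retained, one lead
    p1 = calls[calls["probe_id"] == "p1"]
    assert p1.loc[p1["lead"], "snp_id"].tolist() == ["a"]
    p2 = calls[calls["probe_id"] == "p2"]
    assert p2.loc[p2["lead"], "snp_id"].tolist() == ["c"]


def test_ld_r2_basics(rng):
    x = rng.binomial(2, 0.3, 200).astype(float)
    assert ld_r2(x, x) == pytest.approx(1.0)
    assert ld_r2(x, 2.0 - x) == pytest.approx(1.0)  # allele flip invariance
    assert np.isnan(ld_r2(x, np.ones_like(x)))


def test_independent_snps_have_negligible_r2():
    cfg = SimulationConfig(
        n_individuals=10_000, n_snps=2, n_probes=1, ld_block_size=1,
        ld_decay=0.0, maf_range=(0.3, 0.3), seed=9,
    )
    geno = simulate_genotypes(cfg)
    assert ld_r2(geno.dosages[:, 0], geno.dosages[:, 1]) < 0.01


def _block_genotypes(rng, n=500, r_target=0.95, n_snps=5, p=0.3):
    """Tightly linked SNP block via the copy-or-redraw haplotype scheme."""
    hap = np.zeros((2, n, n_snps))
    for h in range(2):
        fresh = rng.uniform(size=(n, n_snps)) < p
        hap[h, :, 0] = fresh[:, 0]
        for j in range(1, n_snps):
            copy = rng.uniform(size=n) < r_target
            hap[h, :, j] = np.where(copy, hap[h, :, j - 1], fresh[:, j])
    return make_genotypes(hap.sum(axis=0))


def test_prune_trans_drops_cis_linked_snps(rng):
    block = _block_genotypes(rng, n_snps=2)  # s0-s1 r2 ~ 0.9
    lone = rng.binomial(2, 0.4, size=(500, 1)).astype(float)  # independent SNP
    geno = make_genotypes(np.column_stack([block.dosages, lone]))
    cis_calls = pd.DataFrame({"snp_id": ["s00000"]})
    assoc = _assoc([
        ("s00001", "p1", 500, 1.0, 0.1, 10, 1e-20),  # high LD with cis SNP -> dropped
        ("s00002", "p1", 500, 1.0, 0.1, 10, 1e-15),
    ])
    calls, loci, dropped = prune_trans(assoc, 1e-10, cis_calls, geno)
    assert dropped == ["s00001"]
    assert calls["snp_id"].tolist() == ["s00002"]


def test_prune_trans_independent_snps_form_three_loci(rng):
    dosages = rng.binomial(2, 0.3, size=(400, 3)).astype(float)
    geno = make_genotypes(dosages)
    assoc = _assoc([
        ("s00000", "p1", 400, 1.0, 0.1, 10, 1e-20),
        ("s00001", "p1", 400, 1.0, 0.1, 10, 1e-18),
        ("s00002", "p2", 400, 1.0, 0.1, 10, 1e-16),
    ])
    calls, loci, _ = prune_trans(assoc, 1e-10, cis_calls=assoc.iloc[0:0], genotypes=geno)
    assert len(loci) == 3
    assert set(calls["locus_id"]) == {"L000", "L001", "L002"}


def test_prune_trans_clumps_block_into_single_locus(rng):
    """Five trans SNPs in one tight LD block hitting one probe -> one locus
    led by the smallest-p SNP (hand-checked greedy clumping)."""
    geno = _block_genotypes(rng, n_snps=5)
    rows = [(f"s{j:05d}", "p1", 500, 1.0, 0.1, 10, p)
            for j, p in enumerate([1e-12, 1e-20, 1e-15, 1e-13, 1e-11])]
    assoc = _assoc(rows)
    calls, loci, _ = prune_trans(assoc, 1e-10, cis_calls=assoc.iloc[0:0], genotypes=geno)
    assert len(loci) == 1
    assert loci["lead_snp"].iloc[0] == "s00001"  # smallest p founds the locus
    assert sorted(loci["members"].iloc[0].split(",")) == [f"s{j:05d}" for j in range(5)]
    assert calls.loc[calls["lead"], "snp_id"].unique().tolist() == ["s00001"]


def test_prune_invariants_hold(rng):
    geno = _block_genotypes(rng, n_snps=5)
    extra = rng.binomial(2, 0.4, size=(500, 2)).astype(float)
    geno = make_genotypes(np.column_stack([geno.dosages, extra]))
    rows = [(f"s{j:05d}", "p1", 500, 1.0, 0.1, 10, 10.0**-(20 - j)) for j in range(7)]
    calls, loci, _ = prune_trans(_assoc(rows), 1e-10, cis_calls=pd.DataFrame(columns=["snp_id"]),
                                 genotypes=geno)
    col = geno.snp_index()
    leads = list(loci["lead_snp"])
    for i in range(len(leads)):
        for j in range(i + 1, len(leads)):
            assert not ld_r2(geno.dosages[:, col[leads[i]]], geno.dosages[:, col[leads[j]]]) > 0.5
    for _, locus in loci.iterrows():
        for member in locus["members"].split(","):
            if member != locus["lead_snp"]:
                assert ld_r2(
                    geno.dosages[:, col[member]], geno.dosages[:, col[locus["lead_snp"]]]
                ) > 0.5


def test_calling_invariant_to_input_order(rng):
    geno = _block_genotypes(rng, n_snps=5)
    rows = [(f"s{j:05d}", "p1", 500, 1.0, 0.1, 10, p)
            for j, p in enumerate([1e-12, 1e-20, 1e-15, 1e-13, 1e-11])]
    assoc = _assoc(rows)
    shuffled = assoc.sample(frac=1.0, random_state=1).reset_index(drop=True)
    a = prune_trans(assoc, 1e-10, assoc.iloc[0:0], geno)
    b = prune_trans(shuffled, 1e-10, assoc.iloc[0:0], geno)
    assert a[0]["snp_id"].tolist() == b[0]["snp_id"].tolist()
    assert a[1]["lead_snp"].tolist() == b[1]["lead_snp"].tolist()


def test_summarize_discovery_counts():
    cis = pd.DataFrame(
        {
            "snp_id": ["a", "b", "c"],
            "probe_id": ["p1", "p2", "p3"],
            "gene": ["G1", "G1", ""],
        }
    )
    trans = pd.DataFrame({"snp_id": ["d", "e"], "probe_id": ["p4", "p5"]})
    loci = pd.DataFrame({"locus_id": ["L000"]})
    s = summarize_discovery(cis, trans, loci)
    assert s["n_cis"] == 3 and s["n_trans_pairs"] == 2 and s["n_trans_loci"] == 1
    assert s["n_total"] == 4
    assert s["n_multiprobe"] == 1  # G1 hit by two distinct probes
    assert s["n_unassigned"] == 1
    empty = summarize_discovery(cis.iloc[0:0], trans.iloc[0:0], loci.iloc[0:0])
    assert all(v == 0 for v in empty.values())
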