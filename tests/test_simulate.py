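"""Synthetic cohort generator: determinism, HWE structure, planted truth."""
import numpy as np
import pytest

from eqtlscan import (
    ConfigurationError,
    SimulationConfig,
    hwe_exact_test,
    regress_single,
    simulate_cohort,
    simulate_expression,
    simulate_genotypes,
    simulate_replication_cohort,
    simulate_traits,
)
from eqtlscan.simulate import probe_annotation, sample_block_mafs


def test_same_config_and_seed_bit_identical():
    cfg = SimulationConfig(n_individuals=50, n_snps=30, n_probes=8, seed=5)
    a = simulate_cohort(cfg)
    b = simulate_cohort(cfg)
    assert np.array_equal(a.genotypes.dosages, b.genotypes.dosages)
    assert np.array_equal(a.expression.values, b.expression.values)
    assert a.traits.equals(b.traits)


def test_zero_snps_gives_empty_matrix():
    cfg = SimulationConfig(n_individuals=10, n_snps=0, n_probes=3, seed=1)
    geno = simulate_genotypes(cfg)
    assert geno.dosages.shape == (10, 0)


def test_genotype_frequencies_match_binomial_oracle():
    """At MAF 0.5 without LD, genotype frequencies follow Binomial(2, 0.5)."""
    n = 10_000
    cfg = SimulationConfig(
        n_individuals=n, n_snps=1, n_probes=1, maf_range=(0.5, 0.5),
        ld_decay=0.0, ld_block_size=1, seed=11,
    )
    geno = simulate_genotypes(cfg)
    counts = [(geno.dosages == g).sum() for g in (0, 1, 2)]
    for count, expected_freq in zip(counts, (0.25, 0.5, 0.25)):
        sd = np.sqrt(n * expected_freq * (1 - expected_freq))
        assert abs(count - n * expected_freq) < 3 * sd


def test_adjacent_snps_correlated_per_ld_decay():
    cfg = SimulationConfig(
        n_individuals=20_000, n_snps=10, n_probes=1, ld_block_size=10,
        ld_decay=0.9, maf_range=(0.3, 0.3), seed=3,
    )
    geno = simulate_genotypes(cfg)
    for lag in (1, 2):
        r = np.corrcoef(geno.dosages[:, 0], geno.dosages[:, lag])[0, 1]
        assert r == pytest.approx(0.9**lag, abs=0.03)


def test_blocks_are_independent():
    cfg = SimulationConfig(
        n_individuals=20_000, n_snps=20, n_probes=1, ld_block_size=10,
        ld_decay=0.95, seed=3,
    )
    geno = simulate_genotypes(cfg)
    r = np.corrcoef(geno.dosages[:, 9], geno.dosages[:, 10])[0, 1]
    assert abs(r) < 0.03


def test_simulated_snps_pass_hwe():
    """>= 99% of 1,000 simulated SNPs pass the HWE exact test at P > 1e-6."""
    cfg = SimulationConfig(n_individuals=500, n_snps=1000, n_probes=1, seed=21)
    geno = simulate_genotypes(cfg)
    n0, n1, n2 = geno.genotype_counts()
    passing = sum(hwe_exact_test(int(a), int(b), int(c)) > 1e-6 for a, b, c in zip(n0, n1, n2))
    assert passing >= 990


def test_null_expression_is_centered_noise():
    cfg = SimulationConfig(n_individuals=2000, n_snps=5, n_probes=10, seed=9)
    geno = simulate_genotypes(cfg)
    expr, truth = simulate_expression(geno, cfg)
    assert not truth.planted_cis and not truth.planted_trans
    limit = 3 * cfg.noise_sd / np.sqrt(cfg.n_individuals)
    assert np.all(np.abs(expr.values.mean(axis=0)) < limit)


def test_noiseless_cis_effect_recovers_beta_exactly():
    cfg = SimulationConfig(
        n_individuals=200, n_snps=10, n_probes=3, cis_effects=[(2, 1, 1.0)],
        noise_sd=1e-12, seed=13,
    )
    geno = simulate_genotypes(cfg)
    expr, _ = simulate_expression(geno, cfg)
    res = regress_single(geno.dosages[:, 2], expr.values[:, 1])
    assert res.beta == pytest.approx(1.0, abs=1e-6)


def test_hotspot_targets_correlate_with_matching_sign():
    """All 13 hotspot targets correlate with the SNP in the planted direction."""
    targets = list(range(13))
    cfg = SimulationConfig(
        n_individuals=900, n_snps=20, n_probes=15,
        trans_hotspots=[(5, targets, [0.5] * 13)], seed=17,
    )
    geno = simulate_genotypes(cfg)
    expr, truth = simulate_expression(geno, cfg)
    assert len(truth.planted_trans) == 13
    for probe in targets:
        r = np.corrcoef(geno.dosages[:, 5], expr.values[:, probe])[0, 1]
        assert r > 0


def test_truth_ledger_lists_each_nonzero_effect_once():
    cfg = SimulationConfig(
        n_individuals=50, n_snps=20, n_probes=10,
        cis_effects=[(1, 0, 0.5), (3, 1, 0.0)],
        trans_hotspots=[(7, [4, 5], [0.3, 0.0])], seed=2,
    )
    geno = simulate_genotypes(cfg)
    _, truth = simulate_expression(geno, cfg)
    assert truth.planted_cis == {("s00001", "p00000", 0.5)}
    assert truth.planted_trans == {("s00007", "p00004", 0.3)}


def test_planted_index_out_of_bounds_names_field():
    cfg = SimulationConfig(n_individuals=10, n_snps=5, n_probes=2, seed=1)
    cfg.cis_effects = [(9, 0, 1.0)]
    with pytest.raises(ConfigurationError, match="cis_effects"):
        simulate_genotypes(cfg)


def test_trait_null_and_noiseless_limits(small_cohort):
    cohort = small_cohort
    n = cohort.expression.n_samples
    cfg_null = SimulationConfig(
        n_individuals=n, n_snps=60, n_probes=12,
        trait_models=[("null_t", "probe", 0, 0.0, 1.0)], seed=20201,
    )
    traits = simulate_traits(cohort.expression, cohort.genotypes, cfg_null)
    r = np.corrcoef(traits["null_t"], cohort.expression.values[:, 0])[0, 1]
    assert abs(r) < 3 / np.sqrt(n)

    cfg_exact = SimulationConfig(
        n_individuals=n, n_snps=60, n_probes=12,
        trait_models=[("exact_t", "probe", 2, 2.0, 0.0)], seed=20201,
    )
    traits = simulate_traits(cohort.expression, cohort.genotypes, cfg_exact)
    assert np.allclose(traits["exact_t"], 2.0 * cohort.expression.values[:, 2])


def test_trait_r2_matches_closed_form():
    """With trait = source + N(0,1), r^2 ~ var_s / (var_s + 1)."""
    cfg = SimulationConfig(
        n_individuals=1000, n_snps=5, n_probes=3,
        trait_models=[("t", "probe", 0, 1.0, 1.0)], seed=31,
    )
    geno = simulate_genotypes(cfg)
    expr, _ = simulate_expression(geno, cfg)
    traits = simulate_traits(expr, geno, cfg)
    source = expr.values[:, 0]
    var_s = source.var()
    r = np.corrcoef(traits["t"], source)[0, 1]
    expected = var_s / (var_s + 1.0)
    assert r**2 == pytest.approx(expected, abs=4 / np.sqrt(cfg.n_individuals))


def test_unknown_trait_source_raises():
    cfg = SimulationConfig(n_individuals=10, n_snps=5, n_probes=2, seed=1)
    cfg.trait_models = [("t", "probe", 7, 1.0, 1.0)]
    geno = simulate_genotypes(SimulationConfig(n_individuals=10, n_snps=5, n_probes=2, seed=1))
    expr, _ = simulate_expression(geno, SimulationConfig(n_individuals=10, n_snps=5, n_probes=2, seed=1))
    with pytest.raises(ConfigurationError, match="trait_models"):
        simulate_traits(expr, geno, cfg)


def test_replication_cohort_shares_truth_but_not_data(small_cohort):
    cfg = SimulationConfig(
        n_individuals=400, n_snps=60, n_probes=12,
        cis_effects=[(15, 0, 0.8)],
        trans_hotspots=[(35, [5, 6, 7], [0.6, 0.6, -0.6])],
        n_confounders=2,
        trait_models=[("trait_a", "probe", 5, 1.0, 1.0), ("trait_b", "snp", 35, 0.5, 1.0)],
        seed=20201,
    )
    geno_a, expr_a = simulate_replication_cohort(small_cohort.truth, cfg, new_seed=1)
    geno_b, expr_b = simulate_replication_cohort(small_cohort.truth, cfg, new_seed=2)
    assert not np.array_equal(geno_a.dosages, geno_b.dosages)
    # same population frequencies
    assert np.all(np.abs(geno_a.maf() - small_cohort.truth.snp_mafs) < 0.1)
    # planted effect sign is preserved in both cohorts
    for geno, expr in ((geno_a, expr_a), (geno_b, expr_b)):
        res = regress_single(geno.dosages[:, 15], expr.values[:, 0])
        assert res.beta > 0


def test_probe_annotation_places_cis_probes_near_their_snp():
    cfg = SimulationConfig(n_individuals=10, n_snps=50, n_probes=5,
                           cis_effects=[(20, 1, 0.5)], seed=1)
    annot = probe_annotation(cfg)
    assert annot.loc[1, "chrom"] == "1"
    snp_pos = 20 * 10_000
    assert abs(annot.loc[1, "tx_start"] - snp_pos) <= 500_000
    assert (annot.drop(index=1)["chrom"] == "2").all()


def test_maf_override_validated():
    cfg = SimulationConfig(n_individuals=10, n_snps=4, n_probes=1, seed=1)
    with pytest.raises(ConfigurationError, match="mafs"):
        simulate_genotypes(cfg, mafs=np.array([0.1, 0.2]))
    mafs = sample_block_mafs(cfg)
    assert mafs.shape == (4,)
    assert np.all((mafs > 0.05) & (mafs < 0.5))
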