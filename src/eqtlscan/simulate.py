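"""Synthetic genotype/expression/trait cohorts with a planted-truth ledger.

The generator emulates the statistical structure a whole-blood eQTL analysis
assumes: Hardy-Weinberg genotypes at common allele frequencies, blockwise
linkage disequilibrium, additive cis effects on probes within 500 kb of the
transcript, trans "hotspot" SNPs driving many distant probes, latent expression
confounders, and traits driven by a probe or a SNP.  A replication cohort can
be drawn from the same truth (same allele frequencies and planted effect map,
independent individuals).

LD model: within each block all SNPs share one sampled MAF and each haplotype
allele is copied from its left neighbour with probability ``ld_decay`` (fresh
Bernoulli draw otherwise).  This "sequential correlated-allele" scheme keeps
every SNP exactly in HWE and gives dosage correlation ``ld_decay ** lag``
between SNPs ``lag`` apart in a block; blocks are mutually independent.

Genome layout: SNPs sit on chromosome "1" every 10 kb.  Probes default to
chromosome "2" (so un-planted and hotspot-target probes are trans to every
SNP); a probe carrying a planted cis effect is relocated to chromosome "1"
1 kb downstream of its SNP, inside the 500 kb cis window.

RNG: one ``SeedSequence(config.seed)`` spawns four child streams in fixed
order (MAF draws, haplotype draws, expression draws, trait draws), so each
stage is reproducible and a replication cohort can re-seed only the haplotype
and noise streams.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .types import ConfigurationError, ExpressionMatrix, GenotypeMatrix

SNP_SPACING = 10_000
PROBE_SPACING = 100_000
PROBE_LENGTH = 1_000
CIS_OFFSET = 1_000

_STREAM_MAF, _STREAM_HAP, _STREAM_EXPR, _STREAM_TRAIT = range(4)


def _streams(seed: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(4)
    return [np.random.default_rng(c) for c in children]


@dataclass
class SimulationTruth:
    """Ledger of everything planted in a simulated cohort."""

    planted_cis: set[tuple[str, str, float]] = field(default_factory=set)
    planted_trans: set[tuple[str, str, float]] = field(default_factory=set)
    confounder_loadings: np.ndarray | None = None
    trait_edges: set[tuple[str, str, float]] = field(default_factory=set)
    snp_mafs: np.ndarray | None = None

    def planted_pairs(self) -> set[tuple[str, str]]:
        return {(s, p) for s, p, _ in self.planted_cis | self.planted_trans}


def snp_map(config: SimulationConfig) -> pd.DataFrame:
    ids = [f"s{j:05d}" for j in range(config.n_snps)]
    return pd.DataFrame(
        {
            "snp_id": ids,
            "chrom": "1",
            "pos": np.arange(config.n_snps, dtype=int) * SNP_SPACING,
            "ref": "A",
            "alt": "G",
        }
    )


def probe_annotation(config: SimulationConfig) -> pd.DataFrame:
    """BED-like probe annotation matching the simulated genome layout."""
    n = config.n_probes
    annot = pd.DataFrame(
        {
            "probe_id": [f"p{k:05d}" for k in range(n)],
            "gene": [f"G{k:05d}" for k in range(n)],
            "chrom": ["2"] * n,
            "tx_start": np.arange(n, dtype=int) * PROBE_SPACING,
            "tx_end": np.arange(n, dtype=int) * PROBE_SPACING + PROBE_LENGTH,
            "strand": ["+"] * n,
        }
    )
    for snp_idx, probe_idx, _beta in config.cis_effects:
        start = snp_idx * SNP_SPACING + CIS_OFFSET
        annot.loc[probe_idx, ["chrom", "tx_start", "tx_end"]] = ["1", start, start + PROBE_LENGTH]
    return annot


def sample_block_mafs(config: SimulationConfig) -> np.ndarray:
    """Per-SNP MAFs, constant within each LD block, from the MAF stream."""
    rng = _streams(config.seed)[_STREAM_MAF]
    m, bs = config.n_snps, config.ld_block_size
    n_blocks = -(-m // bs) if m else 0
    lo, hi = config.maf_range
    block_mafs = rng.uniform(lo, hi, size=n_blocks)
    return np.repeat(block_mafs, bs)[:m]


def simulate_genotypes(
    config: SimulationConfig,
    *,
    mafs: np.ndarray | None = None,
    haplotype_seed: int | None = None,
) -> GenotypeMatrix:
    """Draw HWE genotypes with blockwise LD.

    ``mafs`` overrides the sampled per-SNP allele frequencies (must be
    constant within each LD block to keep marginal frequencies exact);
    ``haplotype_seed`` re-seeds only the haplotype stream, which is how an
    independent cohort is drawn from the same population.
    """
    config.validate()
    n, m, bs = config.n_individuals, config.n_snps, config.ld_block_size
    if mafs is None:
        mafs = sample_block_mafs(config)
    else:
        mafs = np.asarray(mafs, dtype=float)
        if mafs.shape != (m,):
            raise ConfigurationError(f"mafs: expected {m} values, got {mafs.shape}")
        if np.any((mafs <= 0) | (mafs > 0.5)):
            raise ConfigurationError("mafs: all values must be in (0, 0.5]")
    if haplotype_seed is None:
        hap_rng = _streams(config.seed)[_STREAM_HAP]
    else:
        hap_rng = np.random.default_rng(np.random.SeedSequence(haplotype_seed))

    dosages = np.zeros((n, m))
    for _hap in range(2):
        fresh = (hap_rng.uniform(size=(n, m)) < mafs[None, :]).astype(float)
        copy = hap_rng.uniform(size=(n, m)) < config.ld_decay
        alleles = fresh
        # within-block Markov copy; vectorized over blocks, sequential in lag
        for i in range(1, bs):
            idx = np.arange(i, m, bs)
            if idx.size == 0:
                break
            alleles[:, idx] = np.where(copy[:, idx], alleles[:, idx - 1], fresh[:, idx])
        dosages += alleles
    geno = GenotypeMatrix(
        dosages=dosages, samples=[f"i{r:05d}" for r in range(n)], snps=snp_map(config)
    )
    geno.population_mafs = mafs.copy()  # generation-time frequencies, for replication draws
    return geno


def _planted_effects(config: SimulationConfig) -> list[tuple[int, int, float, str]]:
    """Flatten planted effects as (snp_idx, probe_idx, beta, class)."""
    out = [(s, p, b, "cis") for s, p, b in config.cis_effects]
    for snp_idx, targets, betas in config.trans_hotspots:
        out.extend((snp_idx, p, b, "trans") for p, b in zip(targets, betas))
    return out


def simulate_expression(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    *,
    loadings: np.ndarray | None = None,
    noise_seed: int | None = None,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Expression = planted additive genetic effects (beta x centered dosage)
    + confounder loadings x latent factors + Gaussian noise.

    ``loadings``/``noise_seed`` let a replication cohort reuse the discovery
    confounder structure while drawing fresh factors and noise.
    """
    config.validate()
    n, p, k = genotypes.n_samples, config.n_probes, config.n_confounders
    if n != config.n_individuals:
        raise ConfigurationError("n_individuals: genotype sample count does not match config")
    if noise_seed is None:
        rng = _streams(config.seed)[_STREAM_EXPR]
    else:
        rng = np.random.default_rng(np.random.SeedSequence(noise_seed))
    # draw order: loadings, factors, noise
    drawn_loadings = rng.standard_normal((p, k))
    if loadings is None:
        loadings = drawn_loadings
    else:
        loadings = np.asarray(loadings, dtype=float)
        if loadings.shape != (p, k):
            raise ConfigurationError(f"confounder loadings must have shape {(p, k)}")
    factors = rng.standard_normal((n, k)) * config.confounder_sd
    values = rng.standard_normal((n, p)) * config.noise_sd
    if k:
        values += factors @ loadings.T

    pop_mafs = getattr(genotypes, "population_mafs", None)
    truth = SimulationTruth(
        confounder_loadings=loadings,
        snp_mafs=pop_mafs.copy() if pop_mafs is not None else genotypes.maf().copy(),
    )
    snp_ids = list(genotypes.snps["snp_id"])
    probe_ids = [f"p{j:05d}" for j in range(p)]
    for snp_idx, probe_idx, beta, klass in _planted_effects(config):
        if not (0 <= snp_idx < genotypes.n_snps):
            raise ConfigurationError(f"cis_effects/trans_hotspots: snp_index {snp_idx} out of bounds")
        dosage = genotypes.dosages[:, snp_idx]
        centered = dosage - np.nanmean(dosage)
        values[:, probe_idx] += beta * np.nan_to_num(centered)
        if beta != 0.0:
            entry = (snp_ids[snp_idx], probe_ids[probe_idx], float(beta))
            (truth.planted_cis if klass == "cis" else truth.planted_trans).add(entry)

    expr = ExpressionMatrix(values=values, samples=list(genotypes.samples), probes=probe_ids)
    return expr, truth


def simulate_traits(
    expr: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    truth: SimulationTruth | None = None,
) -> pd.DataFrame:
    """Trait table (samples x traits): trait = beta x source column + noise."""
    config.validate()
    rng = _streams(config.seed)[_STREAM_TRAIT]
    n = expr.n_samples
    traits = {}
    for name, kind, index, beta, trait_sd in config.trait_models:
        if kind == "probe":
            if index >= expr.n_probes:
                raise ConfigurationError(f"trait_models: {name}: probe index {index} out of bounds")
            source = expr.values[:, index]
            source_id = expr.probes[index]
        elif kind == "snp":
            if index >= genotypes.n_snps:
                raise ConfigurationError(f"trait_models: {name}: snp index {index} out of bounds")
            source = genotypes.dosages[:, index]
            source_id = genotypes.snps["snp_id"].iloc[index]
        else:
            raise ConfigurationError(f"trait_models: {name}: unknown source kind {kind!r}")
        traits[name] = beta * source + rng.standard_normal(n) * trait_sd
        if truth is not None and beta != 0.0:
            truth.trait_edges.add((name, source_id, float(beta)))
    return pd.DataFrame(traits, index=list(expr.samples))


def simulate_replication_cohort(
    truth: SimulationTruth,
    config: SimulationConfig,
    new_seed: int,
    n_individuals: int | None = None,
) -> tuple[GenotypeMatrix, ExpressionMatrix]:
    """Independent individuals drawn from the same truth: same allele
    frequencies, LD structure, planted effect map and confounder loadings;
    fresh haplotypes, factors and noise."""
    if truth.snp_mafs is None:
        raise ConfigurationError("truth: missing snp_mafs (not produced by simulate_expression?)")
    cfg = replace(config, n_individuals=n_individuals or config.n_individuals)
    derive = np.random.default_rng(np.random.SeedSequence(new_seed))
    hap_seed, noise_seed = (int(s) for s in derive.integers(2**31 - 1, size=2))
    geno = simulate_genotypes(cfg, mafs=truth.snp_mafs, haplotype_seed=hap_seed)
    expr, _ = simulate_expression(
        geno, cfg, loadings=truth.confounder_loadings, noise_seed=noise_seed
    )
    return geno, expr


@dataclass
class Cohort:
    """Bundle returned by :func:`simulate_cohort`."""

    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    annotation: pd.DataFrame
    traits: pd.DataFrame
    truth: SimulationTruth


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Convenience wrapper: genotypes + expression + annotation + traits."""
    geno = simulate_genotypes(config)
    expr, truth = simulate_expression(geno, config)
    traits = simulate_traits(expr, geno, config, truth)
    return Cohort(geno, expr, probe_annotation(config), traits, truth)
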