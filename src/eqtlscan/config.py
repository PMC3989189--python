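"""Configuration objects for the simulator and the analysis pipeline.

Both configs round-trip through flat YAML files so that every CLI stage can be
driven from a single config.  Defaults encode the discovery-study conditions:
890 individuals, MAF in (0.05, 0.5], a 500 kb cis window, Bonferroni at
alpha = 0.05, 55/25 expression PCs for the cis/trans scans and 50/25 at
replication, LD pruning at r^2 > 0.5 and master-regulator loci defined by
five or more distinct target genes.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .types import ConfigurationError


def _check(condition: bool, fieldname: str, message: str) -> None:
    if not condition:
        raise ConfigurationError(f"{fieldname}: {message}")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic genotype/expression/trait cohort.

    ``cis_effects`` entries are ``(snp_index, probe_index, beta)``;
    ``trans_hotspots`` entries are ``(snp_index, [probe_index, ...],
    [beta, ...])``; ``trait_models`` entries are
    ``(trait_name, source_kind, source_index, beta, noise_sd)`` with
    ``source_kind`` one of ``"probe"`` or ``"snp"``.  Betas are in units of
    expression SD per ALT-allele copy.
    """

    n_individuals: int = 890
    n_snps: int = 200
    n_probes: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_decay: float = 0.95
    cis_effects: list[tuple[int, int, float]] = field(default_factory=list)
    trans_hotspots: list[tuple[int, list[int], list[float]]] = field(default_factory=list)
    n_confounders: int = 0
    confounder_sd: float = 1.0
    noise_sd: float = 1.0
    trait_models: list[tuple[str, str, int, float, float]] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        _check(self.n_individuals >= 0, "n_individuals", "must be >= 0")
        _check(self.n_snps >= 0, "n_snps", "must be >= 0")
        _check(self.n_probes >= 0, "n_probes", "must be >= 0")
        lo, hi = self.maf_range
        _check(0.0 < lo <= hi <= 0.5, "maf_range", "must satisfy 0 < lo <= hi <= 0.5")
        _check(self.ld_block_size >= 1, "ld_block_size", "must be >= 1")
        _check(0.0 <= self.ld_decay < 1.0, "ld_decay", "must be in [0, 1)")
        _check(self.noise_sd > 0.0, "noise_sd", "must be > 0")
        _check(self.confounder_sd > 0.0, "confounder_sd", "must be > 0")
        _check(self.n_confounders >= 0, "n_confounders", "must be >= 0")
        for snp, probe, _beta in self.cis_effects:
            _check(0 <= snp < self.n_snps, "cis_effects", f"snp_index {snp} out of bounds")
            _check(0 <= probe < self.n_probes, "cis_effects", f"probe_index {probe} out of bounds")
        probes_with_cis = [p for _, p, _ in self.cis_effects]
        _check(
            len(probes_with_cis) == len(set(probes_with_cis)),
            "cis_effects",
            "one planted cis effect per probe (probe placement is per effect)",
        )
        for snp, targets, betas in self.trans_hotspots:
            _check(0 <= snp < self.n_snps, "trans_hotspots", f"snp_index {snp} out of bounds")
            _check(len(targets) == len(betas), "trans_hotspots", "targets and betas differ in length")
            for probe in targets:
                _check(
                    0 <= probe < self.n_probes,
                    "trans_hotspots",
                    f"probe_index {probe} out of bounds",
                )
        for name, kind, index, _beta, trait_sd in self.trait_models:
            _check(kind in ("probe", "snp"), "trait_models", f"{name}: source_kind must be probe|snp")
            bound = self.n_probes if kind == "probe" else self.n_snps
            _check(0 <= index < bound, "trait_models", f"{name}: source index {index} out of bounds")
            _check(trait_sd >= 0.0, "trait_models", f"{name}: noise_sd must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["maf_range"] = list(self.maf_range)
        d["cis_effects"] = [list(e) for e in self.cis_effects]
        d["trans_hotspots"] = [[s, list(t), list(b)] for s, t, b in self.trans_hotspots]
        d["trait_models"] = [list(t) for t in self.trait_models]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        if "cis_effects" in d:
            d["cis_effects"] = [tuple(e) for e in d["cis_effects"]]
        if "trans_hotspots" in d:
            d["trans_hotspots"] = [(s, list(t), list(b)) for s, t, b in d["trans_hotspots"]]
        if "trait_models" in d:
            d["trait_models"] = [tuple(t) for t in d["trait_models"]]
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown simulation config fields: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class AnalysisConfig:
    """Thresholds and tuning knobs of the discovery/replication pipeline."""

    cis_flank: int = 500_000
    alpha: float = 0.05
    n_pc_cis: int = 55
    n_pc_trans: int = 25
    n_pc_cis_replication: int = 50
    maf_min: float = 0.05
    callrate_min: float = 0.95
    hwe_p_min: float = 1e-6
    ld_prune_r2: float = 0.5
    proxy_r2_min: float = 0.8
    proxy_window: int = 500_000
    master_min_targets: int = 5
    multi_target_min: int = 2
    pc_assoc_alpha: float = 0.05
    pair_budget: int = 20_000_000

    def validate(self) -> None:
        _check(self.cis_flank > 0, "cis_flank", "must be > 0")
        _check(0.0 < self.alpha < 1.0, "alpha", "must be in (0, 1)")
        for name in ("n_pc_cis", "n_pc_trans", "n_pc_cis_replication"):
            _check(getattr(self, name) >= 0, name, "must be >= 0")
        _check(0.0 <= self.maf_min < 0.5, "maf_min", "must be in [0, 0.5)")
        _check(0.0 <= self.callrate_min <= 1.0, "callrate_min", "must be in [0, 1]")
        _check(0.0 <= self.hwe_p_min <= 1.0, "hwe_p_min", "must be in [0, 1]")
        _check(0.0 <= self.ld_prune_r2 <= 1.0, "ld_prune_r2", "must be in [0, 1]")
        _check(0.0 <= self.proxy_r2_min <= 1.0, "proxy_r2_min", "must be in [0, 1]")
        _check(self.proxy_window > 0, "proxy_window", "must be > 0")
        _check(self.master_min_targets >= 1, "master_min_targets", "must be >= 1")
        _check(self.multi_target_min >= 1, "multi_target_min", "must be >= 1")
        _check(0.0 <= self.pc_assoc_alpha <= 1.0, "pc_assoc_alpha", "must be in [0, 1]")
        _check(self.pair_budget > 0, "pair_budget", "must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown analysis config fields: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


def load_config(path: str | Path) -> dict:
    """Load a YAML config file with optional ``simulation:`` / ``analysis:``
    sections; returns ``{"simulation": SimulationConfig|None,
    "analysis": AnalysisConfig}``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.get("simulation")
    ana = raw.get("analysis", {})
    return {
        "simulation": SimulationConfig.from_dict(sim) if sim is not None else None,
        "analysis": AnalysisConfig.from_dict(ana),
    }


def save_config(
    path: str | Path,
    simulation: SimulationConfig | None = None,
    analysis: AnalysisConfig | None = None,
) -> None:
    payload: dict = {}
    if simulation is not None:
        payload["simulation"] = simulation.to_dict()
    if analysis is not None:
        payload["analysis"] = analysis.to_dict()
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
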