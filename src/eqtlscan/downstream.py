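"""Post-calling analyses: trans hotspots, cross-study overlap, triangles.

* Master regulatory loci: confirmed trans loci whose distinct target-gene
  count reaches a threshold (default five or more genes; probes stand in for
  genes where no gene is assigned).  Loci with two or more targets are listed
  in a companion multi-target report.
* Gene overlap: the share of this study's significant cis-eQTL genes that a
  compared study also finds, as an integer percentage of a fixed denominator.
* Triangular association: the three marginal OLS edges among a SNP, a
  transcript and a trait (transcript~SNP, trait~SNP, trait~transcript), with
  a verdict flag when all three reach the stated alpha.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import AssociationResult, regress_single
from .replicate import percent
from .types import ExpressionMatrix, GenotypeMatrix


def detect_master_loci(
    trans_calls: pd.DataFrame,
    locus_table: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    min_targets: int = 5,
    multi_target_min: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count distinct target genes per trans locus.

    Returns ``(master_loci, multi_target_loci)``: loci with at least
    ``min_targets`` distinct target genes, and the broader report of loci
    with at least ``multi_target_min``.  Probe ids are used as targets for
    calls without a gene assignment.
    """
    if len(trans_calls) == 0:
        empty = pd.DataFrame(columns=["locus_id", "lead_snp", "n_targets", "target_genes"])
        return empty, empty.copy()
    calls = trans_calls.copy()
    if "gene" not in calls.columns and annotation is not None:
        calls = calls.merge(annotation[["probe_id", "gene"]], on="probe_id", how="left")
    if "gene" not in calls.columns:
        calls["gene"] = ""
    calls["target"] = calls["gene"].fillna("")
    blank = calls["target"] == ""
    calls.loc[blank, "target"] = calls.loc[blank, "probe_id"]

    rows = []
    lead_by_locus = dict(zip(locus_table["locus_id"], locus_table["lead_snp"]))
    for locus_id, group in calls.groupby("locus_id", sort=False):
        targets = sorted(group["target"].unique())
        rows.append(
            {
                "locus_id": locus_id,
                "lead_snp": lead_by_locus.get(locus_id, ""),
                "n_targets": len(targets),
                "target_genes": ",".join(targets),
            }
        )
    table = pd.DataFrame(rows).sort_values("n_targets", ascending=False).reset_index(drop=True)
    master = table[table["n_targets"] >= min_targets].reset_index(drop=True)
    multi = table[table["n_targets"] >= multi_target_min].reset_index(drop=True)
    return master, multi


def gene_overlap(
    own_genes: set[str] | None = None,
    other_genes: set[str] | None = None,
    shared_annotated: int | None = None,
    denominator: int | None = None,
) -> int:
    """Cross-study overlap: integer percent of shared significant genes.

    Either pass the two gene sets, or pass the pre-computed
    ``shared_annotated`` count directly (published studies often report only
    counts).  The denominator defaults to the size of this study's gene set.
    """
    if shared_annotated is None:
        if own_genes is None or other_genes is None:
            raise ValueError("need either both gene sets or shared_annotated")
        shared_annotated = len(set(own_genes) & set(other_genes))
    if denominator is None:
        if own_genes is None:
            raise ValueError("need a denominator (or own_genes to derive it)")
        denominator = len(set(own_genes))
    if denominator == 0:
        raise ValueError("overlap denominator is zero")
    return percent(shared_annotated, denominator)


@dataclass
class TriangleResult:
    """Three marginal association edges among a SNP, a transcript and a trait."""

    snp_id: str
    probe_id: str
    trait: str
    snp_transcript: AssociationResult
    snp_trait: AssociationResult
    transcript_trait: AssociationResult
    alpha: float

    @property
    def verdict(self) -> bool:
        edges = (self.snp_transcript, self.snp_trait, self.transcript_trait)
        return all((not e.degenerate or e.p_floored) and e.p <= self.alpha for e in edges)


def triangular_test(
    genotypes: GenotypeMatrix,
    expr: ExpressionMatrix,
    traits: pd.DataFrame,
    snp_id: str,
    probe_id: str,
    trait: str,
    alpha: float = 0.05,
) -> TriangleResult:
    """Test the SNP-transcript-trait triangle with three OLS edges on
    pairwise-complete cases."""
    snp_idx = genotypes.snp_index()
    probe_idx = expr.probe_index()
    if snp_id not in snp_idx:
        raise KeyError(f"unknown snp_id: {snp_id}")
    if probe_id not in probe_idx:
        raise KeyError(f"unknown probe_id: {probe_id}")
    if trait not in traits.columns:
        raise KeyError(f"unknown trait: {trait}")
    x = genotypes.dosages[:, snp_idx[snp_id]]
    y = expr.values[:, probe_idx[probe_id]]
    z = traits[trait].to_numpy(dtype=float)
    return TriangleResult(
        snp_id=snp_id,
        probe_id=probe_id,
        trait=trait,
        snp_transcript=regress_single(x, y, snp_id, probe_id),
        snp_trait=regress_single(x, z, snp_id, trait),
        transcript_trait=regress_single(y, z, probe_id, trait),
        alpha=alpha,
    )
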