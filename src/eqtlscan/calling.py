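"""Turn an association stream into called eQTLs.

Significance is family-wise Bonferroni: the cis threshold divides alpha by the
number of enumerated cis pairs, the trans threshold by the number of trans
tests; thresholds are carried at full precision and rounded to three
significant figures only for display.  Within each probe's cis window only the
smallest-p SNP is flagged as lead.  Trans associations are first cleansed of
SNPs in high LD (r^2 > 0.5) with any significant cis SNP and then greedily
clumped into loci: SNPs are processed by ascending best p-value and join an
existing locus when r^2 with the locus lead exceeds the pruning threshold,
otherwise they found a new locus.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import GenotypeMatrix


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def format_threshold(value: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (display only)."""
    if value == 0:
        return 0.0
    from math import floor, log10

    exp = floor(log10(abs(value)))
    return round(value, -exp + sig - 1)


@dataclass
class ThresholdSet:
    alpha: float
    n_cis_tests: int
    n_trans_tests: int

    @property
    def cis_threshold(self) -> float:
        return bonferroni_threshold(self.n_cis_tests, self.alpha)

    @property
    def trans_threshold(self) -> float:
        return bonferroni_threshold(self.n_trans_tests, self.alpha)


def _merge_snp_columns(calls: pd.DataFrame, snps: pd.DataFrame) -> pd.DataFrame:
    cols = snps[["snp_id", "chrom", "pos"]].rename(
        columns={"chrom": "snp_chrom", "pos": "snp_pos"}
    )
    return calls.merge(cols, on="snp_id", how="left")


def call_cis(
    assocs: pd.DataFrame,
    threshold: float,
    snps: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Significant cis calls with one lead SNP per probe.

    ``assocs`` must already be restricted to enumerated cis pairs.  All pairs
    with p <= threshold are retained; per probe the smallest-p SNP is flagged
    ``lead`` (ties broken by smaller position, then snp_id).
    """
    sig = assocs.loc[~assocs["degenerate"] & (assocs["p"] <= threshold)].copy()
    sig = _merge_snp_columns(sig, snps)
    sig["class"] = "cis"
    sig["lead"] = False
    if len(sig):
        sig = sig.sort_values(["probe_id", "p", "snp_pos", "snp_id"], kind="stable")
        lead_idx = sig.groupby("probe_id", sort=False).head(1).index
        sig.loc[lead_idx, "lead"] = True
        sig = sig.sort_values(["p", "snp_id"], kind="stable").reset_index(drop=True)
    if annotation is not None:
        sig = sig.merge(
            annotation[["probe_id", "gene", "chrom"]].rename(columns={"chrom": "probe_chrom"}),
            on="probe_id",
            how="left",
        )
    return sig


def ld_r2(dosage1: np.ndarray, dosage2: np.ndarray) -> float:
    """Composite LD: squared Pearson correlation of dosages, complete cases.

    Returns NaN (flagged missing) when fewer than 3 complete pairs remain or
    either vector is constant.
    """
    x = np.asarray(dosage1, dtype=float)
    y = np.asarray(dosage2, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if x.size < 3 or np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _r2_matrix(genotypes: GenotypeMatrix, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    """r^2 between two SNP index sets (complete data assumed columnwise)."""
    from .association import pairwise_stats

    A = genotypes.dosages[:, idx_a]
    B = genotypes.dosages[:, idx_b]
    st = pairwise_stats(A, B)
    # r^2 = t^2 / (t^2 + df); avoids recomputing correlations
    t2 = st["t"] ** 2
    df = st["n"] - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(np.isinf(t2), 1.0, t2 / (t2 + df))
    r2 = np.where(st["degenerate"] & ~np.isinf(t2), np.nan, r2)
    return r2


def prune_trans(
    assocs: pd.DataFrame,
    threshold: float,
    cis_calls: pd.DataFrame,
    genotypes: GenotypeMatrix,
    r2_prune: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Threshold, cis-LD-prune and clump trans associations into loci.

    Returns ``(trans_calls, locus_table, dropped_snp_ids)``.  ``trans_calls``
    carries ``locus_id`` and a ``lead`` flag on rows of the locus lead SNP;
    ``locus_table`` has one row per locus with its member SNPs.
    """
    sig = assocs.loc[~assocs["degenerate"] & (assocs["p"] <= threshold)].copy()
    sig = _merge_snp_columns(sig, genotypes.snps)
    sig["class"] = "trans"
    snp_col = genotypes.snp_index()

    # step 1: drop SNPs in high LD with any significant cis SNP
    dropped: list[str] = []
    if len(sig) and len(cis_calls):
        trans_snps = sig["snp_id"].unique()
        cis_snps = cis_calls["snp_id"].unique()
        t_idx = np.array([snp_col[s] for s in trans_snps])
        c_idx = np.array([snp_col[s] for s in cis_snps])
        r2 = _r2_matrix(genotypes, t_idx, c_idx)
        with np.errstate(invalid="ignore"):
            conflicted = np.nanmax(r2, axis=1) > r2_prune
        dropped = [s for s, bad in zip(trans_snps, conflicted) if bad]
        sig = sig[~sig["snp_id"].isin(dropped)]

    sig["locus_id"] = ""
    sig["lead"] = False
    loci: list[dict] = []
    if len(sig):
        # step 2: greedy clumping by ascending best p per SNP
        best = (
            sig.groupby("snp_id", sort=False)
            .agg(best_p=("p", "min"), pos=("snp_pos", "first"))
            .reset_index()
            .sort_values(["best_p", "pos", "snp_id"], kind="stable")
        )
        lead_ids: list[str] = []
        lead_idx: list[int] = []
        membership: dict[str, str] = {}
        members: dict[str, list[str]] = {}
        for _, row in best.iterrows():
            sid = row["snp_id"]
            j = snp_col[sid]
            joined = None
            if lead_idx:
                r2 = _r2_matrix(genotypes, np.array([j]), np.array(lead_idx))[0]
                with np.errstate(invalid="ignore"):
                    candidates = np.flatnonzero(np.nan_to_num(r2) > r2_prune)
                if candidates.size:
                    joined = candidates[np.argmax(r2[candidates])]
            if joined is None:
                locus_id = f"L{len(lead_ids):03d}"
                lead_ids.append(sid)
                lead_idx.append(j)
                members[locus_id] = [sid]
                membership[sid] = locus_id
            else:
                locus_id = f"L{joined:03d}"
                members[locus_id].append(sid)
                membership[sid] = locus_id
        sig["locus_id"] = sig["snp_id"].map(membership)
        sig["lead"] = sig["snp_id"].isin(lead_ids)
        for i, lead in enumerate(lead_ids):
            locus_id = f"L{i:03d}"
            locus_rows = sig[sig["locus_id"] == locus_id]
            loci.append(
                {
                    "locus_id": locus_id,
                    "lead_snp": lead,
                    "n_snps": locus_rows["snp_id"].nunique(),
                    "n_pairs": len(locus_rows),
                    "best_p": float(locus_rows["p"].min()),
                    "members": ",".join(members[locus_id]),
                }
            )
        sig = sig.sort_values(["p", "snp_id"], kind="stable").reset_index(drop=True)
    locus_table = pd.DataFrame(loci, columns=["locus_id", "lead_snp", "n_snps", "n_pairs", "best_p", "members"])
    return sig, locus_table, dropped


def summarize_discovery(
    cis_calls: pd.DataFrame,
    trans_calls: pd.DataFrame,
    locus_table: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
) -> dict:
    """Headline discovery counts: total = cis calls + trans loci.

    ``n_multiprobe`` counts genes supported by two or more distinct
    significant probes; ``n_unassigned`` counts cis calls without a gene.
    """
    n_cis = len(cis_calls)
    n_trans_pairs = len(trans_calls)
    n_trans_loci = len(locus_table)
    n_genes = n_multiprobe = n_unassigned = 0
    if n_cis:
        calls = cis_calls
        if "gene" not in calls.columns and annotation is not None:
            calls = calls.merge(annotation[["probe_id", "gene"]], on="probe_id", how="left")
        if "gene" in calls.columns:
            gene = calls["gene"].fillna("")
            n_unassigned = int((gene == "").sum())
            assigned = calls.loc[gene != ""]
            n_genes = assigned["gene"].nunique()
            probes_per_gene = assigned.groupby("gene")["probe_id"].nunique()
            n_multiprobe = int((probes_per_gene >= 2).sum())
    return {
        "n_cis": n_cis,
        "n_trans_pairs": n_trans_pairs,
        "n_trans_loci": n_trans_loci,
        "n_total": n_cis + n_trans_loci,
        "n_genes": n_genes,
        "n_multiprobe": n_multiprobe,
        "n_unassigned": n_unassigned,
    }
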