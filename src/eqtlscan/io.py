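"""Readers and writers for the formats the pipeline touches.

Genotypes: VCF 4.x (GT field only, single ALT) via cyvcf2, or a dosage TSV
(samples x SNPs, 0/1/2, empty or NA = missing) with a companion SNP-map TSV.
Probe annotation: BED-like TSV with 0-based half-open intervals.  Expression
and traits: TSV with samples as rows and a header row.  Results: tidy TSV
ordered by ascending p then snp_id.  All readers validate rather than coerce;
skipped records are counted and logged.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    ANNOTATION_COLUMNS,
    ExpressionMatrix,
    GenotypeMatrix,
    SNP_MAP_COLUMNS,
    validate_probe_annotation,
)

logger = logging.getLogger(__name__)

RESULT_TSV_COLUMNS = [
    "snp_id", "snp_chrom", "probe_id", "gene", "probe_chrom",
    "class", "n", "beta", "se", "p", "locus_id",
]


# ---------------------------------------------------------------- genotypes

def read_genotypes(path: str | Path, format: str | None = None,
                   snp_map: str | Path | None = None) -> GenotypeMatrix:
    """Read genotypes from VCF or dosage TSV (auto-detected by extension)."""
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix == ".vcf" or path.name.endswith(".vcf.gz") else "dosage-tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage-tsv":
        if snp_map is None:
            raise ValueError("dosage TSV requires a companion SNP map path")
        return _read_dosage_tsv(path, snp_map)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, records = [], []
    n_skipped_multiallelic = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped_multiallelic += 1
            continue
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = np.asarray(var.gt_types, dtype=float)
        dosage = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        rows.append(dosage)
        records.append(
            {
                "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS) - 1,  # VCF is 1-based; 0-based internally
                "ref": var.REF,
                "alt": var.ALT[0],
            }
        )
    if n_skipped_multiallelic:
        logger.warning("skipped %d multi-allelic VCF records", n_skipped_multiallelic)
    dosages = np.array(rows).T if rows else np.empty((len(samples), 0))
    snps = pd.DataFrame(records, columns=SNP_MAP_COLUMNS)
    return GenotypeMatrix(dosages=dosages, samples=samples, snps=snps)


def _read_dosage_tsv(path: Path, snp_map_path: str | Path) -> GenotypeMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    values = frame.to_numpy(dtype=float)
    bad = ~(np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"non-integer dosage {values[i, j]!r} at sample {frame.index[i]!r}, "
            f"SNP {frame.columns[j]!r} (line {i + 2})"
        )
    snps = pd.read_csv(snp_map_path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SNP_MAP_COLUMNS if c not in snps.columns]
    if missing:
        raise ValueError(f"SNP map lacks columns: {missing}")
    if list(frame.columns) != list(snps["snp_id"]):
        raise ValueError("dosage TSV columns do not match SNP map snp_id order")
    return GenotypeMatrix(dosages=values, samples=[str(s) for s in frame.index], snps=snps)


def write_genotypes_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write genotypes as a minimal single-ALT GT-only VCF 4.2 file."""
    code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(genotypes.snps["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(s) for s in genotypes.samples) + "\n")
        for j, row in genotypes.snps.iterrows():
            calls = [
                code.get(d, "./.") if not np.isnan(d) else "./."
                for d in genotypes.dosages[:, j]
            ]
            fh.write(
                f"{row['chrom']}\t{int(row['pos']) + 1}\t{row['snp_id']}\t"
                f"{row['ref']}\t{row['alt']}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def write_genotypes_tsv(genotypes: GenotypeMatrix, dosage_path: str | Path,
                        snp_map_path: str | Path) -> None:
    frame = pd.DataFrame(
        genotypes.dosages, index=genotypes.samples, columns=genotypes.snps["snp_id"]
    )
    frame.index.name = "sample"
    frame.to_csv(dosage_path, sep="\t", float_format="%.0f")
    genotypes.snps[SNP_MAP_COLUMNS].to_csv(snp_map_path, sep="\t", index=False)


# --------------------------------------------------------------- annotation

def read_probe_annotation(path: str | Path) -> pd.DataFrame:
    """Read a BED-like annotation TSV: chrom, start, end, probe_id, gene, strand.

    Intervals are 0-based half-open (BED native).  Rows with start >= end are
    rejected with an error naming the probe; duplicate probe ids are an error;
    an empty gene field is retained.
    """
    frame = pd.read_csv(
        path, sep="\t",
        names=["chrom", "tx_start", "tx_end", "probe_id", "gene", "strand"],
        header=None, comment="#", dtype={"chrom": str, "gene": str},
    )
    if frame["tx_start"].isna().any() or frame["tx_end"].isna().any():
        bad = frame.loc[frame["tx_start"].isna() | frame["tx_end"].isna(), "probe_id"]
        raise ValueError(f"missing coordinates for probes: {list(bad)}")
    annot = frame[["probe_id", "gene", "chrom", "tx_start", "tx_end", "strand"]]
    return validate_probe_annotation(annot)


def write_probe_annotation(annot: pd.DataFrame, path: str | Path) -> None:
    annot = annot[ANNOTATION_COLUMNS].copy()
    annot["gene"] = annot["gene"].fillna("")
    bed = annot[["chrom", "tx_start", "tx_end", "probe_id", "gene", "strand"]]
    bed.to_csv(path, sep="\t", index=False, header=False)


# --------------------------------------------------- expression, traits

def read_expression(path: str | Path) -> ExpressionMatrix:
    """Samples-as-rows expression TSV with a header row of probe ids."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix.from_frame(frame)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    frame = expr.to_frame()
    frame.index.name = "sample"
    frame.to_csv(path, sep="\t")


def read_traits(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_traits(traits: pd.DataFrame, path: str | Path) -> None:
    out = traits.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


# ------------------------------------------------------------------ results

def write_results(records: pd.DataFrame, path: str | Path) -> None:
    """Write eQTL calls/associations as a deterministic TSV.

    Columns: snp_id, snp_chrom, probe_id, gene, probe_chrom, class, n, beta,
    se, p, locus_id; rows ordered by ascending p, ties by snp_id.  An empty
    record set yields a header-only file.
    """
    out = records.copy()
    for col in RESULT_TSV_COLUMNS:
        if col not in out.columns:
            out[col] = "" if col in ("gene", "locus_id", "class", "snp_chrom", "probe_chrom") else np.nan
    out = out[RESULT_TSV_COLUMNS]
    if len(out):
        out = out.sort_values(["p", "snp_id"], kind="stable")
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(
        path, sep="\t", na_values=["NA"], keep_default_na=False,
        dtype={"snp_chrom": str, "probe_chrom": str, "gene": str, "locus_id": str, "class": str},
    )
    missing = [c for c in RESULT_TSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"results file lacks columns: {missing}")
    return frame


def write_truth(truth, path: str | Path) -> None:
    """Write a SimulationTruth ledger of planted effects as a TSV."""
    rows = [
        {"kind": "cis", "snp_id": s, "probe_id": p, "beta": b}
        for s, p, b in sorted(truth.planted_cis)
    ] + [
        {"kind": "trans", "snp_id": s, "probe_id": p, "beta": b}
        for s, p, b in sorted(truth.planted_trans)
    ] + [
        {"kind": "trait", "snp_id": src, "probe_id": name, "beta": b}
        for name, src, b in sorted(truth.trait_edges)
    ]
    pd.DataFrame(rows, columns=["kind", "snp_id", "probe_id", "beta"]).to_csv(
        path, sep="\t", index=False
    )
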