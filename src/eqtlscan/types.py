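"""Core in-memory containers shared by all pipeline stages.

Conventions
-----------
* Genomic coordinates are 0-based, half-open everywhere inside the package
  (BED-native); VCF positions are converted on read/write.
* Genotype dosages count copies of the ALT allele and live in {0, 1, 2};
  missing calls are ``NaN``.  The ALT allele is the reported effect allele.
* Expression matrices are samples x probes, continuous values.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SNP_MAP_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt"]
ANNOTATION_COLUMNS = ["probe_id", "gene", "chrom", "tx_start", "tx_end", "strand"]


class ConfigurationError(ValueError):
    """A configuration field is missing, out of range, or inconsistent."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix plus its SNP map.

    Parameters
    ----------
    dosages
        Float array of shape ``(n_samples, n_snps)`` with values in
        {0, 1, 2, NaN}.
    samples
        Sample identifiers, one per row.
    snps
        DataFrame with columns ``snp_id, chrom, pos, ref, alt`` (one row per
        dosage column, positional order).
    """

    dosages: np.ndarray
    samples: list[str]
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x SNPs)")
        if self.dosages.shape[0] != len(self.samples):
            raise ValueError("dosage rows do not match sample count")
        if self.dosages.shape[1] != len(self.snps):
            raise ValueError("dosage columns do not match SNP map length")
        missing = [c for c in SNP_MAP_COLUMNS if c not in self.snps.columns]
        if missing:
            raise ValueError(f"SNP map lacks columns: {missing}")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def snp_index(self) -> dict[str, int]:
        """Map snp_id -> column index."""
        return {s: i for i, s in enumerate(self.snps["snp_id"])}

    def alt_freq(self) -> np.ndarray:
        """ALT-allele frequency per SNP over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        af = self.alt_freq()
        return np.minimum(af, 1.0 - af)

    def call_rate(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.zeros(self.n_snps)
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def genotype_counts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Counts of hom-ref, het, hom-alt genotypes per SNP (missing ignored)."""
        d = self.dosages
        n0 = np.nansum(d == 0, axis=0).astype(int)
        n1 = np.nansum(d == 1, axis=0).astype(int)
        n2 = np.nansum(d == 2, axis=0).astype(int)
        return n0, n1, n2

    def subset_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            samples=list(self.samples),
            snps=self.snps.iloc[index].reset_index(drop=True),
        )


@dataclass
class ExpressionMatrix:
    """Samples x probes continuous expression values."""

    values: np.ndarray
    samples: list[str]
    probes: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x probes)")
        if self.values.shape[0] != len(self.samples):
            raise ValueError("value rows do not match sample count")
        if self.values.shape[1] != len(self.probes):
            raise ValueError("value columns do not match probe count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]

    def probe_index(self) -> dict[str, int]:
        return {p: i for i, p in enumerate(self.probes)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.probes)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            values=frame.to_numpy(dtype=float),
            samples=[str(s) for s in frame.index],
            probes=[str(p) for p in frame.columns],
        )


def validate_probe_annotation(annot: pd.DataFrame) -> pd.DataFrame:
    """Validate a probe annotation table (0-based half-open intervals).

    Raises ``ValueError`` listing the offending probe_id for an empty/invalid
    interval, and on duplicated probe ids.  Probes with an empty gene field are
    retained (unassigned transcripts are legitimate).
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in annot.columns]
    if missing:
        raise ValueError(f"annotation lacks columns: {missing}")
    annot = annot.reset_index(drop=True).copy()
    dup = annot["probe_id"][annot["probe_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate probe_id: {sorted(set(dup))}")
    has_coords = annot["tx_start"].notna() & annot["tx_end"].notna()
    bad = annot.loc[
        has_coords & (annot["tx_start"].astype(float) >= annot["tx_end"].astype(float)),
        "probe_id",
    ]
    if len(bad):
        raise ValueError(f"tx_start >= tx_end for probes: {list(bad)}")
    annot["gene"] = annot["gene"].fillna("")
    return annot


__all__ = [
    "ANNOTATION_COLUMNS",
    "ConfigurationError",
    "ExpressionMatrix",
    "GenotypeMatrix",
    "SNP_MAP_COLUMNS",
    "validate_probe_annotation",
    "replace",
    "field",
]
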