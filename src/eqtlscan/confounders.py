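"""Latent expression structure removal by principal-component residualization.

Hidden technical and biological factors (batch, cell-type composition, ...)
inflate correlation among probes and mask genetic effects.  The standard
remedy is to regress out the top expression PCs; the number removed trades
confounder removal against loss of genuine trans signal, so the module also
provides the sweep over candidate PC numbers (5..100 in steps of 5, plus the
uncorrected data) and, for replication-time use, the exclusion of PCs that
are themselves associated with the SNP being tested.

PCs are computed on the probe-standardized matrix; component signs are fixed
(largest-magnitude probe loading positive) for determinism.  Residualization
centers the input by its own column means and projects out the component
scores without rescaling, which makes it idempotent and leaves betas on the
original expression scale.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import ExpressionMatrix

logger = logging.getLogger(__name__)

SWEEP_GRID = tuple(range(5, 101, 5))


@dataclass
class PcBasis:
    """Top-k principal components of a (standardized) expression matrix."""

    components: np.ndarray  # (n_samples, k), orthonormal scores
    loadings: np.ndarray  # (n_probes, k)
    explained_variance_ratio: np.ndarray  # (k,)
    center: np.ndarray  # (n_probes,)
    scale: np.ndarray  # (n_probes,)

    @property
    def k(self) -> int:
        return self.components.shape[1]

    def drop(self, indices: Iterable[int]) -> "PcBasis":
        """Basis without the listed components (replication-time exclusion)."""
        keep = [i for i in range(self.k) if i not in set(indices)]
        return PcBasis(
            components=self.components[:, keep],
            loadings=self.loadings[:, keep],
            explained_variance_ratio=self.explained_variance_ratio[keep],
            center=self.center,
            scale=self.scale,
        )


def max_rank(expr: ExpressionMatrix) -> int:
    """Structural rank of the column-centered matrix."""
    return min(expr.n_samples - 1, expr.n_probes)


def compute_pcs(expr: ExpressionMatrix, k: int) -> PcBasis:
    """Top-k PCs of the probe-standardized expression matrix.

    Raises ``ValueError`` when ``k`` exceeds the rank of the centered matrix.
    """
    n, p = expr.n_samples, expr.n_probes
    rank = max_rank(expr)
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > rank:
        raise ValueError(f"k={k} exceeds the rank of the centered matrix ({rank})")
    center = expr.values.mean(axis=0)
    scale = expr.values.std(axis=0, ddof=1)
    scale = np.where(scale > 0, scale, 1.0)
    if k == 0:
        return PcBasis(
            components=np.empty((n, 0)),
            loadings=np.empty((p, 0)),
            explained_variance_ratio=np.empty(0),
            center=center,
            scale=scale,
        )
    Z = (expr.values - center) / scale
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    evr = s**2 / np.sum(s**2)
    U, Vt, evr = U[:, :k], Vt[:k], evr[:k]
    for j in range(k):  # deterministic sign: largest-|loading| entry positive
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    return PcBasis(
        components=U,
        loadings=Vt.T,
        explained_variance_ratio=evr,
        center=center,
        scale=scale,
    )


def residualize(expr: ExpressionMatrix, basis: PcBasis) -> ExpressionMatrix:
    """Project the component scores out of each (centered) probe column."""
    if basis.components.shape[0] != expr.n_samples:
        raise ValueError("basis sample count does not match expression matrix")
    Xc = expr.values - expr.values.mean(axis=0)
    if basis.k:
        U = basis.components
        Xc = Xc - U @ (U.T @ Xc)
    return ExpressionMatrix(values=Xc, samples=list(expr.samples), probes=list(expr.probes))


def residualize_column(y: np.ndarray, basis: PcBasis) -> np.ndarray:
    """Residualize a single (probe or trait) column against a basis."""
    y = np.asarray(y, dtype=float)
    if basis.components.shape[0] != y.shape[0]:
        raise ValueError("basis sample count does not match column length")
    yc = y - np.nanmean(y)
    if basis.k:
        U = basis.components
        yc = yc - U @ (U.T @ np.nan_to_num(yc))
    return yc


def snp_associated_pcs(
    basis: PcBasis,
    snp_dosages: np.ndarray,
    alpha: float = 0.05,
) -> np.ndarray:
    """Indices of PCs whose regression on the dosage has p < alpha.

    A constant (or all-missing) dosage flags nothing and logs a warning.
    """
    from .association import pairwise_stats  # local import avoids cycle

    x = np.asarray(snp_dosages, dtype=float)
    valid = x[~np.isnan(x)]
    if basis.k == 0:
        return np.empty(0, dtype=int)
    if valid.size < 3 or np.ptp(valid) == 0.0:
        logger.warning("constant or near-empty dosage vector; no PC flagged")
        return np.empty(0, dtype=int)
    st = pairwise_stats(x[:, None], basis.components)
    p = st["p"][0]
    # perfect fits are flagged degenerate but carry a floored p: still excluded PCs
    flagged = np.flatnonzero(~np.isnan(p) & (p < alpha))
    return flagged


def pc_sweep(
    expr: ExpressionMatrix,
    genotypes,
    cis_pairs: np.ndarray,
    trans_pairs: np.ndarray,
    cis_threshold: float,
    trans_threshold: float,
    grid: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Sweep the number of removed PCs and report scan summaries per k.

    One row per k in ``grid`` (default 5..100 step 5) plus k=0 (the
    uncorrected data): mean standard error, mean |beta| and the counts of
    cis/trans pairs significant at the supplied thresholds.
    """
    from .association import scan  # local import avoids cycle

    grid = list(grid) if grid is not None else list(SWEEP_GRID)
    rank = max_rank(expr)
    bad = [k for k in grid if k > rank]
    if bad:
        raise ValueError(f"grid values exceed rank {rank}: {bad}")
    rows = []
    for k in [0] + grid:
        basis = compute_pcs(expr, k)
        res_expr = residualize(expr, basis)
        ses, betas = [], []
        n_cis = n_trans = 0
        for pairs, thr, is_cis in ((cis_pairs, cis_threshold, True),
                                   (trans_pairs, trans_threshold, False)):
            if pairs is None or len(pairs) == 0:
                continue
            res = scan(genotypes, res_expr, pairs=np.asarray(pairs))
            ok = ~res["degenerate"]
            ses.append(res.loc[ok, "se"].to_numpy())
            betas.append(np.abs(res.loc[ok, "beta"].to_numpy()))
            n_sig = int((res.loc[ok, "p"] <= thr).sum())
            if is_cis:
                n_cis = n_sig
            else:
                n_trans = n_sig
        all_se = np.concatenate(ses) if ses else np.empty(0)
        all_beta = np.concatenate(betas) if betas else np.empty(0)
        rows.append(
            {
                "k": k,
                "mean_se": float(all_se.mean()) if all_se.size else np.nan,
                "mean_abs_beta": float(all_beta.mean()) if all_beta.size else np.nan,
                "n_significant_cis": n_cis,
                "n_significant_trans": n_trans,
            }
        )
    return pd.DataFrame(rows)
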