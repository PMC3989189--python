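"""Mass simple-linear-regression scan of expression probes on SNP dosages.

Additive coding: expression is regressed on the ALT-allele dosage with an
intercept, on pairwise-complete cases, yielding the slope (beta, in expression
units per allele copy), its standard error, the t statistic on n-2 degrees of
freedom and a two-sided p-value.  The single-pair route goes through
``scipy.stats.linregress``; the vectorized scan is an independent closed-form
implementation and must agree with it to numerical precision.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import ExpressionMatrix, GenotypeMatrix

P_FLOOR = 1e-300
_VAR_TOL = 1e-12  # relative tolerance for "no variance left"

RESULT_COLUMNS = ["snp_id", "probe_id", "n", "beta", "se", "t", "p", "degenerate"]


@dataclass
class AssociationResult:
    """Per SNP-probe regression output."""

    snp_id: str
    probe_id: str
    n: int
    beta: float
    se: float
    t: float
    p: float
    effect_allele: str = ""
    degenerate: bool = False
    p_floored: bool = False


def regress_single(
    dosage: np.ndarray,
    expression: np.ndarray,
    snp_id: str = "",
    probe_id: str = "",
    effect_allele: str = "",
) -> AssociationResult:
    """OLS slope of expression on dosage, complete cases only.

    Degenerate inputs (fewer than 3 complete pairs, constant dosage) are
    flagged rather than raised so that a scan can skip them downstream.  A
    perfect fit (zero residual variance) floors the p-value at ``P_FLOOR`` and
    is flagged degenerate as well.
    """
    x = np.asarray(dosage, dtype=float)
    y = np.asarray(expression, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = int(mask.sum())
    if n < 3 or np.ptp(x) == 0.0:
        return AssociationResult(snp_id, probe_id, n, np.nan, np.nan, np.nan, np.nan,
                                 effect_allele, degenerate=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # linregress warns on perfect fits
        fit = stats.linregress(x, y)
    beta, se, p = float(fit.slope), float(fit.stderr), float(fit.pvalue)
    vy = float(np.var(y))
    resid_var = vy * (1.0 - float(fit.rvalue) ** 2)
    if se == 0.0 or resid_var <= _VAR_TOL * max(vy, 1.0):
        t = np.inf if beta >= 0 else -np.inf
        return AssociationResult(snp_id, probe_id, n, beta, se, t, P_FLOOR,
                                 effect_allele, degenerate=True, p_floored=True)
    t = beta / se
    floored = p < P_FLOOR
    return AssociationResult(snp_id, probe_id, n, beta, se, t, max(p, P_FLOOR),
                             effect_allele, p_floored=floored)


def pairwise_stats(X: np.ndarray, Y: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized OLS of every Y column on every X column.

    Parameters
    ----------
    X : (n_samples, m) dosage matrix, NaN = missing.
    Y : (n_samples, p) expression matrix, NaN = missing.

    Returns dict of (m, p) arrays: ``n, beta, se, t, p, degenerate``.
    Pairwise-complete cases; numerically identical to :func:`regress_single`
    per pair up to floating point.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n_samples, m = X.shape
    p_cols = Y.shape[1]
    if np.isnan(X).any() or np.isnan(Y).any():
        return _pairwise_stats_masked(X, Y)
    n = np.full((m, p_cols), n_samples)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sxx = np.einsum("ij,ij->j", Xc, Xc)
    syy = np.einsum("ij,ij->j", Yc, Yc)
    sxy = Xc.T @ Yc
    return _finish(n, sxx[:, None], syy[None, :], sxy)


def _pairwise_stats_masked(X: np.ndarray, Y: np.ndarray) -> dict[str, np.ndarray]:
    m, p_cols = X.shape[1], Y.shape[1]
    ym = ~np.isnan(Y)
    Y0 = np.where(ym, Y, 0.0)
    Y0sq = Y0 * Y0
    out = {k: np.empty((m, p_cols)) for k in ("n", "beta", "se", "t", "p")}
    out["degenerate"] = np.empty((m, p_cols), dtype=bool)
    for j in range(m):
        x = X[:, j]
        xm = ~np.isnan(x)
        x0 = np.where(xm, x, 0.0)
        M = (ym & xm[:, None]).astype(float)
        nv = M.sum(axis=0)
        sx = x0 @ M
        sxx = (x0 * x0) @ M
        sy = np.einsum("ij,ij->j", Y0, M)
        syy = np.einsum("ij,ij->j", Y0sq, M)
        sxy = x0 @ (Y0 * M)
        with np.errstate(divide="ignore", invalid="ignore"):
            safe_n = np.where(nv > 0, nv, 1.0)
            vx = sxx - sx * sx / safe_n
            vy = syy - sy * sy / safe_n
            cxy = sxy - sx * sy / safe_n
        row = _finish(nv[None, :], vx[None, :], vy[None, :], cxy[None, :])
        for k in out:
            out[k][j] = row[k][0]
    return out


def _finish(n, vx, vy, cxy) -> dict[str, np.ndarray]:
    """Shared tail of the closed-form OLS: beta/se/t/p from central moments."""
    n = np.broadcast_to(np.asarray(n, dtype=float), cxy.shape).copy()
    vx = np.broadcast_to(vx, cxy.shape)
    vy = np.broadcast_to(vy, cxy.shape)
    ok = (n >= 3) & (vx > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(ok, cxy / np.where(vx > 0, vx, 1.0), np.nan)
        ssr = vy - beta * cxy
        perfect = ok & (ssr <= _VAR_TOL * np.maximum(vy, n))
        df = np.maximum(n - 2, 1)
        se = np.sqrt(np.maximum(ssr, 0.0) / df / np.where(vx > 0, vx, 1.0))
        t = np.where(se > 0, beta / se, np.where(beta >= 0, np.inf, -np.inf))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.maximum(p, P_FLOOR)
    p = np.where(perfect, P_FLOOR, p)
    degenerate = ~ok | perfect
    beta = np.where(ok, beta, np.nan)
    se = np.where(ok, se, np.nan)
    t = np.where(ok, t, np.nan)
    p = np.where(ok, p, np.nan)
    return {"n": n.astype(int), "beta": beta, "se": se, "t": t, "p": p, "degenerate": degenerate}


def enumerate_cis_pairs(
    snps: pd.DataFrame,
    annotation: pd.DataFrame,
    flank: int = 500_000,
) -> tuple[np.ndarray, int, int]:
    """All (snp_index, probe_index) pairs with the SNP inside
    ``[tx_start - flank, tx_end + flank]`` (inclusive bounds, clamped at 0) on
    the probe's chromosome.

    Returns ``(pairs, n_pairs, n_probes_without_coordinates)``; the pair count
    is the cis Bonferroni denominator.
    """
    snps = snps.reset_index(drop=True)
    pairs: list[np.ndarray] = []
    n_skipped = 0
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, group in snps.groupby("chrom", sort=False):
        pos = group["pos"].to_numpy(dtype=float)
        order = np.argsort(pos, kind="stable")
        by_chrom[str(chrom)] = (pos[order], group.index.to_numpy()[order])
    for probe_idx, row in annotation.reset_index(drop=True).iterrows():
        if pd.isna(row["chrom"]) or pd.isna(row["tx_start"]) or pd.isna(row["tx_end"]):
            n_skipped += 1
            continue
        entry = by_chrom.get(str(row["chrom"]))
        if entry is None:
            continue
        pos_sorted, idx_sorted = entry
        lo = max(float(row["tx_start"]) - flank, 0.0)
        hi = float(row["tx_end"]) + flank
        a = np.searchsorted(pos_sorted, lo, side="left")
        b = np.searchsorted(pos_sorted, hi, side="right")
        if b > a:
            snp_idx = idx_sorted[a:b]
            pairs.append(np.column_stack([snp_idx, np.full(b - a, probe_idx)]))
    if pairs:
        out = np.concatenate(pairs).astype(int)
    else:
        out = np.empty((0, 2), dtype=int)
    return out, len(out), n_skipped


def scan(
    genotypes: GenotypeMatrix,
    expr: ExpressionMatrix,
    pairs: str | np.ndarray = "all",
    annotation: pd.DataFrame | None = None,
    flank: int = 500_000,
    pair_budget: int = 20_000_000,
    force: bool = False,
) -> pd.DataFrame:
    """Association scan over the requested SNP-probe pairs.

    ``pairs`` is ``"all"``, ``"cis"``, ``"trans"`` (all minus cis) or an
    explicit ``(k, 2)`` integer array of (snp_index, probe_index).  Results
    are a tidy DataFrame (columns ``snp_id, probe_id, n, beta, se, t, p,
    degenerate``), one row per requested pair, ordered by (snp_index,
    probe_index).
    """
    if list(genotypes.samples) != list(expr.samples):
        raise ValueError("genotype and expression sample sets differ")
    m, p_cols = genotypes.n_snps, expr.n_probes
    snp_ids = genotypes.snps["snp_id"].to_numpy()
    probe_ids = np.asarray(expr.probes)

    if isinstance(pairs, str):
        if pairs not in ("all", "cis", "trans"):
            raise ValueError(f"unknown pair mode {pairs!r}")
        if pairs in ("cis", "trans"):
            if annotation is None:
                raise ValueError("cis/trans scans require a probe annotation")
            cis_pairs, _, _ = enumerate_cis_pairs(genotypes.snps, annotation, flank)
        if pairs == "cis":
            pair_array = cis_pairs
        else:
            total = m * p_cols
            if total > pair_budget and not force:
                raise MemoryError(
                    f"{total} pairs exceed the pair budget ({pair_budget}); pass force=True"
                )
            if pairs == "all":
                pair_array = None
            else:  # trans = all minus cis
                keep = np.ones((m, p_cols), dtype=bool)
                if len(cis_pairs):
                    keep[cis_pairs[:, 0], cis_pairs[:, 1]] = False
                pair_array = np.column_stack(np.nonzero(keep))
    else:
        pair_array = np.asarray(pairs, dtype=int).reshape(-1, 2)

    if pair_array is None:  # dense all-pairs scan
        st = pairwise_stats(genotypes.dosages, expr.values)
        si, pi = np.meshgrid(np.arange(m), np.arange(p_cols), indexing="ij")
        si, pi = si.ravel(), pi.ravel()
        flat = {k: v.ravel() for k, v in st.items()}
    else:
        if len(pair_array) > pair_budget and not force:
            raise MemoryError(
                f"{len(pair_array)} pairs exceed the pair budget ({pair_budget}); pass force=True"
            )
        si, pi = pair_array[:, 0], pair_array[:, 1]
        order = np.lexsort((pi, si))
        si, pi = si[order], pi[order]
        flat = {k: np.empty(len(si), dtype=(bool if k == "degenerate" else float))
                for k in ("n", "beta", "se", "t", "p", "degenerate")}
        # group by SNP so each dosage column is processed once
        boundaries = np.flatnonzero(np.diff(si, prepend=-1))
        for b, start in enumerate(boundaries):
            stop = boundaries[b + 1] if b + 1 < len(boundaries) else len(si)
            j = si[start]
            cols = pi[start:stop]
            st = pairwise_stats(genotypes.dosages[:, [j]], expr.values[:, cols])
            for k in flat:
                flat[k][start:stop] = st[k][0]
        flat["n"] = flat["n"].astype(int)

    return pd.DataFrame(
        {
            "snp_id": snp_ids[si],
            "probe_id": probe_ids[pi],
            "n": flat["n"],
            "beta": flat["beta"],
            "se": flat["se"],
            "t": flat["t"],
            "p": flat["p"],
            "degenerate": flat["degenerate"].astype(bool),
        }
    )
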