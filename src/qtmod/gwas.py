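"""Covariate-adjusted per-SNP association of a module trait.

Each variant is tested with the linear model

    trait ~ intercept + dosage + age + sex + education

and a two-sided t-test on the dosage coefficient. The scan residualizes
the trait and all dosage columns against the covariate block once and
then fits all single-SNP regressions with vectorized cross-products;
this is numerically identical to fitting each SNP's full model
separately (Frisch-Waugh-Lovell), which the test suite checks against
an explicit per-SNP least-squares oracle. Missing dosages are
mean-imputed per SNP by default; exact case deletion is available.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "assoc_scan",
    "significant_hits",
    "top_main_snps",
    "manhattan_table",
]

P_FLOOR = 1e-300  # for -log10 transforms only


def _design(covars: pd.DataFrame) -> np.ndarray:
    Z = np.column_stack([np.ones(len(covars)), covars.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("covariate matrix (with intercept) is rank deficient")
    return Z


def _residualize(Z: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Residuals of the columns of M after OLS projection on Z."""
    coef, *_ = np.linalg.lstsq(Z, M, rcond=None)
    return M - Z @ coef


def mean_impute(X: np.ndarray) -> np.ndarray:
    """Replace missing dosages by the per-SNP mean of observed dosages."""
    if not np.isnan(X).any():
        return X
    X = X.copy()
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    idx = np.where(np.isnan(X))
    X[idx] = col_mean[idx[1]]
    return X


def assoc_scan(
    trait: pd.Series | np.ndarray,
    G,
    covars: pd.DataFrame,
    *,
    case_deletion: bool = False,
) -> pd.DataFrame:
    """Per-SNP OLS association of ``trait`` adjusted for ``covars``.

    Returns one row per variant with columns ``snp, chrom, pos, beta,
    se, t, p, n, monomorphic``. Monomorphic variants (zero residual
    dosage variance) are flagged and reported with beta 0, se inf,
    p = 1. With ``case_deletion=True`` each SNP drops its missing rows
    instead of mean-imputing (slower, per-SNP loop).
    """
    y = np.asarray(trait, dtype=float)
    if case_deletion:
        return _assoc_scan_casewise(y, G, covars)
    Z = _design(covars)
    n, q = Z.shape
    X = mean_impute(G.dosages)

    ry = _residualize(Z, y[:, None])[:, 0]
    RX = _residualize(Z, X)
    sxx = np.einsum("ij,ij->j", RX, RX)
    sxy = ry @ RX
    syy = float(ry @ ry)

    dof = n - q - 1
    if dof <= 0:
        raise ValueError("not enough samples for the covariate-adjusted fit")
    mono = sxx <= n * 1e-12  # zero residual dosage variance
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(mono, 0.0, sxy / np.where(mono, 1.0, sxx))
        ssr = np.maximum(syy - beta**2 * sxx, 0.0)
        se = np.sqrt(ssr / dof / np.where(mono, 1.0, sxx))
        t = np.where(mono, 0.0, beta / np.where(se > 0, se, np.inf))
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.where(mono, 1.0, np.clip(p, np.finfo(float).tiny, 1.0))
    se = np.where(mono, np.inf, se)
    return pd.DataFrame(
        {
            "snp": G.variant_ids.to_numpy(),
            "chrom": G.variant_meta["chrom"].to_numpy(),
            "pos": G.variant_meta["pos"].to_numpy(),
            "beta": beta,
            "se": se,
            "t": t,
            "p": p,
            "n": n,
            "monomorphic": mono,
        }
    )


def _assoc_scan_casewise(y: np.ndarray, G, covars: pd.DataFrame) -> pd.DataFrame:
    C = covars.to_numpy(dtype=float)
    rows = []
    for j, snp in enumerate(G.variant_ids):
        x = G.dosages[:, j]
        ok = ~np.isnan(x)
        n_j = int(ok.sum())
        Zj = np.column_stack([np.ones(n_j), C[ok]])
        dof = n_j - Zj.shape[1] - 1
        if dof <= 0:
            raise ValueError(f"too few observed genotypes for {snp}")
        ryj = _residualize(Zj, y[ok, None])[:, 0]
        rxj = _residualize(Zj, x[ok, None])[:, 0]
        sxx = float(rxj @ rxj)
        syy = float(ryj @ ryj)
        mono = sxx <= n_j * 1e-12
        if mono:
            beta, se, t, p = 0.0, np.inf, 0.0, 1.0
        else:
            beta = float(rxj @ ryj) / sxx
            ssr = max(syy - beta**2 * sxx, 0.0)
            se = float(np.sqrt(ssr / dof / sxx))
            t = beta / se if se > 0 else 0.0
            p = float(max(2.0 * stats.t.sf(abs(t), dof), np.finfo(float).tiny))
        rows.append(
            (
                snp,
                G.variant_meta["chrom"].iloc[j],
                G.variant_meta["pos"].iloc[j],
                beta,
                se,
                t,
                p,
                n_j,
                mono,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["snp", "chrom", "pos", "beta", "se", "t", "p", "n", "monomorphic"],
    )


def significant_hits(res: pd.DataFrame, p_thresh: float = 1e-4) -> pd.DataFrame:
    """Variants with p strictly below the threshold, sorted by (p, chrom, pos)."""
    hits = res[res["p"] < p_thresh]
    return hits.sort_values(["p", "chrom", "pos"], kind="mergesort").reset_index(
        drop=True
    )


def top_main_snps(res: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """The k smallest-p variants (the module's main-effect SNPs).

    Ties on p break by (chrom, pos). If fewer than k variants were
    tested, all are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(res) < k:
        warnings.warn(
            f"requested top {k} but only {len(res)} variants tested", stacklevel=2
        )
        k = len(res)
    ordered = res.sort_values(["p", "chrom", "pos"], kind="mergesort")
    return ordered.head(k).reset_index(drop=True)


def manhattan_table(res: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready (chrom, pos, snp, -log10 p) records sorted by position."""
    out = res[["chrom", "pos", "snp"]].copy()
    out["neglog10_p"] = -np.log10(np.maximum(res["p"].to_numpy(), P_FLOOR))
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
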