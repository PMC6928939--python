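"""Covariate-adjusted SNP x SNP interaction tests in matrix form.

The interaction test asks whether the product term improves the full
model

    trait ~ intercept + g1 + g2 + g1*g2 + age + sex + education.

Its t statistic equals the partial correlation between the trait and
the dosage product after projecting both onto the orthogonal complement
of {intercept, g1, g2, covariates}, scaled by sqrt(df / (1 - r^2)) with
df = n - (conditioning columns) - 1. Computing it that way lets one
anchor SNP be screened against every partner in a single matrix pass
while remaining numerically identical to the explicit per-pair OLS fit.
Products are formed on the raw {0,1,2} codes; the projection handles
all centring.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .gwas import _design, _residualize, mean_impute

__all__ = ["interaction_test", "scan_anchors"]


def interaction_test(
    trait: pd.Series | np.ndarray,
    g1: np.ndarray,
    g2: np.ndarray,
    covars: pd.DataFrame,
) -> tuple[float, float]:
    """Two-sided test of the g1*g2 product coefficient.

    Returns ``(t_statistic, p)``. If the product column is (numerically)
    collinear with {intercept, g1, g2, covariates} the pair is untestable
    and ``(0.0, 1.0)`` is returned.
    """
    y = np.asarray(trait, dtype=float)
    g1 = mean_impute(np.asarray(g1, dtype=float)[:, None])[:, 0]
    g2 = mean_impute(np.asarray(g2, dtype=float)[:, None])[:, 0]
    # canonical column order makes the test exactly symmetric in (g1, g2)
    if g2.tobytes() < g1.tobytes():
        g1, g2 = g2, g1
    Z = np.column_stack([_design(covars), g1, g2])
    n, q = Z.shape
    dof = n - q - 1
    if dof <= 0:
        raise ValueError("not enough samples for the interaction fit")
    w = g1 * g2
    ry = _residualize(Z, y[:, None])[:, 0]
    rw = _residualize(Z, w[:, None])[:, 0]
    sww = float(rw @ rw)
    syy = float(ry @ ry)
    if sww <= n * 1e-10 * max(1.0, float(w @ w) / n) or syy <= 0:
        return 0.0, 1.0
    r = float(ry @ rw) / np.sqrt(syy * sww)
    r = float(np.clip(r, -1.0, 1.0))
    denom = max(1.0 - r * r, 1e-300)
    t = r * np.sqrt(dof / denom)
    p = float(max(2.0 * stats.t.sf(abs(t), dof), np.finfo(float).tiny))
    return t, p


def scan_anchors(
    trait: pd.Series | np.ndarray,
    anchors: list[str],
    G,
    covars: pd.DataFrame,
    p_thresh: float = 5e-4,
) -> pd.DataFrame:
    """Screen every (anchor, partner) pair; keep edges with p < p_thresh.

    Partners are all variants not in ``anchors`` (anchor-anchor pairs
    are not tested). For each anchor the conditioning block
    {intercept, covariates, anchor} is projected out once; the residual
    partner dosage then joins the conditioning set through the
    closed-form three-variable partial-correlation update, so each
    pair's statistic matches :func:`interaction_test` exactly. Returns
    the kept edges sorted by (anchor, p, partner) with columns
    ``anchor, partner, chrom_anchor, chrom_partner, stat, p, n``.
    """
    if not anchors:
        raise ValueError("anchor list is empty")
    y = np.asarray(trait, dtype=float)
    anchor_idx = G.variant_index(anchors)
    partner_mask = np.ones(G.n_variants, dtype=bool)
    partner_mask[anchor_idx] = False
    partner_cols = np.flatnonzero(partner_mask)
    X = mean_impute(G.dosages)
    M = X[:, partner_cols]
    Z0 = _design(covars)
    chrom = G.variant_meta["chrom"].to_numpy()
    snp = G.variant_ids.to_numpy()
    n = len(y)

    records = []
    for a_pos, a_col in enumerate(anchor_idx):
        ga = X[:, a_col]
        Z = np.column_stack([Z0, ga])
        q = Z.shape[1] + 1  # conditioning set per pair adds the partner
        dof = n - q - 1
        if dof <= 0:
            raise ValueError("not enough samples for the interaction scan")
        ry = _residualize(Z, y[:, None])[:, 0]
        RM = _residualize(Z, M)
        W = ga[:, None] * M
        RW = _residualize(Z, W)

        syy = float(ry @ ry)
        smm = np.einsum("ij,ij->j", RM, RM)
        sww = np.einsum("ij,ij->j", RW, RW)
        sym = ry @ RM
        syw = ry @ RW
        smw = np.einsum("ij,ij->j", RM, RW)

        with np.errstate(invalid="ignore", divide="ignore"):
            r_ym = sym / np.sqrt(syy * smm)
            r_yw = syw / np.sqrt(syy * sww)
            r_mw = smw / np.sqrt(smm * sww)
            # partial corr of (y, w) given the partner dosage m
            num = r_yw - r_ym * r_mw
            den = np.sqrt((1.0 - r_ym**2) * (1.0 - r_mw**2))
            pc = num / den
        # untestable pairs: degenerate product or partner residual
        scale = np.maximum(1.0, np.einsum("ij,ij->j", W, W) / n)
        bad = (
            ~np.isfinite(pc)
            | (sww <= n * 1e-10 * scale)
            | (smm <= n * 1e-12)
            | (den <= 1e-12)
        )
        pc = np.clip(np.where(bad, 0.0, pc), -1.0, 1.0)
        denom = np.maximum(1.0 - pc**2, 1e-300)
        tstat = pc * np.sqrt(dof / denom)
        p = 2.0 * stats.t.sf(np.abs(tstat), dof)
        p = np.where(bad, 1.0, np.maximum(p, np.finfo(float).tiny))

        keep = p < p_thresh
        for j in np.flatnonzero(keep):
            col = partner_cols[j]
            records.append(
                (
                    anchors[a_pos],
                    snp[col],
                    chrom[a_col],
                    chrom[col],
                    float(tstat[j]),
                    float(p[j]),
                    n,
                )
            )
    out = pd.DataFrame(
        records,
        columns=["anchor", "partner", "chrom_anchor", "chrom_partner", "stat", "p", "n"],
    )
    return out.sort_values(["anchor", "p", "partner"], kind="mergesort").reset_index(
        drop=True
    )
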