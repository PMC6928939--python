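"""Sample and variant quality control plus LD pruning.

Filter order follows standard GWAS practice: sample filters first (call
rate >= 0.90, genetic/reported sex concordance, one member of each
related pair with PI_HAT > 0.2), then variant filters (call rate >=
0.90, Hardy-Weinberg exact p > 5e-7, MAF >= 0.10), then windowed LD
pruning (window 50, step 5, r^2 cap 0.8). All statistics use observed
entries only; missing dosages are never imputed during QC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import GenotypeMatrix, QcReport

__all__ = [
    "call_rates",
    "sex_check",
    "hwe_exact_p",
    "relatedness",
    "ibd_exclusions",
    "variant_filters",
    "ld_prune",
    "run_qc",
]


# ----------------------------------------------------------------------
def call_rates(G: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of non-missing entries per sample and per variant."""
    if G.n_samples == 0 or G.n_variants == 0:
        raise ValueError("genotype matrix is empty")
    obs = ~np.isnan(G.dosages)
    return obs.mean(axis=1), obs.mean(axis=0)


# ----------------------------------------------------------------------
def sex_check(
    G: GenotypeMatrix, t_male: float = 0.05, t_female: float = 0.15
) -> pd.DataFrame:
    """Compare X-heterozygosity-inferred sex with the reported sex.

    A male carries one X, so his X calls are homozygous (het rate ~0);
    a female's het rate is ~2*maf*(1-maf) per SNP. Inferred sex is male
    below ``t_male``, female above ``t_female``, otherwise undetermined
    (never flagged). Returns per-sample het rate, inferred sex and a
    mismatch flag.
    """
    x_cols = np.flatnonzero(G.variant_meta["is_x"].to_numpy())
    if len(x_cols) == 0:
        raise ValueError("sex check requires at least one X-flagged variant")
    x = G.dosages[:, x_cols]
    het = (x == 1.0)
    obs = ~np.isnan(x)
    with np.errstate(invalid="ignore"):
        het_rate = np.where(obs.sum(axis=1) > 0, het.sum(axis=1) / obs.sum(axis=1), np.nan)
    inferred = np.where(
        het_rate < t_male, "M", np.where(het_rate > t_female, "F", "U")
    )
    inferred = np.where(np.isnan(het_rate), "U", inferred)
    reported = G.sample_meta["reported_sex"].to_numpy()
    mismatch = (inferred != "U") & (inferred != reported)
    return pd.DataFrame(
        {
            "sample": G.sample_ids.to_numpy(),
            "x_het_rate": het_rate,
            "inferred_sex": inferred,
            "reported_sex": reported,
            "mismatch": mismatch,
        }
    )


# ----------------------------------------------------------------------
def hwe_exact_distribution(
    n: int, rare: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact heterozygote-count distribution given allele counts.

    For ``n`` diploid samples carrying ``rare`` copies of the rarer
    allele, returns ``(hets, probs, pvals)``: the possible heterozygote
    counts (sharing the parity of ``rare``), their conditional
    probabilities under HWE, and the two-sided exact p-value for each
    (the summed probability of all counts no more likely than it).
    Probabilities are computed with log-factorials.
    """
    if not (0 <= rare <= n):
        raise ValueError("need 0 <= rare allele count <= n (diploid pairs)")
    lf = gammaln  # lf(x+1) = log(x!)
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    logs = (
        lf(n + 1)
        - lf(hom_rare + 1)
        - lf(hets + 1)
        - lf(hom_common + 1)
        + hets * math.log(2.0)
        + lf(rare + 1)
        + lf(2 * n - rare + 1)
        - lf(2 * n + 1)
    )
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    # p-value per possible observation: sum of probs <= that table's prob
    # (tiny relative tolerance so exact ties are counted on both sides)
    order = np.argsort(probs, kind="mergesort")
    csum = np.cumsum(probs[order])
    idx = np.searchsorted(probs[order], probs * (1.0 + 1e-12), side="right")
    pvals = np.minimum(csum[idx - 1], 1.0)
    return hets, probs, pvals


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided Hardy-Weinberg exact test on genotype counts.

    Conditional on the observed allele counts, the heterozygote count
    follows the HWE exact distribution; the p-value sums the
    probabilities of all heterozygote counts whose probability does not
    exceed that of the observed table. Returns p in (0, 1].
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0 or c != int(c):
            raise ValueError("genotype counts must be nonnegative integers")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("HWE test undefined for an empty table")
    nA = 2 * n_AA + n_Aa
    rare = min(nA, 2 * n - nA)
    hets, _, pvals = hwe_exact_distribution(n, rare)
    return float(pvals[np.flatnonzero(hets == n_Aa)[0]])


def _hwe_p_from_dosages(col: np.ndarray) -> float:
    obs = col[~np.isnan(col)]
    if obs.size == 0:
        return 1.0
    n_aa = int((obs == 2.0).sum())
    n_Aa = int((obs == 1.0).sum())
    n_AA = int((obs == 0.0).sum())
    return hwe_exact_p(n_AA, n_Aa, n_aa)


# ----------------------------------------------------------------------
def relatedness(G: GenotypeMatrix, min_variants: int = 50) -> pd.DataFrame:
    """Method-of-moments PI_HAT for every sample pair.

    Counts identity-by-state (IBS) sharing across autosomal variants and
    solves the moment equations P(IBD=0/1/2) against the IBS
    probabilities expected under the sample's own allele frequencies;
    PI_HAT = P(IBD=1)/2 + P(IBD=2). Estimates are clamped to [0, 1].
    Ideally run on LD-pruned variants.

    Returns a DataFrame with columns ``sample1, sample2, pi_hat,
    n_variants`` for all unordered pairs.
    """
    if G.n_samples < 2:
        raise ValueError("relatedness needs at least two samples")
    auto = np.flatnonzero(~G.variant_meta["is_x"].to_numpy())
    X = G.dosages[:, auto]
    m = X.shape[1]
    reliable = m >= min_variants
    if not reliable:
        warnings.warn(
            f"relatedness estimated on only {m} variants (<{min_variants}); unreliable",
            stacklevel=2,
        )

    obs = ~np.isnan(X)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(X, axis=0) / 2.0  # frequency of the dosage-counted allele
    p = np.clip(p, 1e-6, 1 - 1e-6)
    q = 1.0 - p

    # indicator matrices per genotype class (missing rows contribute 0)
    A = [np.where(obs & (X == g), 1.0, 0.0) for g in (0.0, 1.0, 2.0)]
    Mv = obs.astype(float)
    n_pair = Mv @ Mv.T  # non-missing variants per pair
    ibs2 = A[0] @ A[0].T + A[1] @ A[1].T + A[2] @ A[2].T
    ibs0 = A[0] @ A[2].T + A[2] @ A[0].T
    ibs1 = n_pair - ibs2 - ibs0

    # expected per-variant IBS probabilities under IBD state, summed
    # genome-wide and rescaled by each pair's observed variant count
    e0_ibd0 = float(np.sum(2 * p**2 * q**2))
    e1_ibd0 = float(np.sum(4 * p**3 * q + 4 * p * q**3))
    e2_ibd0 = float(np.sum(p**4 + q**4 + 4 * p**2 * q**2))
    e1_ibd1 = float(np.sum(2 * p**2 * q + 2 * p * q**2))
    e2_ibd1 = float(np.sum(p**2 + q**2))

    scale = np.where(n_pair > 0, n_pair / m, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        P0 = ibs0 / (e0_ibd0 * scale)
        P1 = (ibs1 - P0 * e1_ibd0 * scale) / (e1_ibd1 * scale)
        P2 = (ibs2 - P0 * e2_ibd0 * scale - P1 * e2_ibd1 * scale) / n_pair
    # moment estimates are individually noisy at moderate m; only the
    # final combination is clamped, to keep the null estimate unbiased
    pi_hat = np.clip(P1 / 2.0 + P2, 0.0, 1.0)

    iu, ju = np.triu_indices(G.n_samples, k=1)
    ids = G.sample_ids.to_numpy()
    return pd.DataFrame(
        {
            "sample1": ids[iu],
            "sample2": ids[ju],
            "pi_hat": pi_hat[iu, ju],
            "n_variants": n_pair[iu, ju].astype(int),
            "reliable": reliable,
        }
    )


def ibd_exclusions(
    G: GenotypeMatrix, pairs: pd.DataFrame, pi_hat_max: float = 0.2
) -> list[str]:
    """One exclusion per related pair (PI_HAT > threshold).

    The member with the lower call rate is dropped; on a tie the
    lexicographically larger sample id goes.
    """
    cr_s, _ = call_rates(G)
    cr = pd.Series(cr_s, index=G.sample_ids.to_numpy())
    removed: list[str] = []
    flagged = pairs[pairs["pi_hat"] > pi_hat_max].sort_values(
        ["sample1", "sample2"]
    )
    for _, row in flagged.iterrows():
        s1, s2 = row["sample1"], row["sample2"]
        if s1 in removed or s2 in removed:
            continue
        if cr[s1] < cr[s2]:
            removed.append(s1)
        elif cr[s2] < cr[s1]:
            removed.append(s2)
        else:
            removed.append(max(s1, s2))
    return removed


# ----------------------------------------------------------------------
def variant_filters(
    G: GenotypeMatrix,
    maf_min: float = 0.10,
    hwe_alpha: float = 5e-7,
    call_min: float = 0.90,
) -> tuple[list[str], pd.DataFrame]:
    """Apply call-rate, HWE and MAF filters per variant.

    A variant is kept iff call rate >= ``call_min`` AND HWE exact
    p > ``hwe_alpha`` AND MAF >= ``maf_min`` (both boundaries inclusive
    on the keep side, matching the >=/<= phrasing of the thresholds).
    X-flagged variants are HWE-tested on females only, since hemizygous
    male calls are structurally homozygous. The removal reason is the
    first failing filter in the order call_rate, hwe, maf.
    """
    for t in (maf_min, hwe_alpha, call_min):
        if not (0.0 < t < 1.0):
            raise ValueError("thresholds must be in (0, 1)")
    _, cr_v = call_rates(G)
    maf = G.maf()
    female = (G.sample_meta["reported_sex"] == "F").to_numpy()
    is_x = G.variant_meta["is_x"].to_numpy()

    kept: list[str] = []
    records = []
    for j, snp in enumerate(G.variant_ids):
        if cr_v[j] < call_min:
            records.append((snp, "call_rate"))
            continue
        col = G.dosages[:, j]
        hwe_p = _hwe_p_from_dosages(col[female] if is_x[j] else col)
        if hwe_p <= hwe_alpha:
            records.append((snp, "hwe"))
            continue
        if not (maf[j] >= maf_min):
            records.append((snp, "maf"))
            continue
        kept.append(snp)
    removed = pd.DataFrame(records, columns=["snp", "reason"])
    return kept, removed


# ----------------------------------------------------------------------
def _pairwise_r2(X: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns, pairwise-complete."""
    if np.isnan(X).any():
        r = pd.DataFrame(X).corr(min_periods=2).to_numpy()
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(X.T)
    r = np.nan_to_num(np.atleast_2d(r))
    return r * r


def ld_prune(
    G: GenotypeMatrix, window: int = 50, step: int = 5, r2_max: float = 0.8
) -> list[str]:
    """Greedy windowed LD pruning of dosage columns.

    Variants are scanned per chromosome in position order with a sliding
    window of ``window`` variants advanced by ``step``. Within a window,
    while any retained pair exceeds ``r2_max`` (pairs visited in index
    order), the member with the lower MAF is removed (ties: the later
    position goes). Deterministic; returns retained variant ids in the
    original order.
    """
    order = G.variant_meta.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
    maf = G.maf()
    pos = G.variant_meta["pos"].to_numpy()
    chrom = G.variant_meta["chrom"].to_numpy()
    keep = np.ones(G.n_variants, dtype=bool)

    for c in pd.unique(chrom[order]):
        idx = order[chrom[order] == c]
        start = 0
        while start < len(idx):
            win = idx[start : start + window]
            active = [j for j in win if keep[j]]
            if len(active) > 1:
                r2 = _pairwise_r2(G.dosages[:, active])
                alive = {j: True for j in active}
                changed = True
                while changed:
                    changed = False
                    live = [j for j in active if alive[j]]
                    li = {j: active.index(j) for j in live}
                    for a_i in range(len(live)):
                        for b_i in range(a_i + 1, len(live)):
                            ja, jb = live[a_i], live[b_i]
                            if r2[li[ja], li[jb]] > r2_max:
                                if maf[ja] < maf[jb]:
                                    drop = ja
                                elif maf[jb] < maf[ja]:
                                    drop = jb
                                else:
                                    drop = ja if pos[ja] > pos[jb] else jb
                                alive[drop] = False
                                changed = True
                                break
                        if changed:
                            break
                for j in active:
                    if not alive[j]:
                        keep[j] = False
            if start + window >= len(idx):
                break
            start += step
    return [s for j, s in enumerate(G.variant_ids) if keep[j]]


# ----------------------------------------------------------------------
@dataclass
class QcThresholds:
    """Bundle of QC thresholds with the standard defaults."""

    sample_call_min: float = 0.90
    variant_call_min: float = 0.90
    hwe_alpha: float = 5e-7
    maf_min: float = 0.10
    pi_hat_max: float = 0.2
    prune_window: int = 50
    prune_step: int = 5
    prune_r2: float = 0.8
    sex_t_male: float = 0.05
    sex_t_female: float = 0.15

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def run_qc(
    G: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Full QC: sample filters, then variant filters, then LD pruning.

    Sample stages run in order call rate -> sex check -> IBD so each
    removal carries the first applicable reason. Idempotent: running QC
    on its own output removes nothing further (pruning retains a set
    with no over-threshold pair inside any window).
    """
    th = thresholds or QcThresholds()
    report = QcReport(thresholds=th.to_dict())

    # -- samples: call rate
    cr_s, _ = call_rates(G)
    bad = cr_s < th.sample_call_min
    report.add_samples(G.sample_ids[bad], "call_rate")
    G = G.subset(samples=np.flatnonzero(~bad))

    # -- samples: sex concordance
    sx = sex_check(G, th.sex_t_male, th.sex_t_female)
    bad = sx["mismatch"].to_numpy()
    report.add_samples(G.sample_ids[bad], "sex_mismatch")
    G = G.subset(samples=np.flatnonzero(~bad))

    # -- samples: relatedness
    pairs = relatedness(G)
    drop = set(ibd_exclusions(G, pairs, th.pi_hat_max))
    report.add_samples(sorted(drop), "ibd")
    keep = [i for i, s in enumerate(G.sample_ids) if s not in drop]
    G = G.subset(samples=keep)

    # -- variants: call rate / HWE / MAF
    kept, removed = variant_filters(
        G, maf_min=th.maf_min, hwe_alpha=th.hwe_alpha, call_min=th.variant_call_min
    )
    for reason in ("call_rate", "hwe", "maf"):
        report.add_variants(removed.loc[removed["reason"] == reason, "snp"], reason)
    G = G.subset(variants=G.variant_index(kept))

    # -- variants: LD pruning
    retained = set(ld_prune(G, th.prune_window, th.prune_step, th.prune_r2))
    pruned = [s for s in G.variant_ids if s not in retained]
    report.add_variants(pruned, "ld_prune")
    G = G.subset(variants=G.variant_index([s for s in G.variant_ids if s in retained]))
    return G, report
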